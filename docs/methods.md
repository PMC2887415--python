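# Methods

## Setting

The package analyses the *output* of an EST assembly of pooled,
population-level cDNA reads: unigene sequences (contigs and singletons),
the padded multiple alignments of reads within each contig, and tabular
translated-search hits of unigenes against reference protein sets. It does
not clean reads, assemble, or run searches; those artifacts are inputs.
All column analysis happens in padded coordinates; all base-pair-denominated
statistics (lengths, coverage, per-kb rates) use unpadded consensus lengths,
so rates are comparable across assemblies regardless of pad density.

## SNP calling

A column is considered only when its consensus character is not a pad and at
least two distinct nucleotide alleles (A/C/G/T) occur among covering reads.
Reads contributing a pad or an N at the column are excluded from allele
counts *and* from the coverage used by the 25% test: the criteria speak of
nucleotide alleles among ESTs covering the position. Defaults:

| parameter | default | meaning |
|---|---|---|
| `loose_min_reads` | 2 | each of the two most common alleles in ≥ 2 ESTs |
| `strict_min_frac` | 0.25 | minority allele ≥ 25% of covering ESTs |
| `strict_min_cov` | 6 | ≥ 6× non-gap, non-N coverage at the column |

At these defaults strict ⊆ loose (coverage ≥ 6 and fraction ≥ 0.25 force a
minor count ≥ 2). Ties for the minor allele are broken alphabetically;
tri-allelic columns produce one call from the top two alleles. Read quality
values are not used anywhere — the alignment layout carries none.

Variant regions chain polymorphic columns (≥ 2 character states, pads
counted as a state, each state backed by ≥ `min_support` = 2 reads)
separated by at most `max_gap` = 11 non-polymorphic columns; single-column
chains are dropped. Variant strings are counted only over reads spanning
the *entire* region — partially overlapping reads are ignored, since a
truncated read cannot distinguish haplotypes and would manufacture phantom
variants.

SNP tables are written as TSV with 0-based unpadded positions and as
minimal VCF 4.2 (1-based positions; the 0→1 shift happens only in the
writer).

## Ortholog hit ratio and coding classification

The ratio counts non-gap characters of the query hit *in residue units on
the translated query row* and divides by the subject protein length —
counting nucleotides would triple the ratio and is dimensionally wrong
against a residue-length denominator. All HSPs of the best subject are
merged as a union of frame-resolved query codon positions, so duplicated or
overlapping HSPs never inflate the ratio; HSPs in conflicting frames keep
the frame with the largest union and flag the annotation. Best hits are
chosen by lowest e-value below the 1e-5 cutoff, ties by bit score then
subject id (determinism). A reader for the plain 12-column tabular dialect
exists, but without aligned rows and subject lengths the gap-aware ratio and
codon reconstruction degrade, and a warning says so.

The merged hit intervals are the putative coding region: a deliberately
conservative CDS estimate (it can only undershoot the true CDS, never
overshoot into UTR, so completeness is not overestimated). A SNP inside it
is classified by rebuilding the containing codon from the frame phase
(interval boundaries are codon-aligned by construction), substituting the
major and minor alleles, and comparing translations under the standard
genetic code; negative frames translate the reverse complement. Codons that
cannot be reconstructed (truncated at an edge, or containing N) are left
unassigned rather than guessed.

## β statistics

For a contig with `S` SNPs over `L` bp at average depth `D`,

    beta = S / (L · H_{round(D) − 1})

with `round` half-up and `H_n` the n-th harmonic number. This is Watterson's
estimator with read depth substituted for the (unknown) number of sampled
haplotypes; it is therefore a *relative* diversity measure, biased by the
factor `H_{K−1}/H_{D−1}` whenever the true haplotype count `K` differs from
`D`. β_t uses all strict SNPs over the contig length; β_n and β_s use
non-synonymous and synonymous strict SNPs over the coding-region length
(both share the same denominator `L_c`; no synonymous/non-synonymous site
partitioning is attempted — fidelity over sophistication). Values are
absent, not zero, when `D` is below `min_cov` (default 6×, avoiding
diverse-but-lowly-expressed contigs; a 2× variant is one argument away) or
when `round(D) − 1 < 1`. A `continuous=True` switch replaces the integer
harmonic number with `ψ(D) + γ` for sensitivity analysis; it agrees with
the default at integer depths. Summary means/medians are computed per
statistic over the contigs where that statistic is individually defined.

The coding SNP rate denominators sum coding-region lengths over unigenes
whose coding region contains at least one strict coding SNP, mirroring the
contigs-with-SNPs convention of the total rate.

## Clustering

The association graph links each unigene to its best same-species unigene
match (self-matches suppressed; the relation contributes at most one edge
per unigene) and to its best protein hit per database. Components are
computed with networkx and reported as unigene-only clusters; an
independently written union-find oracle cross-checks the implementation in
the tests. Reciprocal best hits are *not* required — single-direction best
hits suffice, which is what makes the clustering aggressive.

## Synthetic data

The generator emulates a pooled, normalised cDNA experiment with known
truth. Per gene: a random CDS (ATG + non-stop codons + stop) flanked by
UTRs; `K = n_haplotypes` population haplotypes; reads of ~400 bp (sd 40)
whose starts may overhang the transcript ends and are clipped, keeping
expected depth uniform along the contig; per-contig depth drawn lognormally
(median ≈ 3.3×, mean ≈ 10×) unless `fixed_depth` is set; iid substitution
errors at `error_rate`. Contig alignments are the *true* read placements:
no assembler runs, isolating the post-assembly analysis from assembler
behaviour. A `singleton_fraction` of genes is emitted as single unassembled
reads, and an optional "rRNA-like" family produces mutually divergent
singleton reads that all hit one protein hub (used to exercise the
large-cluster phenomenon).

**Diversity calibration.** `theta` is a Watterson-style per-site diversity
parameter: segregating sites are planted per site with probability
`theta · H_{K−1}`, the neutral expectation for `K` haplotypes. With this
calibration the only systematic bias in β_t recovery is the
depth-vs-haplotype-count factor `H_{K−1}/H_{D−1}` inherent to the statistic
(≈ 0.84 at K = 16, D = 30); measured recovery error at those conditions is
~14–18%.

**Allele frequencies.** By default the minor allele is placed on `K//2`
haplotypes ("balanced"). Pools built from a handful of wild mothers are
dominated by full-sib broods, which makes intermediate frequencies common,
and the strict 25% criterion is explicitly aimed at such alleles. A
`spectrum` option draws the minor-haplotype count from the neutral
frequency spectrum (P(i) ∝ 1/i) instead; under it most planted sites are
rare and — by design of the criterion — undetectable, so detection-based
recovery statements apply to the balanced model only.

**Mutation model.** Planted alleles follow a transition bias
(`transition_probability = 0.56`, matching the ~42–45% transversion share
observed among lepidopteran EST SNPs); sequencing errors remain uniform.
There is **no selection model**: synonymous and non-synonymous planted SNPs
occur at raw mutational proportions (~¾ non-synonymous), unlike real
transcriptomes where purifying selection leaves a synonymous excess. The
generator also has no homopolymer/indel error model (pads never appear in
simulated alignments — the SNP criteria ignore pad columns anyway), no
expression biology, and truth SNPs are recorded only for contig genes (a
singleton unigene is a single read and cannot express population truth).
Passing tests therefore demonstrate correctness of the column arithmetic,
coordinate handling, classification and recovery behaviour — not realism of
assembly artifacts, selection, or 454 error structure.

`truncate_hits` emulates partial gene discovery: each contig gene's
full-CDS hit is replaced by a random subject prefix/suffix whose
completeness is drawn from `Uniform(0.2, 1.0)`, skewed lower for longer
subjects (`length_bias`), reproducing the negative completeness-vs-length
trend; the resulting ratio tracks the drawn completeness to within
one-residue quantisation.

## Problem sizes and numerics

The shipped test suite and the acceptance script use 80–500 simulated genes
per dataset (~10³–10⁴ reads), sizes at which every statistical check is
stable across seeds while the whole suite runs in seconds. β recovery uses
220 contigs at 30× fixed depth, error 0; sensitivity/label replay uses 80
genes at 20× (measured: sensitivity ~97–98%, zero false positives at error
0, 100% coding-label agreement). Harmonic numbers are computed by direct
summation; medians of even-sized sets are the mean of the central pair;
bin assignment is left-closed/right-open with a right-closed last bin.

## Known limitations

* β is not θ: absolute values depend on depth and calling criteria; only
  within-dataset comparisons are meaningful.
* The loose-criterion rate on balanced synthetic data under-represents the
  rare-allele excess that loose calling is designed to capture (use the
  `spectrum` frequency model to study that regime).
* The ACE reader is a convenience for CAP3-style files: it ignores quality
  clipping and complements nothing (ACE read rows are already oriented),
  and clips placements overhanging the consensus.
* Coding classification assumes the unigene *is* the search query
  (identity coordinate mapping); sub-sequence queries are out of scope.
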