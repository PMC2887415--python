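"""Synthetic population-level EST assemblies with known truth.

The generator emulates the statistical structure of a pooled, normalised
cDNA sequencing experiment on a diverse natural population, so that every
stage of the post-assembly pipeline can be tested against planted ground
truth without external data:

* a reference "proteome" of coding transcripts (5' UTR + CDS + 3' UTR);
* ``n_haplotypes`` population haplotypes per gene carrying SNPs planted at a
  per-site density calibrated to a Watterson-style diversity parameter
  ``theta`` (expected segregating sites per site = ``theta * H_{K-1}`` for
  ``K`` haplotypes);
* reads of ~400 bp sampled with per-contig depth drawn from a lognormal
  expression model, carrying their haplotype's alleles plus iid substitution
  errors;
* contig multiple alignments that are the *true* read placements (no
  assembler is run — the subject of the package is the post-assembly
  analysis, so true placements stand in for assembler output);
* singletons (genes represented by a single unassembled read);
* truth-derived translated-search hit records with correct frames and
  subject lengths, optionally truncated to emulate partial gene discovery;
* an optional "rRNA-like" family of high-diversity unassemblable reads that
  all hit a single protein hub, reproducing the large-cluster phenomenon.

All randomness flows from one ``numpy`` generator seeded by the config, so
identical configs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .assembly_model import (
    AlignedRead,
    MultipleAlignment,
    SequenceRecord,
    write_contig_alignment,
    write_fasta,
)
from .diversity import harmonic
from .ortholog_annotation import HitRecord, write_hits

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass
class RrnaFamilyConfig:
    """An unassemblable high-diversity read family sharing one protein hub."""

    n_reads: int = 200
    divergence: float = 0.10
    length: int = 1200
    hub_db: str = "herato"


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a pooled-larvae 454-style transcriptome experiment:
    ~400 bp reads, lognormal per-contig depth with median ~3.3x and mean
    ~10x, 16 population haplotypes, a low substitution error rate, and a
    substantial singleton fraction.  ``theta`` is the Watterson-style
    per-site diversity; the expected planted segregating-site density is
    ``theta * H_{n_haplotypes - 1}``.  ``snp_frequency_model`` controls the
    planted minor-allele haplotype count: ``balanced`` places the minor
    allele on half the pool (intermediate frequencies, as produced by
    pooling a few full-sib broods), ``spectrum`` draws from the neutral
    frequency spectrum (P(i) proportional to 1/i).
    """

    seed: int = 0
    n_genes: int = 50
    protein_length_mean: float = 300.0  # residues
    protein_length_sd: float = 100.0
    protein_length_min: int = 50
    utr_length_mean: float = 120.0  # nt, each end
    utr_length_sd: float = 60.0
    n_haplotypes: int = 16
    theta: float = 0.003
    depth_lognorm_mu: float = 1.194  # median exp(mu) ~ 3.3x
    depth_lognorm_sigma: float = 1.49  # mean ~ 10x
    fixed_depth: float | None = None
    min_depth: float = 2.0
    read_length_mean: float = 400.0
    read_length_sd: float = 40.0
    read_length_min: int = 50
    error_rate: float = 0.001
    singleton_fraction: float = 0.39
    snp_frequency_model: str = "balanced"
    transition_probability: float = 0.56
    db_label: str = "bmori"
    rrna_family: RrnaFamilyConfig | None = None

    def validate(self) -> None:
        for name in ("theta", "error_rate", "singleton_fraction",
                     "transition_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_haplotypes < 2:
            raise ValueError("need at least two haplotypes")
        if self.snp_frequency_model not in ("balanced", "spectrum"):
            raise ValueError(
                f"unknown snp_frequency_model {self.snp_frequency_model!r}"
            )
        min_transcript = 3 * (self.protein_length_min + 1)
        if self.read_length_min > min_transcript:
            raise ValueError(
                f"infeasible config: minimum read length "
                f"({self.read_length_min} nt) exceeds the shortest possible "
                f"transcript ({min_transcript} nt for "
                f"{self.protein_length_min}-residue proteins)"
            )

    # -- (de)serialisation -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        rrna = data.pop("rrna_family", None)
        cfg = cls(**data)
        if rrna is not None:
            cfg.rrna_family = RrnaFamilyConfig(**rrna)
        return cfg


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class GeneTruth:
    """Where the true CDS sits on a unigene and which protein it encodes."""

    unigene_id: str
    kind: str  # contig | singleton | rrna
    subject_id: str
    subject_length: int  # residues
    cds_start: int  # 0-based nt on the unigene, incl. stop codon
    cds_end: int  # half-open
    frame: int


@dataclass
class SnpTruth:
    """One planted polymorphic site (contig genes only)."""

    unigene_id: str
    position: int  # 0-based on the unigene / contig consensus
    ref: str
    alt: str
    n_minor_haplotypes: int
    label: str  # synonymous | non_synonymous | noncoding


@dataclass
class ReadTruth:
    read_id: str
    unigene_id: str
    haplotype: int
    start: int


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    snps: list[SnpTruth] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)


@dataclass
class SimulationResult:
    config: SimulationConfig
    alignments: list[MultipleAlignment]
    unigenes: list[SequenceRecord]
    proteins: list[SequenceRecord]
    hits: list[HitRecord]
    truth: TruthTable


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + random non-stop codons + one stop codon (n_aa residues total)."""
    body = rng.choice(len(_CODONS), size=n_aa - 1)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(_CODONS[i] for i in body) + stop


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n == 0:
        return ""
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """iid substitutions at ``rate``, each to a uniformly different base."""
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


_TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _mutant_base(rng: np.random.Generator, ref: str, ts_prob: float) -> str:
    """Mutant allele with a transition bias (real SNP data shows fewer
    transversions than the 2/3 a uniform choice would give)."""
    if rng.random() < ts_prob:
        return _TRANSITION_PARTNER[ref]
    tv = [b for b in "ACGT" if b != ref and b != _TRANSITION_PARTNER[ref]]
    return tv[rng.integers(2)]


def _minor_count(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    K = cfg.n_haplotypes
    if cfg.snp_frequency_model == "balanced":
        return K // 2
    weights = 1.0 / np.arange(1, K)
    return int(rng.choice(np.arange(1, K), p=weights / weights.sum()))


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def simulate(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Generate one synthetic dataset with full truth (deterministic per seed)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    alignments: list[MultipleAlignment] = []
    unigenes: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    hits: list[HitRecord] = []
    truth = TruthTable()

    snp_site_rate = min(1.0, config.theta * harmonic(config.n_haplotypes - 1))

    for g in range(config.n_genes):
        is_singleton = rng.random() < config.singleton_fraction
        gene_id = (
            f"sing_{g:04d}" if is_singleton else f"contig_{g:04d}"
        )
        subject_id = f"prot_{g:04d}"

        n_aa = max(
            config.protein_length_min,
            int(round(rng.normal(config.protein_length_mean,
                                 config.protein_length_sd))),
        )
        utr5 = max(0, int(round(rng.normal(config.utr_length_mean,
                                           config.utr_length_sd))))
        utr3 = max(0, int(round(rng.normal(config.utr_length_mean,
                                           config.utr_length_sd))))
        cds = _random_cds(rng, n_aa)
        transcript = _random_seq(rng, utr5) + cds + _random_seq(rng, utr3)
        L = len(transcript)
        cds_start, cds_end = utr5, utr5 + len(cds)
        frame = (cds_start % 3) + 1
        protein = _translate(cds[:-3])
        proteins.append(SequenceRecord(subject_id, protein, kind="contig"))

        # planted SNPs (contig genes only: a singleton unigene is a single
        # read, so population truth cannot be expressed on it)
        snp_haps: dict[int, tuple[str, frozenset[int]]] = {}
        if not is_singleton:
            sites = np.nonzero(rng.random(L) < snp_site_rate)[0]
            for pos in sites.tolist():
                ref = transcript[pos]
                alt = _mutant_base(rng, ref, config.transition_probability)
                n_minor = _minor_count(rng, config)
                carriers = frozenset(
                    rng.choice(config.n_haplotypes, size=n_minor,
                               replace=False).tolist()
                )
                if cds_start <= pos < cds_end - 3:  # coding, stop codon excluded
                    ci = (pos - cds_start) // 3
                    codon = cds[3 * ci : 3 * ci + 3]
                    off = (pos - cds_start) % 3
                    mutant = codon[:off] + alt + codon[off + 1 :]
                    label = (
                        "synonymous"
                        if _translate(codon) == _translate(mutant)
                        else "non_synonymous"
                    )
                else:
                    label = "noncoding"
                snp_haps[pos] = (alt, carriers)
                truth.snps.append(
                    SnpTruth(gene_id, pos, ref, alt, n_minor, label)
                )

        # reads
        def draw_read(read_id: str) -> tuple[AlignedRead, int]:
            length = max(
                config.read_length_min,
                int(round(rng.normal(config.read_length_mean,
                                     config.read_length_sd))),
            )
            # starts may overhang either end and are clipped, keeping the
            # expected depth uniform along the transcript
            s0 = int(rng.integers(-(length - 1), L))
            start, end = max(0, s0), min(L, s0 + length)
            hap = int(rng.integers(config.n_haplotypes))
            chars = list(transcript[start:end])
            for pos, (alt, carriers) in snp_haps.items():
                if start <= pos < end and hap in carriers:
                    chars[pos - start] = alt
            bases = _mutate(rng, "".join(chars), config.error_rate)
            return AlignedRead(read_id, start, bases), hap

        if is_singleton:
            read, hap = draw_read(f"r_{g:04d}_0")
            unigenes.append(SequenceRecord(gene_id, read.bases, kind="singleton"))
            truth.reads.append(ReadTruth(read.read_id, gene_id, hap, read.start))
            hit = _singleton_hit(
                gene_id, subject_id, config.db_label, read, n_aa,
                cds_start, transcript,
            )
            if hit is not None:
                hits.append(hit)
            truth.genes[gene_id] = GeneTruth(
                gene_id, "singleton", subject_id, n_aa,
                max(0, cds_start - read.start),
                min(len(read.bases), cds_end - read.start),
                frame,
            )
            continue

        depth = (
            config.fixed_depth
            if config.fixed_depth is not None
            else max(config.min_depth,
                     float(rng.lognormal(config.depth_lognorm_mu,
                                         config.depth_lognorm_sigma)))
        )
        reads: list[AlignedRead] = []
        total = 0
        j = 0
        while total < depth * L:
            read, hap = draw_read(f"r_{g:04d}_{j}")
            reads.append(read)
            truth.reads.append(ReadTruth(read.read_id, gene_id, hap, read.start))
            total += len(read.bases)
            j += 1
        alignments.append(MultipleAlignment(gene_id, transcript, reads))
        unigenes.append(SequenceRecord(gene_id, transcript, kind="contig"))

        q_res = _translate(cds[:-3])
        hits.append(
            HitRecord(
                query_id=gene_id,
                subject_id=subject_id,
                database_label=config.db_label,
                e_value=1e-30,
                bit_score=2.0 * n_aa,
                query_start=cds_start + 1,
                query_end=cds_start + 3 * n_aa,
                subject_start=1,
                subject_end=n_aa,
                frame=frame,
                query_length=L,
                subject_length=n_aa,
                aligned_query_string=q_res,
                aligned_subject_string=protein,
            )
        )
        truth.genes[gene_id] = GeneTruth(
            gene_id, "contig", subject_id, n_aa, cds_start, cds_end, frame
        )

    if config.rrna_family is not None:
        _add_rrna_family(config, rng, unigenes, proteins, hits, truth)

    return SimulationResult(config, alignments, unigenes, proteins, hits, truth)


def _singleton_hit(
    gene_id: str,
    subject_id: str,
    db_label: str,
    read: AlignedRead,
    n_aa: int,
    cds_start: int,
    transcript: str,
) -> HitRecord | None:
    """The part of the CDS a singleton read covers, as a gapless HSP in the
    read's own coordinates (the singleton unigene IS the read)."""
    s, e = read.start, read.start + len(read.bases)
    cds_cut = cds_start + 3 * n_aa  # stop codon excluded
    c0 = max(s, cds_start)
    c0 = cds_start + 3 * ((c0 - cds_start + 2) // 3)  # round up to codon start
    c1 = min(e, cds_cut)
    n_codons = (c1 - c0) // 3
    if n_codons < 1:
        return None
    c1 = c0 + 3 * n_codons
    sstart = (c0 - cds_start) // 3 + 1
    q0 = c0 - s  # on the read
    # translate from the read itself (it may carry alleles and errors)
    q_row = _translate(read.bases[q0 : q0 + 3 * n_codons])
    s_row = _translate(transcript[c0:c1])
    return HitRecord(
        query_id=gene_id,
        subject_id=subject_id,
        database_label=db_label,
        e_value=1e-20,
        bit_score=2.0 * n_codons,
        query_start=q0 + 1,
        query_end=q0 + 3 * n_codons,
        subject_start=sstart,
        subject_end=sstart + n_codons - 1,
        frame=(q0 % 3) + 1,
        query_length=len(read.bases),
        subject_length=n_aa,
        aligned_query_string=q_row,
        aligned_subject_string=s_row,
    )


def _add_rrna_family(
    config: SimulationConfig,
    rng: np.random.Generator,
    unigenes: list[SequenceRecord],
    proteins: list[SequenceRecord],
    hits: list[HitRecord],
    truth: TruthTable,
) -> None:
    """Singleton reads too divergent to assemble, all best-hitting one hub."""
    fam = config.rrna_family
    n_codons = fam.length // 3
    base = _random_cds(rng, n_codons)
    hub_protein = _translate(base[:-3])
    hub_id = "rrna_hub"
    proteins.append(SequenceRecord(hub_id, hub_protein, kind="contig"))
    n_aa = len(hub_protein)
    for i in range(fam.n_reads):
        uid = f"rrna_{i:04d}"
        seq = _mutate(rng, base, fam.divergence)
        unigenes.append(SequenceRecord(uid, seq, kind="singleton"))
        # hub hit over a random ~half of the protein
        k = max(10, int(n_aa * rng.uniform(0.3, 0.8)))
        s0 = int(rng.integers(0, n_aa - k + 1))
        hits.append(
            HitRecord(
                query_id=uid,
                subject_id=hub_id,
                database_label=fam.hub_db,
                e_value=1e-15,
                bit_score=1.5 * k,
                query_start=3 * s0 + 1,
                query_end=3 * (s0 + k),
                subject_start=s0 + 1,
                subject_end=s0 + k,
                frame=1,
                query_length=len(seq),
                subject_length=n_aa,
                aligned_query_string=_translate(seq[3 * s0 : 3 * (s0 + k)]),
                aligned_subject_string=hub_protein[s0 : s0 + k],
            )
        )
        truth.genes[uid] = GeneTruth(
            uid, "rrna", hub_id, n_aa, 0, len(seq), 1
        )


# ---------------------------------------------------------------------------
# hit truncation (partial gene discovery)
# ---------------------------------------------------------------------------


def truncate_hits(
    result: SimulationResult,
    completeness: tuple[float, float] = (0.2, 1.0),
    length_bias: float = 2.0,
    rng: np.random.Generator | None = None,
) -> list[HitRecord]:
    """Replace each contig gene's full-CDS hit with a partial HSP.

    Each hit keeps a random subject prefix or suffix whose fraction of the
    subject is drawn from ``Uniform(completeness)`` skewed low for longer
    subjects (``length_bias`` > 0 gives the negative completeness-vs-length
    trend seen in real transcript discovery).  The resulting ortholog hit
    ratio approximates the drawn completeness up to one-residue quantisation.
    """
    rng = rng if rng is not None else np.random.default_rng(result.config.seed + 1)
    lo, hi = completeness
    if not 0 < lo <= hi <= 1.5:
        raise ValueError(f"bad completeness range {completeness}")

    contig_hits = [
        h for h in result.hits
        if result.truth.genes[h.query_id].kind == "contig"
    ]
    other = [
        h for h in result.hits
        if result.truth.genes[h.query_id].kind != "contig"
    ]
    slens = np.array([h.subject_length for h in contig_hits], dtype=float)
    if slens.size and slens.max() > slens.min():
        w = (slens - slens.min()) / (slens.max() - slens.min())
    else:
        w = np.zeros_like(slens)

    out: list[HitRecord] = []
    for h, wi in zip(contig_hits, w):
        gene = result.truth.genes[h.query_id]
        n_aa = h.subject_length
        u = rng.uniform()
        c = lo + (hi - lo) * u ** (1.0 + length_bias * wi)
        k = max(1, int(round(c * n_aa)))
        if k >= n_aa:
            out.append(h)
            continue
        if rng.random() < 0.5:
            sstart, send = 1, k  # prefix
        else:
            sstart, send = n_aa - k + 1, n_aa  # suffix
        q0 = gene.cds_start + 3 * (sstart - 1)
        out.append(
            HitRecord(
                query_id=h.query_id,
                subject_id=h.subject_id,
                database_label=h.database_label,
                e_value=h.e_value,
                bit_score=2.0 * k,
                query_start=q0 + 1,
                query_end=q0 + 3 * k,
                subject_start=sstart,
                subject_end=send,
                frame=h.frame,
                query_length=h.query_length,
                subject_length=n_aa,
                aligned_query_string=h.aligned_query_string[sstart - 1 : send],
                aligned_subject_string=h.aligned_subject_string[sstart - 1 : send],
            )
        )
    return out + other


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_dataset(result: SimulationResult, out_dir: str | Path) -> None:
    """Write alignments, FASTAs, hit table, truth tables and the config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_contig_alignment(result.alignments, out / "alignments.txt")
    write_fasta(result.unigenes, out / "unigenes.fasta")
    write_fasta(result.proteins, out / "proteins.fasta")
    write_hits(result.hits, out / "hits.tsv")
    result.config.to_json(out / "config.json")

    with open(out / "truth_genes.tsv", "w") as fh:
        fh.write(
            "unigene_id\tkind\tsubject_id\tsubject_length\t"
            "cds_start\tcds_end\tframe\n"
        )
        for g in result.truth.genes.values():
            fh.write(
                f"{g.unigene_id}\t{g.kind}\t{g.subject_id}\t"
                f"{g.subject_length}\t{g.cds_start}\t{g.cds_end}\t{g.frame}\n"
            )
    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("unigene_id\tposition\tref\talt\tn_minor_haplotypes\tlabel\n")
        for s in result.truth.snps:
            fh.write(
                f"{s.unigene_id}\t{s.position}\t{s.ref}\t{s.alt}\t"
                f"{s.n_minor_haplotypes}\t{s.label}\n"
            )
    with open(out / "truth_reads.tsv", "w") as fh:
        fh.write("read_id\tunigene_id\thaplotype\tstart\n")
        for r in result.truth.reads:
            fh.write(f"{r.read_id}\t{r.unigene_id}\t{r.haplotype}\t{r.start}\n")
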