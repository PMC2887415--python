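"""Column-wise SNP calling from contig multiple alignments.

Each padded column of a contig's read layout is analysed independently.  A
column is a candidate SNP when the consensus position is not a pad and at
least two distinct nucleotide alleles (over ``A C G T``; ``N`` and pads are
ignored) are present among the covering reads.  Two published criteria are
implemented:

* **loose** — each of the two most common alleles is found in at least two
  ESTs; designed to maximise the discovery of rare alleles.
* **strict** — the minority allele (second most common nucleotide) accounts
  for at least 25% of the ESTs covering the position, and total coverage at
  the position is at least 6x; designed to minimise false positives from
  sequencing error.

At the defaults every strict call is also a loose call (coverage >= 6 and
minor fraction >= 0.25 imply a minor count >= 2).

The module also provides substitution classification (transition vs
transversion), assembler-style variant-region detection (runs of nearby
polymorphic columns whose spanning read strings define multi-base variants),
and dataset-level SNP-rate summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .assembly_model import GAP, MultipleAlignment, profile_matrix

NUCLEOTIDES = "ACGT"
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

TRANSITION = "transition"
TRANSVERSION = "transversion"

LOOSE = "loose"
STRICT = "strict"


@dataclass
class SnpCall:
    """One polymorphic alignment column.

    ``coverage`` counts non-gap, non-N reads at the column; allele counts
    are over ``A C G T`` only.  ``coding_class`` starts ``unassigned`` and is
    filled in by the annotation stage.
    """

    contig_id: str
    padded_column: int
    unpadded_position: int
    consensus_base: str
    allele_counts: dict[str, int]
    major_allele: str
    minor_allele: str
    coverage: int
    passes_loose: bool
    passes_strict: bool
    substitution_class: str
    coding_class: str = "unassigned"


def classify_substitution(base1: str, base2: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    if base1 == base2:
        raise ValueError(f"identical alleles {base1!r}")
    pair = {base1, base2}
    if not pair <= set(NUCLEOTIDES):
        raise ValueError(f"non-nucleotide alleles {base1!r}, {base2!r}")
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return TRANSITION
    return TRANSVERSION


def _top_two_alleles(counts: dict[str, int]) -> tuple[str, str]:
    """Major and minor allele; ties broken alphabetically for determinism."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[0][0], ranked[1][0]


def call_snps(
    alignment: MultipleAlignment,
    criterion: str = STRICT,
    strict_min_frac: float = 0.25,
    strict_min_cov: int = 6,
    loose_min_reads: int = 2,
) -> list[SnpCall]:
    """Call SNPs on every column of one alignment under ``criterion``.

    Returns calls passing the requested criterion, each carrying both
    ``passes_loose`` and ``passes_strict`` flags.  Columns whose consensus
    character is a pad are never reported, and tri-allelic columns yield a
    single call built from the top two alleles.
    """
    if criterion not in (LOOSE, STRICT):
        raise ValueError(f"unknown criterion {criterion!r}")

    counts = profile_matrix(alignment)[:, :4]  # A C G T
    coverage = counts.sum(axis=1)
    n_alleles = (counts > 0).sum(axis=1)
    ranked = -np.sort(-counts, axis=1)
    major_n, minor_n = ranked[:, 0], ranked[:, 1]

    cons = np.frombuffer(alignment.consensus.encode(), dtype=np.uint8)
    candidate = (n_alleles >= 2) & (cons != ord(GAP))
    loose_ok = candidate & (major_n >= loose_min_reads) & (minor_n >= loose_min_reads)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(coverage > 0, minor_n / np.maximum(coverage, 1), 0.0)
    strict_ok = candidate & (coverage >= strict_min_cov) & (frac >= strict_min_frac)

    wanted = loose_ok if criterion == LOOSE else strict_ok
    cols = np.nonzero(wanted)[0]
    if cols.size == 0:
        return []

    pads_before = np.cumsum(
        np.frombuffer(alignment.consensus.encode(), dtype=np.uint8) == ord(GAP)
    )
    calls: list[SnpCall] = []
    for col in cols.tolist():
        allele_counts = {
            b: int(counts[col, i]) for i, b in enumerate(NUCLEOTIDES) if counts[col, i]
        }
        major, minor = _top_two_alleles(allele_counts)
        unpadded = col - (int(pads_before[col - 1]) if col > 0 else 0)
        calls.append(
            SnpCall(
                contig_id=alignment.contig_id,
                padded_column=col,
                unpadded_position=unpadded,
                consensus_base=alignment.consensus[col],
                allele_counts=allele_counts,
                major_allele=major,
                minor_allele=minor,
                coverage=int(coverage[col]),
                passes_loose=bool(loose_ok[col]),
                passes_strict=bool(strict_ok[col]),
                substitution_class=classify_substitution(major, minor),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# variant regions
# ---------------------------------------------------------------------------


@dataclass
class VariantRegion:
    """A run of nearby polymorphic columns and its spanning haplotype strings.

    Polymorphic columns (>= 2 character states, pads included, each backed by
    at least ``min_support`` reads) are chained while at most ``max_gap``
    non-polymorphic columns separate them.  ``n_variants`` counts the
    distinct full-span read strings with sufficient support among reads that
    cover the whole region.
    """

    contig_id: str
    start: int
    end: int  # inclusive, padded coordinates
    length: int  # unpadded bp spanned
    n_variants: int
    support: dict[str, int]


def _polymorphic_columns(
    alignment: MultipleAlignment, min_support: int
) -> np.ndarray:
    counts = profile_matrix(alignment)
    # allele states are A, C, G, T and the pad; N is never an allele
    states = np.concatenate([counts[:, :4], counts[:, 5:6]], axis=1)
    return np.nonzero((states >= min_support).sum(axis=1) >= 2)[0]


def detect_variant_regions(
    alignment: MultipleAlignment, max_gap: int = 11, min_support: int = 2
) -> list[VariantRegion]:
    """Chain polymorphic columns into multi-column variant regions.

    Single-column chains (isolated SNPs flanked by more than ``max_gap``
    monomorphic columns) are excluded.  Variant strings are counted only
    over reads spanning the entire region, each needing ``min_support``
    reads; regions with fewer than two supported variants are dropped.
    """
    poly = _polymorphic_columns(alignment, min_support)
    if poly.size == 0:
        return []

    chains: list[list[int]] = [[int(poly[0])]]
    for col in poly[1:].tolist():
        if col - chains[-1][-1] - 1 <= max_gap:
            chains[-1].append(col)
        else:
            chains.append([col])

    regions: list[VariantRegion] = []
    for chain in chains:
        if len(chain) < 2:
            continue
        start, end = chain[0], chain[-1]
        support: dict[str, int] = {}
        for read in alignment.reads:
            if read.start <= start and read.end > end:
                s = read.bases[start - read.start : end - read.start + 1]
                support[s] = support.get(s, 0) + 1
        support = {s: n for s, n in support.items() if n >= min_support}
        if len(support) < 2:
            continue
        span = alignment.consensus[start : end + 1]
        regions.append(
            VariantRegion(
                contig_id=alignment.contig_id,
                start=start,
                end=end,
                length=len(span) - span.count(GAP),
                n_variants=len(support),
                support=support,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# rate summaries
# ---------------------------------------------------------------------------


def per_kb(n: int, bp: float) -> float:
    """Events per 1,000 bases; rounding happens only at presentation."""
    if bp <= 0:
        raise ValueError("denominator must be positive")
    return 1000.0 * n / bp


@dataclass
class SnpRateSummary:
    """Dataset-level SNP discovery statistics.

    The per-kb denominator is the summed unpadded length of contigs that
    contain at least one reported SNP.
    """

    n_snps: int
    n_contigs_with_snps: int
    bp_in_contigs_with_snps: int
    transversions: int
    transitions: int
    snps_per_kb: float | None = field(init=False)
    transversion_fraction: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.snps_per_kb = (
            per_kb(self.n_snps, self.bp_in_contigs_with_snps)
            if self.bp_in_contigs_with_snps > 0
            else None
        )
        self.transversion_fraction = (
            self.transversions / self.n_snps if self.n_snps else None
        )


def snp_rate_summary(
    alignments: Sequence[MultipleAlignment], calls: Sequence[SnpCall]
) -> SnpRateSummary:
    """Summarise calls produced from ``alignments`` into dataset rates."""
    lengths = {a.contig_id: a.unpadded_length for a in alignments}
    with_snps = {c.contig_id for c in calls}
    missing = with_snps - lengths.keys()
    if missing:
        raise ValueError(f"calls reference unknown contigs: {sorted(missing)[:3]}")
    return SnpRateSummary(
        n_snps=len(calls),
        n_contigs_with_snps=len(with_snps),
        bp_in_contigs_with_snps=sum(lengths[c] for c in with_snps),
        transversions=sum(
            1 for c in calls if c.substitution_class == TRANSVERSION
        ),
        transitions=sum(1 for c in calls if c.substitution_class == TRANSITION),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "contig_id\tposition\tmajor\tminor\tmajor_count\tminor_count\tcoverage\t"
    "passes_loose\tpasses_strict\tsubstitution_class\tcoding_class\n"
)


def write_snp_tsv(calls: Iterable[SnpCall], path: str | Path) -> None:
    """SNP table with 0-based unpadded positions."""
    with open(path, "w") as fh:
        fh.write(_TSV_COLUMNS)
        for c in calls:
            fh.write(
                f"{c.contig_id}\t{c.unpadded_position}\t{c.major_allele}\t"
                f"{c.minor_allele}\t{c.allele_counts[c.major_allele]}\t"
                f"{c.allele_counts[c.minor_allele]}\t{c.coverage}\t"
                f"{int(c.passes_loose)}\t{int(c.passes_strict)}\t"
                f"{c.substitution_class}\t{c.coding_class}\n"
            )


def write_vcf(calls: Iterable[SnpCall], path: str | Path) -> None:
    """Minimal VCF 4.2: CHROM is the contig id, POS is 1-based (internal
    coordinates are 0-based; the shift happens only here), REF is the
    consensus base and ALT the called allele differing from it."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Coverage">\n')
        fh.write(
            '##INFO=<ID=MC,Number=2,Type=Integer,Description='
            '"Major and minor allele read counts">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            ref = c.consensus_base
            alt = c.minor_allele if c.minor_allele != ref else c.major_allele
            info = (
                f"DP={c.coverage};"
                f"MC={c.allele_counts[c.major_allele]},"
                f"{c.allele_counts[c.minor_allele]}"
            )
            fh.write(
                f"{c.contig_id}\t{c.unpadded_position + 1}\t.\t{ref}\t{alt}\t"
                f".\tPASS\t{info}\n"
            )
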