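"""Translated-search hit parsing, ortholog hit ratios, and SNP coding classes.

Unigenes are compared against reference protein sets with a translated
search; each unigene and its best hit are treated as putative orthologs.  The
**ortholog hit ratio** measures how much of the reference protein a unigene
recovers: the number of non-gap characters of the query's hit region, counted
in residue (codon) units on the translated query row, divided by the subject
protein length.  A gapless alignment covering the whole subject gives exactly
1.0; ratios above 1.0 indicate relative insertions in the unigene.

The query interval of the best hit is also a conservative estimate of the
unigene's coding region ("putative coding region"); SNPs inside it can be
classified as synonymous or non-synonymous by substituting the two alleles
into the codon that contains them and translating with the standard genetic
code (reverse frames via the reverse complement).

Coordinates: the tabular hit dialect is 1-based inclusive (nucleotides on
the query, residues on the subject); everything internal is 0-based
half-open, and the converters in this module are the only place the shift
happens.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .assembly_model import FormatError, SequenceRecord
from .snp_caller import SnpCall

NON_SYNONYMOUS = "non_synonymous"
SYNONYMOUS = "synonymous"
NONCODING = "noncoding"
UNASSIGNED = "unassigned"

#: header of the extended tabular dialect (a superset of the standard
#: translated-search tabular output, with frame, lengths and aligned rows)
EXTENDED_COLUMNS = [
    "qseqid", "sseqid", "db", "evalue", "bitscore", "qstart", "qend",
    "sstart", "send", "frame", "qlen", "slen", "qseq_aln", "sseq_aln",
]

_STANDARD_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class HitRecord:
    """One translated-search alignment (HSP) of a nucleotide query against a
    protein subject."""

    query_id: str
    subject_id: str
    database_label: str
    e_value: float
    bit_score: float
    query_start: int  # 1-based inclusive, nucleotides on the query
    query_end: int
    subject_start: int  # 1-based inclusive, residues on the subject
    subject_end: int
    frame: int  # in {+-1, +-2, +-3}
    query_length: int  # nt
    subject_length: int  # residues
    aligned_query_string: str | None = None  # translated query row, gapped
    aligned_subject_string: str | None = None

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise FormatError(f"{self.query_id}: negative e-value")
        if self.frame not in (-3, -2, -1, 1, 2, 3):
            raise FormatError(f"{self.query_id}: bad frame {self.frame}")
        q, s = self.aligned_query_string, self.aligned_subject_string
        if (q is None) != (s is None):
            raise FormatError(f"{self.query_id}: only one aligned row present")
        if q is not None and s is not None:
            if len(q) != len(s):
                raise FormatError(
                    f"{self.query_id} vs {self.subject_id}: gapped rows of "
                    f"unequal length ({len(q)} vs {len(s)})"
                )
            q_res = len(q) - q.count("-")
            expect_q = (abs(self.query_end - self.query_start) + 1) // 3
            if q_res != expect_q:
                raise FormatError(
                    f"{self.query_id}: query row has {q_res} residues, "
                    f"coordinates span {expect_q}"
                )
            s_res = len(s) - s.count("-")
            expect_s = self.subject_end - self.subject_start + 1
            if s_res != expect_s:
                raise FormatError(
                    f"{self.query_id}: subject row has {s_res} residues, "
                    f"coordinates span {expect_s}"
                )

    @property
    def has_alignment_rows(self) -> bool:
        return self.aligned_query_string is not None


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def read_hits(path: str | Path, dialect: str = "extended") -> list[HitRecord]:
    """Read a tabular hit file.  No e-value filtering happens here.

    ``dialect='extended'`` expects the 14-column format with a header line
    (see :data:`EXTENDED_COLUMNS`).  ``dialect='standard'`` accepts plain
    12-column translated-search tabular output without aligned rows; frames
    are then inferred from coordinate orientation, subject lengths are
    unknown (0), and downstream gap-aware computations degrade.
    """
    if dialect == "extended":
        return _read_extended(path)
    if dialect == "standard":
        return _read_standard(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_extended(path: str | Path) -> list[HitRecord]:
    records: list[HitRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EXTENDED_COLUMNS:
            raise FormatError(f"{path}:1: bad or missing header line")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(EXTENDED_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(EXTENDED_COLUMNS)} "
                    f"columns, found {len(fields)}"
                )
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    database_label=fields[2],
                    e_value=float(fields[3]),
                    bit_score=float(fields[4]),
                    query_start=int(fields[5]),
                    query_end=int(fields[6]),
                    subject_start=int(fields[7]),
                    subject_end=int(fields[8]),
                    frame=int(fields[9]),
                    query_length=int(fields[10]),
                    subject_length=int(fields[11]),
                    aligned_query_string=fields[12],
                    aligned_subject_string=fields[13],
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_standard(path: str | Path) -> list[HitRecord]:
    warnings.warn(
        "standard 12-column hits carry no aligned rows or subject lengths; "
        "ortholog hit ratios and SNP classification will degrade",
        stacklevel=2,
    )
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != len(_STANDARD_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_STANDARD_COLUMNS)} "
                    f"columns, found {len(fields)}"
                )
            try:
                qstart, qend = int(fields[6]), int(fields[7])
                forward = qstart <= qend
                frame = ((min(qstart, qend) - 1) % 3) + 1
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    database_label="",
                    e_value=float(fields[10]),
                    bit_score=float(fields[11]),
                    query_start=qstart,
                    query_end=qend,
                    subject_start=int(fields[8]),
                    subject_end=int(fields[9]),
                    frame=frame if forward else -frame,
                    query_length=0,
                    subject_length=0,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_hits(records: Iterable[HitRecord], path: str | Path) -> None:
    """Write the extended 14-column dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("\t".join(EXTENDED_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.database_label}\t"
                f"{r.e_value:g}\t{r.bit_score:g}\t{r.query_start}\t"
                f"{r.query_end}\t{r.subject_start}\t{r.subject_end}\t"
                f"{r.frame}\t{r.query_length}\t{r.subject_length}\t"
                f"{r.aligned_query_string or ''}\t"
                f"{r.aligned_subject_string or ''}\n"
            )


# ---------------------------------------------------------------------------
# best hits
# ---------------------------------------------------------------------------


def best_hit(
    records: Sequence[HitRecord], e_cutoff: float = 1e-5
) -> list[HitRecord] | None:
    """All HSPs of the best subject for one query, or ``None``.

    Records at or above the e-value cutoff are discarded; the best subject
    has the lowest e-value, ties broken by highest bit score and then
    lexicographic subject id for determinism.
    """
    if not records:
        return None
    queries = {r.query_id for r in records}
    if len(queries) > 1:
        raise ValueError(f"records span multiple queries: {sorted(queries)}")
    kept = [r for r in records if r.e_value < e_cutoff]
    if not kept:
        return None
    by_subject: dict[str, list[HitRecord]] = {}
    for r in kept:
        by_subject.setdefault(r.subject_id, []).append(r)
    best = min(
        by_subject,
        key=lambda s: (
            min(r.e_value for r in by_subject[s]),
            -max(r.bit_score for r in by_subject[s]),
            s,
        ),
    )
    return by_subject[best]


def best_hits_by_query(
    records: Iterable[HitRecord], e_cutoff: float = 1e-5
) -> dict[str, list[HitRecord]]:
    """Group records by query and select each query's best subject."""
    grouped: dict[str, list[HitRecord]] = {}
    for r in records:
        grouped.setdefault(r.query_id, []).append(r)
    out: dict[str, list[HitRecord]] = {}
    for q, recs in grouped.items():
        chosen = best_hit(recs, e_cutoff=e_cutoff)
        if chosen is not None:
            out[q] = chosen
    return out


# ---------------------------------------------------------------------------
# ortholog hit ratio
# ---------------------------------------------------------------------------


@dataclass
class OrthologAnnotation:
    """Best-hit region of one unigene and its ortholog hit ratio.

    ``hit_intervals`` are the merged query nucleotide intervals (0-based,
    half-open) of the dominant frame; ``non_gap_query_residues`` counts the
    union of frame-resolved aligned query codons over all HSPs of the best
    subject (duplicated or overlapping HSPs count once).
    """

    query_id: str
    subject_id: str
    subject_length: int
    hit_intervals: list[tuple[int, int]]
    non_gap_query_residues: int
    ortholog_hit_ratio: float
    frame: int
    frame_conflict: bool = False


def _codon_starts(hit: HitRecord) -> set[int]:
    """0-based plus-strand query nt positions of the first base of every
    aligned non-gap query codon in one HSP."""
    if hit.has_alignment_rows:
        row = hit.aligned_query_string
        n_codons = None
    else:
        # degraded: assume a gapless span
        row = None
        n_codons = (abs(hit.query_end - hit.query_start) + 1) // 3

    starts: set[int] = set()
    if hit.frame > 0:
        q0 = min(hit.query_start, hit.query_end) - 1
        if row is None:
            starts.update(q0 + 3 * k for k in range(n_codons))
        else:
            k = 0
            for ch in row:
                if ch != "-":
                    starts.add(q0 + 3 * k)
                    k += 1
    else:
        qhi = max(hit.query_start, hit.query_end)
        if row is None:
            starts.update(qhi - 3 * (k + 1) for k in range(n_codons))
        else:
            k = 0
            for ch in row:
                if ch != "-":
                    starts.add(qhi - 3 * (k + 1))
                    k += 1
    return starts


def _merge_codons(starts: set[int]) -> list[tuple[int, int]]:
    """Merge 3-nt codon blocks into maximal half-open intervals."""
    intervals: list[tuple[int, int]] = []
    for p in sorted(starts):
        if intervals and p <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], p + 3))
        else:
            intervals.append((p, p + 3))
    return intervals


def ortholog_hit_ratio(hsps: Sequence[HitRecord]) -> OrthologAnnotation:
    """Ortholog hit ratio from all HSPs of one query's best subject.

    Non-gap query characters are counted in residue units on the translated
    query row and unioned over HSPs (frame-resolved, overlaps once); the
    ratio divides this union by the subject protein length.
    """
    if not hsps:
        raise ValueError("no HSPs supplied")
    subjects = {h.subject_id for h in hsps}
    if len(subjects) > 1:
        raise ValueError(f"HSPs span multiple subjects: {sorted(subjects)}")
    slen = hsps[0].subject_length
    if slen == 0:
        raise ValueError(f"{hsps[0].subject_id}: subject length is zero")

    by_frame: dict[int, set[int]] = {}
    for h in hsps:
        by_frame.setdefault(h.frame, set()).update(_codon_starts(h))

    total = sum(len(s) for s in by_frame.values())
    dominant = min(by_frame, key=lambda f: (-len(by_frame[f]), f))
    return OrthologAnnotation(
        query_id=hsps[0].query_id,
        subject_id=hsps[0].subject_id,
        subject_length=slen,
        hit_intervals=_merge_codons(by_frame[dominant]),
        non_gap_query_residues=total,
        ortholog_hit_ratio=total / slen,
        frame=dominant,
        frame_conflict=len(by_frame) > 1,
    )


@dataclass
class CodingRegion:
    """Putative coding region of a unigene: merged query nt intervals of the
    dominant frame of its best hit (a conservative CDS estimate)."""

    query_id: str
    intervals: list[tuple[int, int]]  # 0-based half-open, plus-strand coords
    frame: int
    length: int  # L_c in nt
    frame_conflict: bool = False

    def contains(self, position: int) -> tuple[int, int] | None:
        for lo, hi in self.intervals:
            if lo <= position < hi:
                return lo, hi
        return None


def putative_coding_region(annotation: OrthologAnnotation) -> CodingRegion:
    """Hit intervals of the dominant frame as the putative coding region.

    When HSPs of the best subject disagree on frame, the frame with the
    largest codon union is kept and the region is flagged.
    """
    length = sum(hi - lo for lo, hi in annotation.hit_intervals)
    return CodingRegion(
        query_id=annotation.query_id,
        intervals=list(annotation.hit_intervals),
        frame=annotation.frame,
        length=length,
        frame_conflict=annotation.frame_conflict,
    )


# ---------------------------------------------------------------------------
# SNP coding classification
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def classify_snp(
    snp: SnpCall, region: CodingRegion | None, query_sequence: str
) -> str:
    """Synonymous / non-synonymous / noncoding label for one SNP.

    The SNP's unpadded contig position is a query coordinate (the unigene is
    the query).  Positions outside the coding region are noncoding; inside,
    the containing codon is reconstructed from the frame phase, the major and
    minor alleles are substituted, and the translations compared.  Reverse
    frames translate the reverse complement.  Codons that cannot be fully
    reconstructed (truncated at an edge or ambiguous) are left unassigned.
    """
    if region is None:
        return UNASSIGNED
    pos = snp.unpadded_position
    interval = region.contains(pos)
    if interval is None:
        return NONCODING
    lo, hi = interval

    if region.frame > 0:
        codon_lo = lo + 3 * ((pos - lo) // 3)
    else:
        offset_from_end = hi - pos - 1
        codon_lo = hi - 3 * (offset_from_end // 3) - 3
    codon_hi = codon_lo + 3
    if codon_lo < 0 or codon_hi > len(query_sequence) or codon_hi > hi:
        return UNASSIGNED

    plus = query_sequence[codon_lo:codon_hi]
    idx = pos - codon_lo
    variants = []
    for allele in (snp.major_allele, snp.minor_allele):
        codon = plus[:idx] + allele + plus[idx + 1 :]
        if region.frame < 0:
            codon = codon.translate(_COMPLEMENT)[::-1]
        if set(codon) - set("ACGT"):
            return UNASSIGNED
        variants.append(_translate(codon))
    return SYNONYMOUS if variants[0] == variants[1] else NON_SYNONYMOUS


def annotate_calls(
    calls: Iterable[SnpCall],
    regions: Mapping[str, CodingRegion],
    sequences: Mapping[str, str],
) -> None:
    """Fill ``coding_class`` on calls in place.  Calls on unigenes without a
    best-hit annotation stay unassigned."""
    for call in calls:
        region = regions.get(call.contig_id)
        if region is None:
            call.coding_class = UNASSIGNED
        else:
            call.coding_class = classify_snp(
                call, region, sequences[call.contig_id]
            )


# ---------------------------------------------------------------------------
# species hit profiles and stratified ratios
# ---------------------------------------------------------------------------


@dataclass
class SpeciesHitProfile:
    """Which reference protein databases a unigene hits (below the e-value
    cutoff)."""

    query_id: str
    flags: dict[str, bool]

    @property
    def n_databases_hit(self) -> int:
        return sum(self.flags.values())

    @property
    def hit_set(self) -> frozenset[str]:
        return frozenset(db for db, f in self.flags.items() if f)


def species_hit_profiles(
    query_ids: Sequence[str], hit_ids_by_db: Mapping[str, set[str]]
) -> list[SpeciesHitProfile]:
    """Per-query hit/no-hit flags against each database (hit sets must
    already be filtered at the e-value cutoff)."""
    return [
        SpeciesHitProfile(
            q, {db: q in ids for db, ids in hit_ids_by_db.items()}
        )
        for q in query_ids
    ]


def venn_counts(
    profiles: Sequence[SpeciesHitProfile],
) -> dict[frozenset[str], int]:
    """Number of unigenes in each non-empty database-combination region."""
    counts: dict[frozenset[str], int] = {}
    for p in profiles:
        s = p.hit_set
        if s:
            counts[s] = counts.get(s, 0) + 1
    return counts


def venn_composition(
    profiles: Sequence[SpeciesHitProfile],
    kinds: Mapping[str, str],
    coverages: Mapping[str, float],
) -> dict[frozenset[str], dict[str, int]]:
    """Per Venn region, counts of high-coverage contigs (above the median
    contig coverage), low-coverage contigs, and singletons."""
    contig_covs = [
        coverages[q] for q in coverages if kinds.get(q) == "contig"
    ]
    median_cov = statistics.median(contig_covs) if contig_covs else 0.0
    out: dict[frozenset[str], dict[str, int]] = {}
    for p in profiles:
        s = p.hit_set
        if not s:
            continue
        comp = out.setdefault(
            s, {"high_coverage_contig": 0, "low_coverage_contig": 0, "singleton": 0}
        )
        if kinds.get(p.query_id) == "singleton":
            comp["singleton"] += 1
        elif coverages.get(p.query_id, 0.0) > median_cov:
            comp["high_coverage_contig"] += 1
        else:
            comp["low_coverage_contig"] += 1
    return out


def ohr_by_stratum(
    annotations: Sequence[OrthologAnnotation],
    coverages: Mapping[str, float],
    kinds: Mapping[str, str],
) -> dict[str, float | None]:
    """Mean ortholog hit ratio for contigs below vs above the median contig
    coverage, with singletons (coverage 1.0 by definition) as their own
    stratum."""
    contig_covs = [
        cov for q, cov in coverages.items() if kinds.get(q) == "contig"
    ]
    median_cov = statistics.median(contig_covs) if contig_covs else 0.0
    strata: dict[str, list[float]] = {
        "below_median": [], "above_median": [], "singleton": []
    }
    for ann in annotations:
        if kinds.get(ann.query_id) == "singleton":
            strata["singleton"].append(ann.ortholog_hit_ratio)
        elif coverages.get(ann.query_id, 0.0) < median_cov:
            strata["below_median"].append(ann.ortholog_hit_ratio)
        else:
            strata["above_median"].append(ann.ortholog_hit_ratio)
    out: dict[str, float | None] = {
        k: (statistics.fmean(v) if v else None) for k, v in strata.items()
    }
    out["median_coverage"] = median_cov
    return out


def ohr_by_subject_length(
    annotations: Sequence[OrthologAnnotation], bin_edges: Sequence[int]
) -> list[tuple[int, int, int, float | None]]:
    """Mean ortholog hit ratio per subject-length bin (left-closed bins,
    last bin right-closed).  Returns ``(low, high, n, mean_ratio)`` rows."""
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing, >= 2 edges")
    rows: list[tuple[int, int, int, float | None]] = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        vals = [
            a.ortholog_hit_ratio
            for a in annotations
            if lo <= a.subject_length < hi
            or (last and a.subject_length == hi)
        ]
        rows.append((lo, hi, len(vals), statistics.fmean(vals) if vals else None))
    return rows
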