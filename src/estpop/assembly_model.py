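"""Data model and I/O for unigenes and contig multiple alignments.

A transcriptome assembly of expressed sequence tags (ESTs) yields *unigenes*:
contigs (consensus sequences with an associated padded multiple alignment of
their reads) and singletons (reads that assembled with nothing else, treated
as 1x-coverage unigenes).  This module holds the in-memory containers for
both, readers/writers for the plain-text alignment layout format (and a
convenience reader for ACE files as produced by CAP3), and the assembly-level
summary statistics: unigene counts, length distributions, the fraction of
assembled bases left in singletons, and fold-coverage statistics.

Coordinate conventions
----------------------
Column analysis is always carried out in *padded* coordinates (pads are
``'-'``).  Base-pair-denominated quantities (contig length, coverage
denominators) use the *unpadded* consensus length, so that per-kilobase rates
are comparable across assemblies.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

GAP = "-"
#: fixed base ordering used by :func:`profile_matrix` columns
PROFILE_BASES = "ACGTN-"
_BASE_INDEX = {b: i for i, b in enumerate(PROFILE_BASES)}
_SEQ_ALPHABET = set("ACGTN")
_ALN_ALPHABET = _SEQ_ALPHABET | {GAP}


class FormatError(ValueError):
    """A file did not conform to its documented layout."""


class StructuralError(ValueError):
    """Parsed data violated a structural invariant (e.g. read out of bounds)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """One unigene (or reference protein) sequence.

    ``kind`` distinguishes assembled contigs from unassembled singleton ESTs;
    protein records reuse the default kind.
    """

    id: str
    sequence: str
    kind: str = "contig"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty identifier")
        if len(self.sequence) < 1:
            raise FormatError(f"empty sequence for record '{self.id}'")
        if self.kind not in ("contig", "singleton"):
            raise ValueError(f"unknown record kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedRead:
    """A padded read row placed at a 0-based ``start`` on the padded consensus."""

    read_id: str
    start: int
    bases: str

    @property
    def end(self) -> int:
        """Exclusive end in padded coordinates."""
        return self.start + len(self.bases)

    @property
    def n_bases(self) -> int:
        """Non-gap characters contributed by this read."""
        return len(self.bases) - self.bases.count(GAP)


@dataclass
class MultipleAlignment:
    """Padded read layout over one contig consensus.

    Every read must fit inside the consensus bounds, and the unpadded
    consensus (pads removed) is the contig's unigene sequence.
    """

    contig_id: str
    consensus: str
    reads: list[AlignedRead] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if not self.contig_id:
            raise StructuralError("alignment with empty contig id")
        if len(self.consensus) == 0:
            raise StructuralError(f"contig {self.contig_id}: empty consensus")
        bad = set(self.consensus) - _ALN_ALPHABET
        if bad:
            raise StructuralError(
                f"contig {self.contig_id}: consensus contains {sorted(bad)}"
            )
        for read in self.reads:
            if read.start < 0 or read.end > len(self.consensus):
                raise StructuralError(
                    f"contig {self.contig_id}: read {read.read_id} "
                    f"([{read.start}, {read.end})) exceeds consensus bounds "
                    f"[0, {len(self.consensus)})"
                )
            bad = set(read.bases) - _ALN_ALPHABET
            if bad:
                raise StructuralError(
                    f"contig {self.contig_id}: read {read.read_id} "
                    f"contains {sorted(bad)}"
                )

    # -- coordinates -------------------------------------------------------

    @property
    def padded_length(self) -> int:
        return len(self.consensus)

    @property
    def unpadded_consensus(self) -> str:
        return self.consensus.replace(GAP, "")

    @property
    def unpadded_length(self) -> int:
        return len(self.consensus) - self.consensus.count(GAP)

    def unpadded_positions(self) -> np.ndarray:
        """For every padded column, the 0-based unpadded position of its
        consensus base (pad columns get the position of the next base)."""
        is_base = np.frombuffer(self.consensus.encode(), dtype=np.uint8) != ord(GAP)
        return np.cumsum(is_base) - is_base.astype(np.int64)

    def unpadded_position(self, column: int) -> int:
        """Map a padded column holding a consensus base to unpadded coords."""
        if not 0 <= column < self.padded_length:
            raise IndexError(f"column {column} out of range")
        if self.consensus[column] == GAP:
            raise ValueError(
                f"contig {self.contig_id}: column {column} is a consensus pad"
            )
        return column - self.consensus.count(GAP, 0, column)

    def reads_covering(self, column: int) -> Iterator[tuple[str, str]]:
        """Yield ``(read_id, character)`` for reads spanning a padded column."""
        for read in self.reads:
            if read.start <= column < read.end:
                yield read.read_id, read.bases[column - read.start]

    def to_record(self) -> SequenceRecord:
        return SequenceRecord(self.contig_id, self.unpadded_consensus, kind="contig")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, kind: str = "contig") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Empty
    sequences and duplicate identifiers raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not rec.id:
            raise FormatError(f"{path}: FASTA entry with empty header")
        if not seq:
            raise FormatError(f"{path}: empty sequence for record '{rec.id}'")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq, kind=kind))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = (_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records)
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# contig-alignment layout format
# ---------------------------------------------------------------------------
#
# Plain text, one block per contig, blocks separated by blank lines:
#
#   CO <contig_id> <padded_consensus>
#   RD <read_id> <start_0based> <padded_read>
#   RD ...
#
# Pads are '-'.  The format round-trips bit-exactly.


def read_contig_alignment(path: str | Path) -> list[MultipleAlignment]:
    """Parse the documented ``CO``/``RD`` layout file."""
    alignments: list[MultipleAlignment] = []
    contig_id: str | None = None
    consensus = ""
    reads: list[AlignedRead] = []

    def flush() -> None:
        nonlocal contig_id, consensus, reads
        if contig_id is not None:
            alignments.append(MultipleAlignment(contig_id, consensus, reads))
        contig_id, consensus, reads = None, "", []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            fields = line.split()
            tag = fields[0]
            if tag == "CO":
                if contig_id is not None:
                    flush()
                if len(fields) != 3:
                    raise FormatError(f"{path}:{lineno}: malformed CO line")
                contig_id, consensus = fields[1], fields[2].upper()
            elif tag == "RD":
                if contig_id is None:
                    raise FormatError(f"{path}:{lineno}: RD line before CO line")
                if len(fields) != 4:
                    raise FormatError(f"{path}:{lineno}: malformed RD line")
                try:
                    start = int(fields[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer read start {fields[2]!r}"
                    ) from exc
                reads.append(AlignedRead(fields[1], start, fields[3].upper()))
            else:
                raise FormatError(f"{path}:{lineno}: unknown record tag {tag!r}")
    flush()
    return alignments


def write_contig_alignment(
    alignments: Iterable[MultipleAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"CO {aln.contig_id} {aln.consensus}\n")
            for read in aln.reads:
                fh.write(f"RD {read.read_id} {read.start} {read.bases}\n")
            fh.write("\n")


def read_ace(path: str | Path) -> list[MultipleAlignment]:
    """Read an ACE assembly file (CAP3 output) into the same data model.

    Handles the ``CO``/``AF``/``RD`` records; ``*`` pads become ``'-'``.
    Reads whose placement overhangs the consensus are clipped to the
    consensus bounds (quality clipping / ``QA`` records are ignored).
    """
    alignments: list[MultipleAlignment] = []
    with open(path) as fh:
        lines = fh.read().splitlines()

    i = 0
    contig_id: str | None = None
    consensus = ""
    offsets: dict[str, int] = {}
    reads: list[AlignedRead] = []

    def flush() -> None:
        nonlocal contig_id, consensus, reads, offsets
        if contig_id is not None:
            alignments.append(MultipleAlignment(contig_id, consensus, reads))
        contig_id, consensus, reads, offsets = None, "", [], {}

    def read_block(start: int) -> tuple[str, int]:
        seq: list[str] = []
        j = start
        while j < len(lines) and lines[j].strip():
            seq.append(lines[j].strip())
            j += 1
        return "".join(seq), j

    while i < len(lines):
        fields = lines[i].split()
        if not fields:
            i += 1
            continue
        tag = fields[0]
        if tag == "CO":
            flush()
            contig_id = fields[1]
            consensus, i = read_block(i + 1)
            consensus = consensus.upper().replace("*", GAP)
            continue
        if tag == "AF":
            # AF <read> <C|U> <padded start, 1-based>
            offsets[fields[1]] = int(fields[3]) - 1
        elif tag == "RD":
            name = fields[1]
            seq, i = read_block(i + 1)
            seq = seq.upper().replace("*", GAP).replace("X", "N")
            if contig_id is None or name not in offsets:
                raise FormatError(f"{path}: RD '{name}' without AF placement")
            start = offsets[name]
            # clip overhanging ends to the consensus span
            if start < 0:
                seq = seq[-start:]
                start = 0
            if start + len(seq) > len(consensus):
                seq = seq[: len(consensus) - start]
            if seq:
                reads.append(AlignedRead(name, start, seq))
            continue
        i += 1
    flush()
    return alignments


# ---------------------------------------------------------------------------
# column-wise profiles and coverage
# ---------------------------------------------------------------------------


def profile_matrix(alignment: MultipleAlignment) -> np.ndarray:
    """Character counts per padded column.

    Returns an ``(padded_length, 6)`` integer array whose columns follow
    :data:`PROFILE_BASES` (``A C G T N -``); row sums equal the number of
    reads covering each column.
    """
    lut = np.zeros(256, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    counts = np.zeros((alignment.padded_length, len(PROFILE_BASES)), dtype=np.int64)
    for read in alignment.reads:
        codes = lut[np.frombuffer(read.bases.encode(), dtype=np.uint8)]
        np.add.at(counts, (np.arange(read.start, read.end), codes), 1)
    return counts


def column_profile(alignment: MultipleAlignment, column: int) -> dict[str, int]:
    """Counts of ``{A, C, G, T, N, -}`` among reads covering a padded column."""
    if not 0 <= column < alignment.padded_length:
        raise IndexError(
            f"column {column} out of range for contig {alignment.contig_id} "
            f"(padded length {alignment.padded_length})"
        )
    counts = dict.fromkeys(PROFILE_BASES, 0)
    for _, char in alignment.reads_covering(column):
        counts[char] += 1
    return counts


def average_coverage(alignment: MultipleAlignment) -> float:
    """Fold coverage: total non-gap read bases over the unpadded contig length."""
    length = alignment.unpadded_length
    if length == 0:
        raise ValueError(f"contig {alignment.contig_id}: zero-length consensus")
    return sum(read.n_bases for read in alignment.reads) / length


def consensus_discrepancies(alignment: MultipleAlignment) -> list[int]:
    """Padded columns where the majority read character differs from the
    consensus.  The consensus row is otherwise trusted as-is; this is a
    validation aid, not a recomputation."""
    counts = profile_matrix(alignment)
    flagged = []
    for col in range(alignment.padded_length):
        total = counts[col].sum()
        if total == 0:
            continue
        best = int(np.argmax(counts[col]))
        if PROFILE_BASES[best] != alignment.consensus[col]:
            flagged.append(col)
    return flagged


# ---------------------------------------------------------------------------
# assembly summaries
# ---------------------------------------------------------------------------


@dataclass
class AssemblySummary:
    """Dataset-level assembly statistics (unigene accounting, lengths in bp,
    singleton base fraction, fold-coverage statistics)."""

    n_contigs: int
    n_singletons: int
    n_unigenes: int
    mean_contig_length: float | None
    median_contig_length: float | None
    mean_singleton_length: float | None
    median_singleton_length: float | None
    total_bp: int
    singleton_bp_fraction: float | None
    mean_contig_coverage: float | None = None
    median_contig_coverage: float | None = None


def _mean_median(values: Sequence[float]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    # median of an even-sized set is the mean of the central pair
    return statistics.fmean(values), statistics.median(values)


def assembly_summary(
    contigs: Sequence[SequenceRecord],
    singletons: Sequence[SequenceRecord],
    alignments: Sequence[MultipleAlignment] | None = None,
) -> AssemblySummary:
    """Compute unigene counts, length statistics and (when alignments are
    supplied) coverage statistics for one assembly."""
    contig_lengths = [len(r) for r in contigs]
    singleton_lengths = [len(r) for r in singletons]
    mean_c, median_c = _mean_median(contig_lengths)
    mean_s, median_s = _mean_median(singleton_lengths)
    total = sum(contig_lengths) + sum(singleton_lengths)
    frac = (sum(singleton_lengths) / total) if total else None

    mean_cov = median_cov = None
    if alignments:
        covs = [average_coverage(a) for a in alignments]
        mean_cov, median_cov = _mean_median(covs)

    return AssemblySummary(
        n_contigs=len(contigs),
        n_singletons=len(singletons),
        n_unigenes=len(contigs) + len(singletons),
        mean_contig_length=mean_c,
        median_contig_length=median_c,
        mean_singleton_length=mean_s,
        median_singleton_length=median_s,
        total_bp=total,
        singleton_bp_fraction=frac,
        mean_contig_coverage=mean_cov,
        median_contig_coverage=median_cov,
    )


@dataclass
class CoverageBin:
    low: float
    high: float
    n_contigs: int
    mean_length: float | None


def coverage_histogram(
    alignments: Sequence[MultipleAlignment], bin_edges: Sequence[float]
) -> list[CoverageBin]:
    """Group contigs by average read coverage.

    Bins are left-closed/right-open, except the last which is right-closed,
    so every contig with coverage inside ``[edges[0], edges[-1]]`` lands in
    exactly one bin.
    """
    edges = list(bin_edges)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")

    bins = [CoverageBin(lo, hi, 0, None) for lo, hi in zip(edges, edges[1:])]
    sums = [0.0] * len(bins)
    for aln in alignments:
        cov = average_coverage(aln)
        for i, b in enumerate(bins):
            last = i == len(bins) - 1
            if b.low <= cov < b.high or (last and cov == b.high):
                b.n_contigs += 1
                sums[i] += aln.unpadded_length
                break
    for i, b in enumerate(bins):
        if b.n_contigs:
            b.mean_length = sums[i] / b.n_contigs
    return bins
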