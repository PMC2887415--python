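"""Shared fixture builders for the test suite.

Fixtures are constructed programmatically: small hand-written alignments for
exact-value checks, and seeded random generators for property-style tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from estpop.assembly_model import AlignedRead, MultipleAlignment


def make_alignment(
    contig_id: str, consensus: str, reads: list[tuple[str, int, str]]
) -> MultipleAlignment:
    return MultipleAlignment(
        contig_id, consensus, [AlignedRead(r, s, b) for r, s, b in reads]
    )


def column_alignment(contig_id: str, column_chars: str, consensus_base: str = "A"
                     ) -> MultipleAlignment:
    """Single-column alignment: one read per character in ``column_chars``."""
    reads = [(f"r{i}", 0, ch) for i, ch in enumerate(column_chars)]
    return make_alignment(contig_id, consensus_base, reads)


def random_alignment(
    rng: np.random.Generator,
    n_columns: int = 30,
    max_reads: int = 12,
    pad_prob: float = 0.05,
    n_prob: float = 0.02,
) -> MultipleAlignment:
    """A random padded alignment with reads of random spans and characters."""
    cons_chars = rng.choice(list("ACGTACGT-"), size=n_columns)
    # avoid an all-pad consensus
    if all(c == "-" for c in cons_chars):
        cons_chars[0] = "A"
    consensus = "".join(cons_chars)
    n_reads = int(rng.integers(1, max_reads + 1))
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, n_columns))
        length = int(rng.integers(1, n_columns - start + 1))
        chars = []
        for _ in range(length):
            u = rng.random()
            if u < pad_prob:
                chars.append("-")
            elif u < pad_prob + n_prob:
                chars.append("N")
            else:
                chars.append("ACGT"[rng.integers(4)])
        reads.append((f"r{i}", start, "".join(chars)))
    return make_alignment("rand", consensus, reads)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
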