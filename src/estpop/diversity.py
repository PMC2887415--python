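"""Watterson-style relative nucleotide diversity from EST read depth.

When reads are pooled from an unknown number of natural haplotypes, the
classical estimator theta_W (segregating sites over ``L * H_{n-1}`` for *n*
sampled sequences) cannot be computed because *n* is unknown.  The beta
statistics substitute the average read depth *D* for the sample size:

    beta = S / (L * H_{round(D) - 1})

with ``H_n`` the n-th harmonic number.  Per contig, three flavours are
reported:

* ``beta_t`` — all strict-criterion SNPs ``S_t`` over the contig length ``L_t``;
* ``beta_n`` — non-synonymous SNPs ``S_n`` over the coding-region length ``L_c``;
* ``beta_s`` — synonymous SNPs ``S_s`` over ``L_c``.

Because beta conditions on read depth rather than the true number of
haplotypes, it is a *relative* measure: comparable within one dataset, biased
as an absolute estimate of theta whenever depth differs from the haplotype
count.  Summaries are restricted to contigs with average coverage of at
least ``min_cov`` (default 6x) to avoid diverse-but-lowly-expressed contigs
dominating.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import special, stats

from .assembly_model import MultipleAlignment, average_coverage
from .ortholog_annotation import (
    NON_SYNONYMOUS,
    SYNONYMOUS,
    CodingRegion,
    SpeciesHitProfile,
)
from .snp_caller import SnpCall

_EULER_GAMMA = float(np.euler_gamma)


def harmonic(n: int) -> float:
    """The n-th harmonic number ``H_n = sum_{i=1..n} 1/i`` (n >= 1)."""
    if n < 1:
        raise ValueError(f"harmonic number undefined for n={n}")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def beta_stats(
    S: int,
    L: int,
    D: float,
    min_cov: float = 6.0,
    continuous: bool = False,
) -> float | None:
    """One beta value, or ``None`` when undefined.

    ``None`` is returned when ``D < min_cov`` or when ``round(D) - 1 < 1``
    (harmonic number undefined).  ``continuous=True`` replaces the integer
    harmonic number by its digamma generalisation ``psi(D) + gamma`` (a
    sensitivity-analysis switch; the default rounds half-up).
    """
    if S < 0:
        raise ValueError("negative SNP count")
    if L < 1:
        raise ValueError("non-positive length")
    if D < min_cov:
        return None
    if continuous:
        h = float(special.digamma(D)) + _EULER_GAMMA  # == H_{D-1} at integer D
        if h <= 0:
            return None
    else:
        n = _round_half_up(D) - 1
        if n < 1:
            return None
        h = harmonic(n)
    return S / (L * h)


@dataclass
class ContigDiversity:
    """Per-contig SNP counts, lengths, depth and derived beta statistics."""

    contig_id: str
    S_t: int
    S_n: int | None
    S_s: int | None
    L_t: int
    L_c: int | None
    D: float
    beta_t: float | None
    beta_n: float | None
    beta_s: float | None


@dataclass
class DiversitySummary:
    """Mean and median of each beta statistic over contigs where that
    statistic is individually defined (coverage already >= ``min_cov``)."""

    mean_beta_t: float | None
    median_beta_t: float | None
    n_beta_t: int
    mean_beta_n: float | None
    median_beta_n: float | None
    n_beta_n: int
    mean_beta_s: float | None
    median_beta_s: float | None
    n_beta_s: int


def _summarise(values: list[float]) -> tuple[float | None, float | None, int]:
    if not values:
        return None, None, 0
    return statistics.fmean(values), statistics.median(values), len(values)


def diversity_table(
    alignments: Sequence[MultipleAlignment],
    strict_calls: Sequence[SnpCall],
    coding_regions: Mapping[str, CodingRegion] | None = None,
    min_cov: float = 6.0,
    continuous: bool = False,
) -> tuple[list[ContigDiversity], DiversitySummary]:
    """Per-contig diversity rows (coverage >= ``min_cov``) plus summary.

    ``strict_calls`` must be strict-criterion calls with coding classes
    already assigned where annotations exist.  ``beta_n``/``beta_s`` are
    only defined for contigs with a coding region.
    """
    coding_regions = coding_regions or {}
    by_contig: dict[str, list[SnpCall]] = {}
    for call in strict_calls:
        by_contig.setdefault(call.contig_id, []).append(call)

    rows: list[ContigDiversity] = []
    for aln in alignments:
        D = average_coverage(aln)
        if D < min_cov:
            continue
        calls = by_contig.get(aln.contig_id, [])
        S_t = len(calls)
        L_t = aln.unpadded_length
        region = coding_regions.get(aln.contig_id)
        if region is not None and region.length > 0:
            S_n = sum(1 for c in calls if c.coding_class == NON_SYNONYMOUS)
            S_s = sum(1 for c in calls if c.coding_class == SYNONYMOUS)
            L_c = region.length
            beta_n = beta_stats(S_n, L_c, D, min_cov, continuous)
            beta_s = beta_stats(S_s, L_c, D, min_cov, continuous)
        else:
            S_n = S_s = L_c = beta_n = beta_s = None
        rows.append(
            ContigDiversity(
                contig_id=aln.contig_id,
                S_t=S_t,
                S_n=S_n,
                S_s=S_s,
                L_t=L_t,
                L_c=L_c,
                D=D,
                beta_t=beta_stats(S_t, L_t, D, min_cov, continuous),
                beta_n=beta_n,
                beta_s=beta_s,
            )
        )

    mt, dt, nt = _summarise([r.beta_t for r in rows if r.beta_t is not None])
    mn, dn, nn = _summarise([r.beta_n for r in rows if r.beta_n is not None])
    ms, ds, ns = _summarise([r.beta_s for r in rows if r.beta_s is not None])
    summary = DiversitySummary(mt, dt, nt, mn, dn, nn, ms, ds, ns)
    return rows, summary


@dataclass
class CodingRateSummary:
    """Non-synonymous and synonymous SNPs per kb of coding sequence.

    The denominator sums coding-region lengths over unigenes whose coding
    region contains at least one (strict) coding SNP.
    """

    n_non_synonymous: int
    n_synonymous: int
    coding_bp: int
    n_coding_regions_with_snps: int
    non_synonymous_per_kb: float | None
    synonymous_per_kb: float | None


def coding_rate_summary(
    strict_calls: Sequence[SnpCall],
    coding_regions: Mapping[str, CodingRegion],
) -> CodingRateSummary:
    """Coding SNP rates from classified strict calls."""
    coding = [
        c for c in strict_calls
        if c.coding_class in (NON_SYNONYMOUS, SYNONYMOUS)
    ]
    with_snps = {c.contig_id for c in coding}
    bp = sum(
        coding_regions[q].length for q in with_snps if q in coding_regions
    )
    n_non = sum(1 for c in coding if c.coding_class == NON_SYNONYMOUS)
    n_syn = len(coding) - n_non
    return CodingRateSummary(
        n_non_synonymous=n_non,
        n_synonymous=n_syn,
        coding_bp=bp,
        n_coding_regions_with_snps=len(with_snps),
        non_synonymous_per_kb=(1000.0 * n_non / bp) if bp else None,
        synonymous_per_kb=(1000.0 * n_syn / bp) if bp else None,
    )


def beta_hitcount_correlation(
    rows: Sequence[ContigDiversity],
    profiles: Mapping[str, SpeciesHitProfile],
) -> tuple[float, float] | None:
    """Pearson correlation between ``beta_t`` and the number of reference
    databases hit (0..k), with a two-sided t-distributed p-value.

    Returns ``None`` (with a warning-free absence) when fewer than three
    paired observations exist or either variable has zero variance.
    """
    xs, ys = [], []
    for r in rows:
        if r.beta_t is None or r.contig_id not in profiles:
            continue
        xs.append(float(profiles[r.contig_id].n_databases_hit))
        ys.append(r.beta_t)
    if len(xs) < 3:
        return None
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return None
    res = stats.pearsonr(xs, ys)
    return float(res.statistic), float(res.pvalue)
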