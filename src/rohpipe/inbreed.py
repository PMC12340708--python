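"""Genomic inbreeding coefficients from ROH, with bootstrap uncertainty.

F_ROH is the fraction of the autosomal genome covered by ROH at or above a
length threshold (1 Mb for inbreeding over roughly the last 50 generations,
10 Mb for very recent consanguinity).  The denominator is the summed physical
length of the autosomes in the genome layout; an assayable-length alternative
can be supplied explicitly via ``denominator_bp``.

Population means carry 95% nonparametric bootstrap confidence intervals:
individual F_ROH values are resampled with replacement ``n_boot`` times and
the interval is the 2.5% / 97.5% quantiles of the resampled means (linear
interpolation of order statistics, numpy's default convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .rohcall import ROHSegment
from .simgenome import GenomeLayout

__all__ = [
    "FrohEstimate",
    "BootstrapCI",
    "compute_froh",
    "froh_table",
    "bootstrap_mean_ci",
    "froh_depth_regression",
    "cohort_summary",
]


@dataclass(frozen=True)
class FrohEstimate:
    individual: str
    froh_1mb: float
    froh_10mb: float
    mean_depth: float = float("nan")


@dataclass(frozen=True)
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    n_boot: int
    seed: int


def compute_froh(
    segments: Sequence[ROHSegment],
    min_len_bp: int,
    layout: GenomeLayout,
    denominator_bp: int | None = None,
) -> float:
    """Fraction of the genome in segments of at least ``min_len_bp``.

    Segments must be the non-overlapping calls of a single individual; a
    segment extending beyond its chromosome is an error.
    """
    denom = denominator_bp if denominator_bp is not None else layout.total_length
    total = 0
    for seg in segments:
        clen = layout.chrom_lengths.get(seg.chrom)
        if clen is None:
            raise ValueError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.start < 1 or seg.end > clen:
            raise ValueError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} exceeds chromosome bounds"
            )
        if seg.length >= min_len_bp:
            total += seg.length
    froh = total / denom
    if not (0.0 <= froh <= 1.0):
        raise ValueError("F_ROH outside [0, 1]; overlapping segments?")
    return froh


def froh_table(
    segments: Sequence[ROHSegment],
    individuals: Sequence[str],
    layout: GenomeLayout,
    mean_depths: dict[str, float] | None = None,
    thresholds_bp: tuple[int, int] = (1_000_000, 10_000_000),
) -> list[FrohEstimate]:
    """Per-individual F_ROH at both thresholds (individuals with no calls get 0)."""
    by_ind: dict[str, list[ROHSegment]] = {i: [] for i in individuals}
    for seg in segments:
        if seg.individual in by_ind:
            by_ind[seg.individual].append(seg)
    lo, hi = thresholds_bp
    out = []
    for ind in individuals:
        segs = by_ind[ind]
        out.append(
            FrohEstimate(
                individual=ind,
                froh_1mb=compute_froh(segs, lo, layout),
                froh_10mb=compute_froh(segs, hi, layout),
                mean_depth=(mean_depths or {}).get(ind, float("nan")),
            )
        )
    return out


def bootstrap_mean_ci(values: Sequence[float], n_boot: int = 5000, seed: int = 0) -> BootstrapCI:
    """95% percentile bootstrap CI on the mean (deterministic given seed)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    lo, hi = np.quantile(means, [0.025, 0.975])
    return BootstrapCI(float(v.mean()), float(lo), float(hi), n_boot, seed)


def froh_depth_regression(froh: Sequence[float], depths: Sequence[float]) -> tuple[float, float]:
    """OLS of F_ROH on mean read depth; returns (slope, two-sided p).

    A significant slope would indicate that coverage, not ancestry, drives
    the inbreeding estimates.  p from the t distribution with n - 2 df.
    """
    y = np.asarray(froh, dtype=float)
    x = np.asarray(depths, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(x) == 0:
        raise ValueError("depth has zero variance")
    if np.ptp(y) == 0:
        return 0.0, 1.0  # constant response: no association by construction
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue)


def cohort_summary(
    estimates: Sequence[FrohEstimate],
    populations: dict[str, str],
    n_boot: int = 5000,
    seed: int = 0,
) -> dict[str, dict]:
    """Per-population mean F_ROH with bootstrap CIs at both thresholds."""
    out: dict[str, dict] = {}
    for pop in sorted(set(populations.values())):
        members = [e for e in estimates if populations.get(e.individual) == pop]
        if not members:
            continue
        entry = {"n": len(members)}
        for key, attr in (("froh_1mb", "froh_1mb"), ("froh_10mb", "froh_10mb")):
            ci = bootstrap_mean_ci([getattr(e, attr) for e in members], n_boot, seed)
            entry[key] = {"mean": ci.mean, "ci_lower": ci.lower, "ci_upper": ci.upper}
        out[pop] = entry
    return out
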