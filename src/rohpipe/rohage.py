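"""Dating ROH: genetic length, generations to the common ancestor, age bins.

An IBD tract inherited from an ancestor ``g`` generations back has expected
genetic length ``100/(2g)`` cM (recombination whittles tracts down by a factor
2g meioses).  Inverting, a segment of genetic length ``l`` cM is dated as
``g_hat = 50 / l`` generations.  Segments are then binned into six coalescent
age classes and summarized per population as mean Mb per individual per bin,
a profile of inbreeding through time.

Bin convention: edges are half-open ``[0,10), [10,20), [20,30), [30,40),
[40,50), [50,inf)``; a boundary estimate (g_hat exactly 10, 20, ... or 50)
falls in the higher bin, and ``l = 0`` (zero-recombination span) is assigned
to the oldest bin with an infinite g_hat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rohcall import ROHSegment
from .simgenome import GenomeLayout

__all__ = [
    "AGE_BINS",
    "AgedROH",
    "segment_genetic_length",
    "estimate_generations",
    "age_bin_label",
    "age_segments",
    "bin_roh_by_age",
]

AGE_BIN_EDGES = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf)
AGE_BINS = ("<10", "10-20", "20-30", "30-40", "40-50", ">50")


@dataclass(frozen=True)
class AgedROH:
    segment: ROHSegment
    genetic_length_cm: float
    g_hat: float
    bin: str
    clamped: bool = False


def segment_genetic_length(
    layout: GenomeLayout, chrom: str, start: int, end: int
) -> tuple[float, bool]:
    """Genetic length in cM by piecewise-linear map interpolation.

    Coordinates outside the anchor range are clamped to the terminal anchor
    cM (additivity over subdivision still holds); the flag reports whether
    clamping occurred.
    """
    if chrom not in layout.map_anchors:
        raise ValueError(f"no map anchors for chromosome {chrom!r}")
    bp, _ = layout.map_anchors[chrom]
    clamped = start < bp[0] or end > bp[-1]
    l_cm = float(layout.bp_to_cm(chrom, end) - layout.bp_to_cm(chrom, start))
    return max(l_cm, 0.0), bool(clamped)


def estimate_generations(l_cm: float) -> float:
    """Generations to the tract's common ancestor: g_hat = 100/(2 l) = 50/l."""
    if l_cm < 0:
        raise ValueError("genetic length must be >= 0")
    if l_cm == 0.0:
        return float("inf")
    return 50.0 / l_cm


def age_bin_label(g_hat: float) -> str:
    if np.isinf(g_hat) or g_hat >= 50.0:
        return ">50"
    idx = int(np.searchsorted(AGE_BIN_EDGES, g_hat, side="right")) - 1
    return AGE_BINS[idx]


def age_segments(segments: Sequence[ROHSegment], layout: GenomeLayout) -> tuple[list[AgedROH], int]:
    """Date every segment; returns the aged list and the clamp counter."""
    out: list[AgedROH] = []
    n_clamped = 0
    for seg in segments:
        l_cm, clamped = segment_genetic_length(layout, seg.chrom, seg.start, seg.end)
        n_clamped += clamped
        g_hat = estimate_generations(l_cm)
        out.append(AgedROH(seg, l_cm, g_hat, age_bin_label(g_hat), clamped))
    return out, n_clamped


def bin_roh_by_age(
    aged: Sequence[AgedROH],
    populations: dict[str, str],
    individuals: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-population, per-bin Mb in ROH.

    ``mean_mb`` averages each individual's summed physical Mb over the
    individuals of the population (individuals without segments contribute
    zeros); ``pooled_mean_mb`` is the alternative mean over segments pooled
    across the population.  Within each individual the bin sums conserve the
    total Mb in ROH exactly.
    """
    if individuals is None:
        individuals = sorted(populations)
    per_ind = {ind: {b: 0.0 for b in AGE_BINS} for ind in individuals}
    seg_mb: dict[str, dict[str, list[float]]] = {}
    for a in aged:
        ind = a.segment.individual
        if ind not in per_ind:
            continue
        mb = a.segment.length / 1e6
        per_ind[ind][a.bin] += mb
        seg_mb.setdefault(populations[ind], {}).setdefault(a.bin, []).append(mb)

    rows = []
    for pop in sorted(set(populations[i] for i in individuals)):
        members = [i for i in individuals if populations[i] == pop]
        for b in AGE_BINS:
            vals = [per_ind[i][b] for i in members]
            pooled = seg_mb.get(pop, {}).get(b, [])
            rows.append(
                {
                    "population": pop,
                    "bin": b,
                    "mean_mb": float(np.mean(vals)) if vals else 0.0,
                    "pooled_mean_mb": float(np.mean(pooled)) if pooled else 0.0,
                    "total_mb": float(np.sum(vals)),
                    "n_segments": len(pooled),
                }
            )
    return pd.DataFrame(rows)
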