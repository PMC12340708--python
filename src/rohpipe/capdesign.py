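"""Hybridization-capture target design as interval arithmetic.

Targets of fixed length are tiled greedily left-to-right along each
chromosome, keeping an end-to-start gap of at least ``min_gap`` between
consecutive targets and never intersecting the exclusion mask (repeat
intervals plus exons padded by a flank, merged).  A second pass prunes
targets whose empirical mean coverage in a pilot sequencing run is three or
more times the mean on-target coverage, where that mean is computed only
over targets with non-zero coverage (zero-coverage targets reflect low
sequencing effort, not bad probes, and are never pruned).

All intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Target", "TargetSet", "merge_intervals", "select_targets", "prune_high_coverage",
           "read_bed_intervals", "write_bed_intervals"]


@dataclass(frozen=True)
class Target:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    coverage: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TargetSet:
    targets: list[Target] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.targets)

    def validate(self) -> None:
        by_chrom: dict[str, list[Target]] = {}
        for t in self.targets:
            if t.length <= 0:
                raise ValueError("zero-length target")
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            for prev, cur in zip(ts, ts[1:]):
                if cur.start < prev.end:
                    raise ValueError(f"overlapping targets on {chrom}")


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint set."""
    out: list[list[int]] = []
    for s, e in sorted((int(s), int(e)) for s, e in intervals if e > s):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def select_targets(
    chrom_sizes: dict[str, int],
    target_len: int,
    min_gap: int,
    exclusion_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
    exon_intervals: dict[str, Sequence[tuple[int, int]]] | None = None,
    exon_flank: int = 100_000,
) -> TargetSet:
    """Greedy earliest-placement tiling of capture targets.

    On each chromosome, place a target of ``target_len`` at the earliest
    position at least ``min_gap`` past the previous target's end that does
    not intersect the merged mask (exclusions plus exons padded by
    ``exon_flank`` on both sides).  Deterministic; fully masked chromosomes
    simply yield no targets.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    exclusion_intervals = exclusion_intervals or {}
    exon_intervals = exon_intervals or {}

    targets: list[Target] = []
    for chrom, clen in chrom_sizes.items():
        mask = list(exclusion_intervals.get(chrom, []))
        for s, e in exon_intervals.get(chrom, []):
            mask.append((max(0, s - exon_flank), min(clen, e + exon_flank)))
        mask = merge_intervals(mask)
        mstarts = np.array([s for s, _ in mask], dtype=np.int64)
        mends = np.array([e for _, e in mask], dtype=np.int64)

        pos = 0
        while pos + target_len <= clen:
            # first mask interval that could intersect [pos, pos+target_len)
            i = int(np.searchsorted(mends, pos, side="right"))
            if i < len(mstarts) and mstarts[i] < pos + target_len:
                pos = int(mends[i])  # jump past the blocking interval
                continue
            targets.append(Target(chrom, pos, pos + target_len))
            pos += target_len + min_gap
    ts = TargetSet(targets)
    ts.validate()
    return ts


def prune_high_coverage(target_set: TargetSet) -> tuple[TargetSet, float]:
    """Drop targets with coverage >= 3x the mean over targets with coverage > 0.

    Zero-coverage targets are retained and excluded from the mean.  Returns
    the pruned set and the mean used; if every target has zero coverage the
    mean is undefined and nothing is pruned (with a warning).
    """
    ts = target_set.targets
    if not ts:
        return TargetSet([]), float("nan")
    if any(t.coverage is None for t in ts):
        raise ValueError("every target needs a coverage value")
    covs = np.array([t.coverage for t in ts], dtype=float)
    nonzero = covs[covs > 0]
    if nonzero.size == 0:
        warnings.warn("all targets have zero coverage; mean undefined, nothing pruned")
        return TargetSet(list(ts)), float("nan")
    mean_cov = float(nonzero.mean())
    kept = [t for t, c in zip(ts, covs) if c < 3.0 * mean_cov]
    return TargetSet(kept), mean_cov


def read_bed_intervals(path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def write_bed_intervals(target_set: TargetSet, path) -> None:
    with open(path, "w") as fh:
        for t in target_set.targets:
            cov = "" if t.coverage is None else f"\t{t.coverage:g}"
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}{cov}\n")
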