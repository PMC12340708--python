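"""Runs-of-homozygosity detection from genotype likelihoods.

A windowed likelihood-ratio scan.  For each SNP the evidence that the site
lies inside a homozygous-IBD tract is a log10 likelihood ratio (LOD) between
two site models evaluated on the genotype-likelihood triple:

* outside an ROH, genotype probabilities follow Hardy-Weinberg proportions at
  the population alternate-allele frequency ``q``;
* inside an ROH, the two haplotypes are identical by descent: the genotype is
  homozygous for an allele drawn once from the population (hom-ref with
  probability ``p(1-h)``, hom-alt with ``q(1-h)``), heterozygous only with a
  small residual probability ``h`` (mutation since the common ancestor, or
  genotyping error).

Working on likelihoods rather than hard calls keeps low-coverage sites
informative: a site with no reads has a flat triple and a LOD of exactly 0.

Windows of ``window_snps`` consecutive SNPs are slid along each chromosome;
windows whose summed LOD exceeds the threshold are merged (bridging gaps up
to ``merge_gap_bp``), trimmed to their outermost SNPs, and split wherever the
distance between adjacent SNPs exceeds ``max_snp_gap_bp`` (a capture panel
has no information inside large gaps).  Length thresholds (>= 1 Mb, >= 10 Mb)
are applied downstream, not here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simgenome import GenomeLayout  # noqa: F401  (re-exported convenience)
from .variantio import SiteTable, estimate_allele_freq, linear_gl

__all__ = [
    "ROHSegment",
    "ROHCallParams",
    "site_lod",
    "call_roh",
    "call_roh_cohort",
    "population_frequencies",
    "write_roh_bed",
    "read_roh_bed",
]


@dataclass(frozen=True)
class ROHSegment:
    """A called homozygous-IBD segment (1-based inclusive span)."""

    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int
    lod: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(kw_only=True)
class ROHCallParams:
    """Scan parameters; defaults target capture-density panels (~50 kb/SNP)."""

    window_snps: int = 25
    window_step: int = 5
    residual_het: float = 0.001
    lod_threshold: float = 0.0
    merge_gap_bp: int = 100_000
    max_snp_gap_bp: int = 500_000
    min_pop_size: int = 4   # below this, fall back to global allele frequencies

    def __post_init__(self) -> None:
        if self.window_snps < 5:
            raise ValueError("window_snps must be >= 5")
        if not (1 <= self.window_step <= self.window_snps):
            raise ValueError("window_step must be in [1, window_snps]")
        if not np.isfinite(self.lod_threshold):
            raise ValueError("lod_threshold must be finite")


def site_lod(gl_log10: np.ndarray, q, h: float = 0.001) -> np.ndarray:
    """Per-site log10 likelihood ratio of the IBD model over the HWE model.

    ``gl_log10`` has shape (..., 3); ``q`` broadcasts against the leading
    dimensions.  Flat triples give exactly 0.  ``q`` must lie strictly inside
    (0, 1); boundary frequencies carry no information and must be excluded by
    the caller.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0.0) | (q >= 1.0)):
        raise ValueError("allele frequency must be in (0, 1)")
    L = linear_gl(np.asarray(gl_log10, dtype=float))
    p = 1.0 - q
    l_out = L[..., 0] * p**2 + L[..., 1] * 2 * p * q + L[..., 2] * q**2
    l_in = L[..., 0] * p * (1 - h) + L[..., 1] * h + L[..., 2] * q * (1 - h)
    return np.log10(l_in) - np.log10(l_out)


def _scan_chromosome(
    pos: np.ndarray, lod: np.ndarray, params: ROHCallParams
) -> list[tuple[int, int]]:
    """Return (first_snp_idx, last_snp_idx) runs of merged flagged windows."""
    n = len(pos)
    W, step = params.window_snps, params.window_step
    if n < W:
        return []
    csum = np.concatenate([[0.0], np.cumsum(lod)])
    starts = np.arange(0, n - W + 1, step)
    sums = csum[starts + W] - csum[starts]
    flagged = starts[sums > params.lod_threshold]
    if len(flagged) == 0:
        return []
    regions: list[list[int]] = []
    for s in flagged:
        e = s + W - 1
        if regions and (s <= regions[-1][1] or pos[s] - pos[regions[-1][1]] <= params.merge_gap_bp):
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    # split runs at large inter-SNP gaps
    out: list[tuple[int, int]] = []
    for s, e in regions:
        gaps = np.nonzero(np.diff(pos[s : e + 1]) > params.max_snp_gap_bp)[0]
        cut = s
        for g in gaps:
            out.append((cut, s + g))
            cut = s + g + 1
        out.append((cut, e))
    # trim segment edges: merged window spans overhang a few SNPs past the
    # homozygous tract, so peel off the worst-scoring prefix and suffix while
    # keeping at least window_snps SNPs in the segment
    refined = [_trim_edges(lod, s, e, params.window_snps) for s, e in out]
    return [(s, e) for s, e in refined if e - s + 1 >= params.window_snps]


def _trim_edges(lod: np.ndarray, s: int, e: int, min_snps: int) -> tuple[int, int]:
    """Drop the minimum-sum prefix and suffix of ``lod[s..e]``.

    The new start follows the deepest non-positive prefix-sum minimum (and
    symmetrically for the end), subject to retaining ``min_snps`` SNPs.
    """
    budget = (e - s + 1) - min_snps
    if budget <= 0:
        return s, e
    prefix = np.concatenate([[0.0], np.cumsum(lod[s : e + 1])])
    # left trim: largest i (within budget) minimizing the prefix sum, if <= 0
    lim = budget + 1
    i_min = int(np.argmin(prefix[:lim]))
    t_l = i_min if prefix[i_min] <= 0 else 0
    budget -= t_l
    suffix = np.concatenate([[0.0], np.cumsum(lod[s : e + 1][::-1])])
    j_min = int(np.argmin(suffix[: budget + 1]))
    t_r = j_min if suffix[j_min] <= 0 else 0
    return s + t_l, e - t_r


def call_roh(
    chrom: np.ndarray,
    pos: np.ndarray,
    gl_log10: np.ndarray,
    freqs: np.ndarray,
    params: ROHCallParams | None = None,
    individual: str = "ind",
) -> tuple[list[ROHSegment], dict[str, int]]:
    """Call ROH segments for one individual across chromosomes.

    ``gl_log10`` is (S, 3); ``freqs`` the per-site alternate allele frequency.
    Sites with boundary frequencies (q of 0 or 1, or undefined) are dropped
    from the scan and counted.  Returns the segments plus a counter dict
    (``skipped_sites``, ``short_chromosomes``).
    """
    params = params or ROHCallParams()
    pos = np.asarray(pos)
    freqs = np.asarray(freqs, dtype=float)
    info = {"skipped_sites": 0, "short_chromosomes": 0}
    usable = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    info["skipped_sites"] = int((~usable).sum())
    segments: list[ROHSegment] = []
    for cname in dict.fromkeys(np.asarray(chrom).tolist()):
        m = (chrom == cname) & usable
        if m.sum() < params.window_snps:
            info["short_chromosomes"] += 1
            continue
        cpos = pos[m]
        order = np.argsort(cpos, kind="mergesort")
        cpos = cpos[order]
        lod = site_lod(gl_log10[m][order], freqs[m][order], params.residual_het)
        for s, e in _scan_chromosome(cpos, lod, params):
            segments.append(
                ROHSegment(
                    individual=individual,
                    chrom=str(cname),
                    start=int(cpos[s]),
                    end=int(cpos[e]),
                    n_snps=int(e - s + 1),
                    lod=float(lod[s : e + 1].sum()),
                )
            )
    return segments, info


def population_frequencies(
    table: SiteTable,
    populations: dict[str, str],
    min_pop_size: int = 4,
) -> dict[str, np.ndarray]:
    """Per-population EM allele frequencies with a small-cohort fallback.

    The HWE baseline of the ROH likelihood should reflect the mating pool of
    the focal individual, so frequencies are estimated within each assigned
    population; populations smaller than ``min_pop_size`` fall back to the
    whole-cohort estimate.
    """
    q_global, global_missing = estimate_allele_freq(table)
    q_global = np.where(global_missing, np.nan, q_global)
    out: dict[str, np.ndarray] = {}
    pops = sorted(set(populations.values()))
    for pop in pops:
        members = [s for s in table.samples if populations.get(s) == pop]
        if len(members) < min_pop_size:
            out[pop] = q_global
            continue
        q, miss = estimate_allele_freq(table, table.sample_indices(members))
        out[pop] = np.where(miss, np.nan, q)
    return out


def call_roh_cohort(
    table: SiteTable,
    populations: dict[str, str],
    params: ROHCallParams | None = None,
) -> tuple[list[ROHSegment], dict[str, int]]:
    """Call ROH for every individual in the table."""
    params = params or ROHCallParams()
    freqs = population_frequencies(table, populations, params.min_pop_size)
    default_pop = next(iter(freqs)) if freqs else None
    all_segments: list[ROHSegment] = []
    totals = {"skipped_sites": 0, "short_chromosomes": 0}
    for i, name in enumerate(table.samples):
        pop = populations.get(name, default_pop)
        segs, info = call_roh(
            table.chrom, table.pos, table.gl[:, i], freqs[pop], params, individual=name
        )
        all_segments.extend(segs)
        for k in totals:
            totals[k] += info[k]
    return all_segments, totals


def write_roh_bed(segments: Sequence[ROHSegment], path) -> None:
    """Export as BED (0-based half-open): chrom, start, end, individual, LOD, n_snps."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.individual}\t{s.lod:.3f}\t{s.n_snps}\n")


def read_roh_bed(path) -> list[ROHSegment]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                ROHSegment(
                    individual=f[3], chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                    lod=float(f[4]) if len(f) > 4 else 0.0,
                    n_snps=int(f[5]) if len(f) > 5 else 0,
                )
            )
    return out
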