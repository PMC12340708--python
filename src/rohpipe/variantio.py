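"""VCF/BED/linkage-map IO and the SNP filtering ladder.

The in-memory unit is :class:`SiteTable`: biallelic SNPs with, per individual,
allelic read counts and a log10 genotype-likelihood triple normalized so the
best genotype has value 0.  VCF 4.2 is read through cyvcf2 (accepting GL or
PL; PL is converted to log10 likelihoods as -PL/10) and written as plain text
with FORMAT ``GT:AD:DP:GQ:GL`` (GT left missing: calls downstream are made
from likelihoods, not from the file).

The site-filter ladder mirrors a VCFtools-style command: genotype-quality
masking of individual calls first, then per-site drops in a fixed order
(biallelic, missingness, mean depth minimum, mean depth maximum, minor allele
frequency, Hardy-Weinberg exact test) so that every rejected site is
attributed to exactly one rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SiteTable",
    "FilterConfig",
    "write_vcf",
    "read_vcf",
    "estimate_allele_freq",
    "call_genotypes",
    "hwe_exact_test",
    "apply_site_filters",
    "filter_individuals_by_depth",
    "subsample_sites",
    "read_linkage_map",
]

FILTER_ORDER = ("biallelic", "missing", "depth_min", "depth_max", "maf", "hwe")


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Biallelic SNP panel with per-individual read counts and GL triples."""

    samples: list[str]
    chrom: np.ndarray          # (S,) object
    pos: np.ndarray            # (S,) int64, 1-based
    ref: np.ndarray            # (S,) object
    alt: np.ndarray            # (S,) object
    ad_ref: np.ndarray         # (S, N) int
    ad_alt: np.ndarray         # (S, N) int
    gl: np.ndarray             # (S, N, 3) float, log10, max 0 per triple
    n_alleles: np.ndarray = field(default=None)  # (S,) total alleles in source record

    def __post_init__(self) -> None:
        if self.n_alleles is None:
            self.n_alleles = np.full(self.n_sites, 2, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        return self.ad_ref + self.ad_alt

    @property
    def site_mean_depth(self) -> np.ndarray:
        return self.depth.mean(axis=1) if self.n_samples else np.zeros(self.n_sites)

    @property
    def gq(self) -> np.ndarray:
        """Phred-scaled confidence in the best genotype (0 where data absent)."""
        second = np.partition(self.gl, -2, axis=2)[:, :, -2]
        gq = np.minimum(np.rint(-10.0 * second), 99).astype(np.int32)
        gq[self.depth == 0] = 0
        gq[np.ptp(self.gl, axis=2) == 0] = 0
        return gq

    def take_sites(self, index) -> "SiteTable":
        idx = np.asarray(index)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            gl=self.gl[idx],
            n_alleles=self.n_alleles[idx],
        )

    def take_samples(self, names: Sequence[str]) -> "SiteTable":
        idx = [self.samples.index(n) for n in names]
        return replace(
            self,
            samples=list(names),
            ad_ref=self.ad_ref[:, idx],
            ad_alt=self.ad_alt[:, idx],
            gl=self.gl[:, idx],
        )

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.samples.index(n) for n in names], dtype=int)


# ---------------------------------------------------------------------------
# VCF IO
# ---------------------------------------------------------------------------

def write_vcf(table: SiteTable, path, contigs: dict[str, int] | None = None) -> None:
    """Write the table as VCF 4.2 text (GT missing, AD/DP/GQ/GL populated)."""
    gq = table.gq
    depth = table.depth
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohpipe\n")
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in dict.fromkeys(table.chrom.tolist()):
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,Description="log10 genotype likelihoods">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples) + "\n")
        for s in range(table.n_sites):
            info = f"DP={int(depth[s].sum())}"
            fields = [
                str(table.chrom[s]), str(int(table.pos[s])), ".",
                str(table.ref[s]), str(table.alt[s]), ".", "PASS", info,
                "GT:AD:DP:GQ:GL",
            ]
            for i in range(table.n_samples):
                gl = table.gl[s, i]
                fields.append(
                    "./.:%d,%d:%d:%d:%.4f,%.4f,%.4f"
                    % (table.ad_ref[s, i], table.ad_alt[s, i], depth[s, i], gq[s, i], gl[0], gl[1], gl[2])
                )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path) -> SiteTable:
    """Read a VCF (GL or PL) into a :class:`SiteTable`.

    Multi-allelic records are retained with ``n_alleles > 2`` (first ALT's
    data kept) so the biallelic filter can count them; the filter ladder is
    where they are dropped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, nall = [], [], [], [], []
    ad_ref, ad_alt, gls = [], [], []
    n = len(samples)
    for v in vcf:
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0] if v.ALT else ".")
        nall.append(1 + len(v.ALT))
        ad = v.format("AD")
        if ad is None:
            dp = v.format("DP")
            dp = np.zeros(n, dtype=np.int32) if dp is None else dp.reshape(n, -1)[:, 0]
            aref = np.maximum(dp, 0)
            aalt = np.zeros(n, dtype=np.int32)
        else:
            ad = ad.reshape(n, -1)
            aref = np.maximum(ad[:, 0], 0)
            aalt = np.maximum(ad[:, 1], 0) if ad.shape[1] > 1 else np.zeros(n, dtype=np.int32)
        ad_ref.append(aref)
        ad_alt.append(aalt)
        gl = v.format("GL")
        if gl is not None:
            g = np.asarray(gl, dtype=float).reshape(n, -1)[:, :3]
        else:
            pl = v.format("PL")
            if pl is None:
                g = np.zeros((n, 3))
            else:
                g = -np.asarray(pl, dtype=float).reshape(n, -1)[:, :3] / 10.0
        g = g - g.max(axis=1, keepdims=True)
        gls.append(g)
    vcf.close()
    return SiteTable(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        ad_ref=np.array(ad_ref, dtype=np.int32) if chrom else np.empty((0, n), dtype=np.int32),
        ad_alt=np.array(ad_alt, dtype=np.int32) if chrom else np.empty((0, n), dtype=np.int32),
        gl=np.array(gls) if chrom else np.empty((0, n, 3)),
        n_alleles=np.array(nall, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# Allele frequencies and genotype calls from likelihoods
# ---------------------------------------------------------------------------

def linear_gl(gl_log10: np.ndarray) -> np.ndarray:
    return np.power(10.0, gl_log10)


def missing_mask(table: SiteTable) -> np.ndarray:
    """(S, N) True where an individual has no usable data at a site."""
    flat = np.ptp(table.gl, axis=2) == 0
    return (table.depth == 0) | flat


def estimate_allele_freq(
    table: SiteTable,
    sample_idx: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """EM estimate of the alternate-allele frequency per site from GLs.

    Iterates ``q <- sum_i E[g_i | GL_i, q] / (2N)`` under a Hardy-Weinberg
    prior to convergence ``tol``.  Returns ``(q, all_missing)``: sites where
    no individual has data keep the initialization value 0.5 and are flagged.
    """
    gl = table.gl if sample_idx is None else table.gl[:, sample_idx]
    if gl.shape[1] == 0:
        raise ValueError("need at least one individual")
    L = linear_gl(gl)  # (S, N, 3)
    miss = np.ptp(gl, axis=2) == 0
    n_eff = (~miss).sum(axis=1)
    q = np.full(gl.shape[0], 0.5)
    dose = np.array([0.0, 1.0, 2.0])
    for _ in range(max_iter):
        prior = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)  # (S,3)
        w = L * prior[:, None, :]
        denom = w.sum(axis=2, keepdims=True)
        post = np.divide(w, denom, out=np.full_like(w, 1.0 / 3.0), where=denom > 0)
        eg = post @ dose  # (S, N)
        q_new = eg.mean(axis=1) / 2.0
        delta = np.abs(q_new - q).max() if len(q) else 0.0
        q = q_new
        if delta < tol:
            break
    all_missing = n_eff == 0
    q = np.where(all_missing, 0.5, q)
    return q, all_missing


def call_genotypes(table: SiteTable, gq_min: int | None = None) -> np.ndarray:
    """Maximum-likelihood genotype calls (flat prior); -1 where missing.

    With ``gq_min`` set, calls whose phred-scaled margin over the runner-up
    genotype is below the threshold are masked to -1 (VCFtools --minGQ
    semantics).
    """
    calls = table.gl.argmax(axis=2).astype(np.int8)
    miss = missing_mask(table)
    if gq_min is not None:
        miss = miss | (table.gq < gq_min)
    calls[miss] = -1
    return calls


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed that of the observed
    count.  Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("need at least one individual")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hets = hets[(n_minor - hets) % 2 == 0]
    hets = hets[hets <= 2 * n - n_minor]
    lg = math.lgamma
    # log P(h) = log[ n! / (a! h! c!) * 2^h ] + log[ n1! (2n-n1)! / (2n)! ]
    const = lg(n + 1) + lg(n_minor + 1) + lg(2 * n - n_minor + 1) - lg(2 * n + 1)
    a = (n_minor - hets) // 2
    c = n - a - hets
    logp = const + hets * math.log(2.0) - gammaln(a + 1) - gammaln(hets + 1) - gammaln(c + 1)
    logp_obs = logp[hets == n_Aa]
    if len(logp_obs) == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = np.exp(logp - logp.max())
    p /= p.sum()
    p_obs = float(p[hets == n_Aa][0])
    return float(min(1.0, p[p <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Filter ladder
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class FilterConfig:
    """Thresholds of the site/individual filtering ladder."""

    maf_min: float = 0.05
    gq_min: int = 20
    site_mean_depth_min: float = 10.0
    max_missing: float = 0.85          # min fraction of individuals with data
    hwe_p_min: float = 0.001
    site_mean_depth_max: float = 24.0
    individual_mean_depth_min: float = 5.0

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must be in [0, 1]")
        if not (0 <= self.hwe_p_min <= 1):
            raise ValueError("hwe_p_min must be in [0, 1]")
        if self.site_mean_depth_min > self.site_mean_depth_max:
            raise ValueError("site mean-depth bounds inverted")


def apply_site_filters(
    table: SiteTable, config: FilterConfig | None = None
) -> tuple[SiteTable, dict[str, int]]:
    """Apply the site filter ladder; attribute each drop to its first failure.

    Genotype-quality masking (depth 0, flat GL, or GQ below ``gq_min``) is
    applied to individual calls before any per-site rule, so it feeds the
    missingness, MAF and HWE computations.  Site mean depth uses the raw read
    depths (masking hides genotypes, not reads).  Returns the surviving table
    (order preserved, likelihood data intact) and the per-filter tally.
    """
    config = config or FilterConfig()
    tally = {k: 0 for k in FILTER_ORDER}
    if table.n_sites == 0:
        return table, tally

    masked = missing_mask(table) | (table.gq < config.gq_min)
    frac_present = 1.0 - masked.mean(axis=1)
    mean_depth = table.site_mean_depth

    # EM allele frequencies over unmasked individuals only
    gl_masked = table.gl.copy()
    gl_masked[masked] = 0.0  # flat -> contributes the HWE prior mean only
    tmp = replace(table, gl=gl_masked)
    q, all_missing = estimate_allele_freq(tmp)
    maf = np.minimum(q, 1.0 - q)
    maf[all_missing] = 0.0

    calls = call_genotypes(table)
    calls = np.where(masked, -1, calls)

    keep = np.ones(table.n_sites, dtype=bool)
    reason = np.full(table.n_sites, "", dtype=object)

    def drop(mask: np.ndarray, name: str) -> None:
        fresh = mask & keep
        reason[fresh] = name
        keep[fresh] = False
        tally[name] += int(fresh.sum())

    drop(table.n_alleles != 2, "biallelic")
    drop(frac_present < config.max_missing, "missing")
    drop(mean_depth < config.site_mean_depth_min, "depth_min")
    drop(mean_depth > config.site_mean_depth_max, "depth_max")
    drop(maf < config.maf_min, "maf")
    hwe_fail = np.zeros(table.n_sites, dtype=bool)
    if config.hwe_p_min > 0:  # p-values are strictly positive
        for s in np.nonzero(keep)[0]:
            c = calls[s]
            n_aa = int((c == 0).sum())
            n_ab = int((c == 1).sum())
            n_bb = int((c == 2).sum())
            if n_aa + n_ab + n_bb == 0:
                continue
            if hwe_exact_test(n_aa, n_ab, n_bb) < config.hwe_p_min:
                hwe_fail[s] = True
    drop(hwe_fail, "hwe")

    return table.take_sites(np.nonzero(keep)[0]), tally


def filter_individuals_by_depth(
    table: SiteTable, min_mean_depth: float = 5.0
) -> tuple[SiteTable, list[str], np.ndarray]:
    """Drop individuals whose genome-wide mean read depth is below threshold.

    The mean is taken over all sites with missing entries counting zero reads.
    Raises if no individual survives.
    """
    if table.n_sites == 0:
        raise ValueError("need at least one site")
    means = table.depth.mean(axis=0)
    keep = means >= min_mean_depth
    if not keep.any():
        raise ValueError("all individuals removed by the mean-depth filter")
    kept = [s for s, k in zip(table.samples, keep) if k]
    return table.take_samples(kept), kept, means


def subsample_sites(table: SiteTable, n_target: int, seed: int) -> SiteTable:
    """Uniformly prune the panel to ``n_target`` sites (position order kept)."""
    if n_target > table.n_sites:
        raise ValueError("n_target exceeds the number of sites")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(table.n_sites, size=n_target, replace=False))
    return table.take_sites(idx)


# ---------------------------------------------------------------------------
# Linkage map
# ---------------------------------------------------------------------------

def read_linkage_map(path, chrom_lengths: dict[str, int] | None = None):
    """Read a TSV linkage map (chrom, position bp, cumulative cM) into a layout.

    Rows are sorted by position within chromosome before validation; a
    decreasing cM value is rejected with the offending line named.  Chromosome
    lengths default to the last anchor position.
    """
    import pandas as pd

    from .simgenome import GenomeLayout

    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 3:
        raise ValueError("linkage map needs >= 3 columns: chrom, pos_bp, cM")
    df.columns = ["chrom", "pos_bp", "cm"] + list(df.columns[3:])
    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    names: list[str] = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos_bp", kind="mergesort")
        bp = grp["pos_bp"].to_numpy(dtype=float)
        cm = grp["cm"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(cm) < 0)[0]
        if len(bad):
            row = grp.index[bad[0] + 1]
            raise ValueError(
                f"linkage map not monotone: cM decreases on chromosome {chrom} "
                f"at input line {row + 2}"
            )
        if np.any(np.diff(bp) <= 0):
            raise ValueError(f"duplicate bp positions on chromosome {chrom}")
        anchors[str(chrom)] = (bp, cm)
        names.append(str(chrom))
    lengths = chrom_lengths or {c: int(anchors[c][0][-1]) for c in names}
    return GenomeLayout(tuple(names), lengths, anchors)
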