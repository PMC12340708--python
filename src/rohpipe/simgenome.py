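"""Synthetic cohorts with planted identity-by-descent tracts of known coalescent age.

The generator emulates the data regime of a hybridization-capture SNP panel on a
canid-like genome: 38 autosomes, a sparse panel (~1 SNP per 20-100 kb), shallow
shotgun coverage (Poisson mean read depth ~10) and per-read base error, with
genotypes reported only as genotype likelihoods.

The inbreeding signal is tract-based: for an ancestor ``g`` generations back, the
genetic length of a surviving IBD tract is drawn Exponential with mean
``100/(2g)`` cM, converted to physical coordinates through the linkage map and
placed uniformly on the genome.  Inside a planted tract the two haplotypes are
identical (heterozygous only with a small residual probability ``h``); outside,
genotypes follow Hardy-Weinberg proportions at the site's population allele
frequency.  Population divergence follows the Balding-Nichols model, so the
expected Weir-Cockerham F_ST between populations equals the divergence
parameter ``F_div``.

Because tracts are sampled directly from the age distribution (rather than run
through a pedigree/recombination simulation), the truth set is exact: every
downstream stage (ROH calling, F_ROH, tract dating, diversity) can be scored
against known segments and known genotypes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenomeLayout",
    "SimConfig",
    "PlantedROH",
    "SimResult",
    "plant_roh",
    "simulate_site_reads",
    "simulate_cohort",
    "write_truth_bed",
    "read_truth_bed",
    "write_populations",
    "read_populations",
]


# ---------------------------------------------------------------------------
# Genome frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Named autosomes with physical lengths and a linkage map.

    ``map_anchors`` maps each chromosome to a pair of parallel arrays
    ``(pos_bp, cum_cM)``: positions strictly increasing, cumulative genetic
    position non-decreasing.  Genetic <-> physical conversion is piecewise
    linear between anchors and clamped outside them.  This is the single
    source of truth for the F_ROH denominator and for cM interpolation used
    both when planting tracts and when dating called segments.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    map_anchors: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.chrom_names:
            raise ValueError("empty genome layout")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name, 0)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if name not in self.map_anchors:
                raise ValueError(f"chromosome {name!r} has no map anchors")
            bp, cm = self.map_anchors[name]
            if len(bp) < 2:
                raise ValueError(f"chromosome {name!r} needs >= 2 map anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map anchors for {name!r} not strictly increasing in bp")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"map anchors for {name!r} decreasing in cM")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths[c] for c in self.chrom_names))

    def bp_to_cm(self, chrom: str, bp) -> np.ndarray | float:
        pos, cm = self.map_anchors[chrom]
        return np.interp(bp, pos, cm)

    def cm_to_bp(self, chrom: str, cm_val) -> np.ndarray | float:
        pos, cm = self.map_anchors[chrom]
        return np.interp(cm_val, cm, pos)

    @classmethod
    def uniform(
        cls,
        n_chrom: int = 38,
        chrom_length_bp: int = 60_000_000,
        cm_per_mb: float = 1.0,
        prefix: str = "chr",
    ) -> "GenomeLayout":
        """Equal-length autosomes with a constant recombination rate."""
        names = tuple(f"{prefix}{i + 1}" for i in range(n_chrom))
        lengths = {n: int(chrom_length_bp) for n in names}
        anchors = {}
        for n in names:
            bp = np.array([0.0, float(chrom_length_bp)])
            cm = np.array([0.0, chrom_length_bp / 1e6 * cm_per_mb])
            anchors[n] = (bp, cm)
        return cls(names, lengths, anchors)


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

@dataclass(kw_only=True)
class SimConfig:
    """Study conditions for one simulated cohort.

    ``roh_age_spec`` is a list of ``(g, fraction)`` pairs: each inbred
    individual carries IBD tracts from ancestors ``g`` generations back
    covering in expectation the given fraction of the genome.  ``n_outbred``
    individuals per population carry no tracts (controls).  ``depth_mean``
    may be a scalar or a per-individual sequence (to decouple coverage from
    inbreeding in diagnostics).
    """

    seed: int
    n_individuals: int | Sequence[int] = 10
    n_populations: int = 1
    n_outbred: int = 0
    f_div: float = 0.0
    beta_a: float = 0.5
    beta_b: float = 0.5
    freq_min: float = 0.05
    freq_max: float = 0.95
    snp_spacing_bp: float = 50_000.0
    depth_mean: float | Sequence[float] = 10.0
    error_rate: float = 0.01
    roh_age_spec: Sequence[tuple[float, float]] = field(default_factory=tuple)
    residual_het: float = 0.001

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 < self.error_rate < 0.5):
            raise ValueError("error_rate must be in (0, 0.5)")
        if not (0.0 <= self.residual_het < 0.5):
            raise ValueError("residual_het must be in [0, 0.5)")
        fracs = [f for _, f in self.roh_age_spec]
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1.0:
            raise ValueError("age-spec fractions must lie in [0,1] and sum <= 1")
        if any(g <= 0 for g, _ in self.roh_age_spec):
            raise ValueError("tract ages must be positive")
        if not (0 <= self.freq_min < self.freq_max <= 1):
            raise ValueError("invalid allele-frequency truncation bounds")

    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_individuals, int):
            return [self.n_individuals] * self.n_populations
        sizes = list(self.n_individuals)
        if len(sizes) != self.n_populations:
            raise ValueError("n_individuals sequence length != n_populations")
        return sizes


@dataclass(frozen=True)
class PlantedROH:
    """A truth homozygous-IBD tract (1-based inclusive physical span)."""

    individual: str
    chrom: str
    start: int
    end: int
    true_g: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimResult:
    """Everything a downstream stage or an oracle needs from one simulation."""

    table: "SiteTable"  # noqa: F821 - variantio.SiteTable
    truth: list[PlantedROH]
    populations: dict[str, str]
    true_genotypes: np.ndarray  # (n_sites, n_individuals) in {0,1,2}
    ancestral_freq: np.ndarray  # (n_sites,)
    pop_freq: np.ndarray  # (n_sites, n_populations)


# ---------------------------------------------------------------------------
# Planting IBD tracts
# ---------------------------------------------------------------------------

def plant_roh(
    layout: GenomeLayout,
    age_spec: Sequence[tuple[float, float]],
    rng: np.random.Generator | int,
    individual: str = "ind",
    max_failures: int = 5000,
) -> list[PlantedROH]:
    """Plant non-overlapping IBD tracts for one individual.

    For each ``(g, fraction)`` class, tracts with genetic length
    Exponential(mean ``50/g`` cM) are placed uniformly (chromosome chosen
    proportional to physical length) until the summed physical length reaches
    ``fraction *`` genome size.  Overlaps with already-placed tracts are
    resolved by rejection; tracts truncated at a chromosome end keep their
    realized (shorter) span.  Raises ``RuntimeError`` after ``max_failures``
    consecutive rejections (infeasible fill).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    fracs = [f for _, f in age_spec]
    if sum(fracs) > 0.9:
        raise ValueError("age-spec fractions must sum <= 0.9 to remain placeable")

    names = list(layout.chrom_names)
    lengths = np.array([layout.chrom_lengths[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    total = layout.total_length

    # per-chromosome sorted interval bookkeeping for overlap rejection
    starts: dict[str, list[int]] = {c: [] for c in names}
    ends: dict[str, list[int]] = {c: [] for c in names}
    out: list[PlantedROH] = []

    for g, fraction in age_spec:
        target = fraction * total
        planted = 0.0
        failures = 0
        while planted < target:
            ci = int(rng.choice(len(names), p=probs))
            chrom = names[ci]
            clen = int(lengths[ci])
            l_cm = rng.exponential(50.0 / g)
            start = int(rng.integers(1, clen + 1))
            end = int(round(float(layout.cm_to_bp(chrom, layout.bp_to_cm(chrom, start) + l_cm))))
            end = min(max(end, start), clen)
            # rejection on overlap with any existing tract of this individual
            i = bisect.bisect_right(starts[chrom], end)
            overlaps = i > 0 and ends[chrom][i - 1] >= start
            if not overlaps and i < len(starts[chrom]):
                overlaps = starts[chrom][i] <= end
            if overlaps:
                failures += 1
                if failures >= max_failures:
                    raise RuntimeError(
                        f"could not place ROH for {individual} (g={g}): "
                        f"{failures} consecutive rejections at fill "
                        f"{planted / total:.3f} of target {fraction:.3f}"
                    )
                continue
            failures = 0
            bisect.insort(starts[chrom], start)
            ends[chrom].insert(bisect.bisect_left(starts[chrom], start), end)
            out.append(PlantedROH(individual, chrom, start, end, float(g)))
            planted += end - start + 1
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# Read and genotype-likelihood simulation
# ---------------------------------------------------------------------------

def genotype_likelihoods(alt_counts: np.ndarray, depths: np.ndarray, error_rate: float) -> np.ndarray:
    """log10 genotype likelihoods (hom-ref, het, hom-alt), normalized to max 0.

    Per-read alternate-allele probability is ``error_rate`` for hom-ref, 1/2
    for het and ``1 - error_rate`` for hom-alt; the likelihood is binomial in
    the alternate read count.  Zero-depth entries get a flat triple.
    """
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    alt = np.asarray(alt_counts)
    dep = np.asarray(depths)
    p = np.array([error_rate, 0.5, 1.0 - error_rate])
    with np.errstate(divide="ignore"):
        ll = stats.binom.logpmf(alt[..., None], dep[..., None], p) / np.log(10.0)
    ll = ll - ll.max(axis=-1, keepdims=True)
    ll[dep == 0] = 0.0
    return ll


def simulate_site_reads(
    true_genotype: int,
    depth: int,
    error_rate: float,
    rng: np.random.Generator | int,
) -> tuple[int, int, np.ndarray]:
    """Simulate one individual's pileup at one biallelic site.

    Returns ``(ref_count, alt_count, GL)`` with the GL triple log10-scaled and
    normalized so the maximum is 0.  ``depth == 0`` yields a flat triple (the
    site is missing for this individual).
    """
    if true_genotype not in (0, 1, 2):
        raise ValueError("true_genotype must be 0, 1 or 2")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p_alt = (error_rate, 0.5, 1.0 - error_rate)[true_genotype]
    alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
    gl = genotype_likelihoods(np.array(alt), np.array(depth), error_rate)
    return depth - alt, alt, gl


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Beta(a, b) truncated to [lo, hi] via inverse-CDF sampling."""
    u = rng.random(size)
    flo, fhi = stats.beta.cdf([lo, hi], a, b)
    return stats.beta.ppf(flo + u * (fhi - flo), a, b)


def simulate_cohort(config: SimConfig, layout: GenomeLayout) -> SimResult:
    """Simulate a multi-population cohort on the given genome frame.

    Deterministic given ``config.seed``.  Sites are laid along each chromosome
    with inter-SNP gaps uniform in [0.5, 1.5] x mean spacing (capture panels
    tile the genome fairly regularly).  Returns the genotype-likelihood site
    table together with the exact truth: planted tracts, true genotypes, and
    the drawn allele frequencies.
    """
    from .variantio import SiteTable  # deferred: variantio owns the container

    rng = np.random.default_rng(config.seed)
    pop_sizes = config.pop_sizes()
    pop_names = [f"pop{i + 1}" for i in range(config.n_populations)]

    samples: list[str] = []
    populations: dict[str, str] = {}
    inbred: list[bool] = []
    for pname, size in zip(pop_names, pop_sizes):
        for j in range(size + config.n_outbred):
            name = f"{pname}_i{j + 1:02d}"
            samples.append(name)
            populations[name] = pname
            inbred.append(j < size)
    n_ind = len(samples)

    depth_means = config.depth_mean
    if np.isscalar(depth_means):
        depth_means = np.full(n_ind, float(depth_means))
    else:
        depth_means = np.asarray(depth_means, dtype=float)
        if depth_means.shape != (n_ind,):
            raise ValueError("per-individual depth_mean length mismatch")

    # --- site positions -----------------------------------------------------
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for cname in layout.chrom_names:
        clen = layout.chrom_lengths[cname]
        n_max = int(clen / (0.5 * config.snp_spacing_bp)) + 2
        gaps = config.snp_spacing_bp * (0.5 + rng.random(n_max))
        pos = np.cumsum(gaps)
        pos = pos[pos <= clen].astype(np.int64)
        chroms.extend([cname] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    chrom_all = np.array(chroms, dtype=object)
    n_sites = len(pos_all)

    # --- allele frequencies -------------------------------------------------
    anc = _truncated_beta(rng, config.beta_a, config.beta_b, config.freq_min, config.freq_max, n_sites)
    if config.f_div > 0 and config.n_populations >= 1:
        fd = config.f_div
        a = anc * (1 - fd) / fd
        b = (1 - anc) * (1 - fd) / fd
        pop_freq = np.column_stack(
            [rng.beta(a, b) for _ in range(config.n_populations)]
        )
    else:
        pop_freq = np.tile(anc[:, None], (1, config.n_populations))

    # --- truth tracts and genotypes ----------------------------------------
    truth: list[PlantedROH] = []
    geno = np.empty((n_sites, n_ind), dtype=np.int8)
    chrom_slices: dict[str, slice] = {}
    off = 0
    for cname, pos in zip(layout.chrom_names, positions):
        chrom_slices[cname] = slice(off, off + len(pos))
        off += len(pos)

    for idx, name in enumerate(samples):
        pidx = pop_names.index(populations[name])
        q = pop_freq[:, pidx]
        g = rng.binomial(2, q).astype(np.int8)  # HWE background
        if inbred[idx] and config.roh_age_spec:
            segs = plant_roh(layout, config.roh_age_spec, rng, individual=name)
            truth.extend(segs)
            in_roh = np.zeros(n_sites, dtype=bool)
            for seg in segs:
                sl = chrom_slices[seg.chrom]
                p = pos_all[sl]
                lo = np.searchsorted(p, seg.start, side="left")
                hi = np.searchsorted(p, seg.end, side="right")
                in_roh[sl.start + lo : sl.start + hi] = True
            n_in = int(in_roh.sum())
            if n_in:
                ibd_alt = rng.random(n_in) < q[in_roh]
                g_roh = np.where(ibd_alt, 2, 0).astype(np.int8)
                het = rng.random(n_in) < config.residual_het
                g_roh[het] = 1
                g[in_roh] = g_roh
        geno[:, idx] = g

    # --- reads and likelihoods ----------------------------------------------
    depth = rng.poisson(depth_means[None, :], size=(n_sites, n_ind)).astype(np.int32)
    p_read = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])[geno]
    alt = rng.binomial(depth, p_read).astype(np.int32)
    gl = genotype_likelihoods(alt, depth, config.error_rate)

    ref_base = np.full(n_sites, "A", dtype=object)
    alt_base = np.full(n_sites, "G", dtype=object)
    table = SiteTable(
        samples=list(samples),
        chrom=chrom_all,
        pos=pos_all,
        ref=ref_base,
        alt=alt_base,
        ad_ref=depth - alt,
        ad_alt=alt,
        gl=gl,
        n_alleles=np.full(n_sites, 2, dtype=np.int8),
    )
    return SimResult(
        table=table,
        truth=truth,
        populations=populations,
        true_genotypes=geno,
        ancestral_freq=anc,
        pop_freq=pop_freq,
    )


# ---------------------------------------------------------------------------
# Truth / assignment file IO (plain text)
# ---------------------------------------------------------------------------

def write_truth_bed(truth: Sequence[PlantedROH], path) -> None:
    """BED (0-based half-open): chrom, start, end, individual, true_g."""
    with open(path, "w") as fh:
        for seg in truth:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.individual}\t{seg.true_g:g}\n")


def read_truth_bed(path) -> list[PlantedROH]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, name, score = line.rstrip("\n").split("\t")[:5]
            out.append(PlantedROH(name, chrom, int(s) + 1, int(e), float(score)))
    return out


def write_populations(populations: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tpopulation\n")
        for ind, pop in populations.items():
            fh.write(f"{ind}\t{pop}\n")


def read_populations(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        cols = header.rstrip("\n").split("\t")
        if cols[:2] != ["individual", "population"]:
            # headerless two-column file
            if len(cols) >= 2:
                out[cols[0]] = cols[1]
        for line in fh:
            if line.strip():
                ind, pop = line.rstrip("\n").split("\t")[:2]
                out[ind] = pop
    return out
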