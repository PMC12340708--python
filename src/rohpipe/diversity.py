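"""Nucleotide diversity from genotype likelihoods, and Weir-Cockerham F_ST.

The diversity path follows the standard genotype-likelihood recipe:

1. per-site allele-frequency likelihood vectors (SAF): the likelihood of the
   read data given each possible population alternate-allele count
   j in {0..2N}, computed by dynamic programming over individuals;
2. folding to minor-allele counts (ancestral state unknown);
3. a maximum-likelihood folded site-frequency spectrum by EM across sites;
4. per-site expected heterozygosity (pairwise theta) under the SFS-posterior
   over allele counts, tP = E[ k(2N-k) ] / C(2N,2);
5. genome-wide pi = sum of per-site tP divided by the total number of
   nucleotide sites with data (variant plus invariant), supplied explicitly.

F_ST between populations is the Weir & Cockerham (1984) variance-component
estimator on called genotypes, with the weighted multi-site form
``sum(a) / sum(a + b + c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "FoldedSFS",
    "FstResult",
    "site_saf",
    "fold_saf",
    "estimate_folded_sfs",
    "genomewide_pi",
    "weir_cockerham_fst",
]


def _log_comb(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def site_saf(gl_log10: np.ndarray) -> np.ndarray:
    """Site allele-frequency likelihoods, shape (S, 2N+1), max-normalized.

    ``gl_log10``: (S, N, 3) per-individual log10 genotype likelihoods.  The
    dynamic programme convolves individuals with genotype weights C(2, g) =
    (1, 2, 1), then divides by C(2N, j), yielding P(data | alt count j) up to
    a per-site constant.  Flat input triples for every individual give a flat
    SAF.
    """
    gl = np.asarray(gl_log10, dtype=float)
    if gl.ndim != 3 or gl.shape[2] != 3:
        raise ValueError("expected (S, N, 3) genotype likelihoods")
    S, N, _ = gl.shape
    if N < 1:
        raise ValueError("need at least one individual")
    L = np.power(10.0, gl)
    B = np.ones((S, 1))
    for i in range(N):
        nb = np.zeros((S, B.shape[1] + 2))
        nb[:, :-2] += B * L[:, i, 0][:, None]
        nb[:, 1:-1] += 2.0 * B * L[:, i, 1][:, None]
        nb[:, 2:] += B * L[:, i, 2][:, None]
        # guard against underflow for large N; SAF is defined up to a constant
        scale = nb.max(axis=1, keepdims=True)
        np.divide(nb, scale, out=nb, where=scale > 0)
        B = nb
    j = np.arange(2 * N + 1)
    saf = B / np.exp(_log_comb(2 * N, j))[None, :]
    saf /= saf.max(axis=1, keepdims=True)
    return saf


def fold_saf(saf: np.ndarray) -> np.ndarray:
    """Fold a (S, 2N+1) SAF to minor-allele counts (S, N+1).

    L_f(k) = L(k) + L(2N-k) for k < N; the k = N class is not doubled.
    """
    S, M = saf.shape
    if M % 2 == 0:
        raise ValueError("SAF length must be odd (2N+1)")
    N = (M - 1) // 2
    folded = saf[:, : N + 1].copy()
    if N > 0:
        folded[:, :N] += saf[:, N + 1 :][:, ::-1]
    return folded


@dataclass
class FoldedSFS:
    """Estimated folded spectrum (probabilities over minor-allele count)."""

    eta: np.ndarray
    loglik: float
    n_iter: int
    converged: bool


def estimate_folded_sfs(
    folded_saf: np.ndarray, tol: float = 1e-8, max_iter: int = 2000
) -> FoldedSFS:
    """Maximum-likelihood folded SFS across sites by EM.

    Starts from the uniform spectrum; each E step computes per-site posteriors
    over minor-allele counts, each M step averages them.  The per-iteration
    log-likelihood is non-decreasing (checked); non-convergence within
    ``max_iter`` returns ``converged=False``.
    """
    Lf = np.asarray(folded_saf, dtype=float)
    if Lf.ndim != 2 or Lf.shape[0] < 1:
        raise ValueError("need at least one site")
    K = Lf.shape[1]
    eta = np.full(K, 1.0 / K)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = Lf * eta[None, :]
        denom = w.sum(axis=1)
        ll = float(np.log(denom).sum())
        if ll + 1e-9 < prev_ll:
            raise AssertionError("EM log-likelihood decreased")
        post = w / denom[:, None]
        new_eta = post.mean(axis=0)
        delta = np.abs(new_eta - eta).max()
        eta = new_eta
        if delta < tol and np.isfinite(ll) and abs(ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
    return FoldedSFS(eta=eta, loglik=prev_ll, n_iter=it, converged=converged)


def genomewide_pi(folded_saf: np.ndarray, sfs: FoldedSFS | np.ndarray, n_total_sites: int) -> float:
    """Average pairwise nucleotide diversity.

    Per variant site the expected pairwise difference is
    ``E[k (2N - k)] / C(2N, 2)`` under the posterior over minor-allele counts
    (SFS prior times folded SAF); summing over sites and dividing by the
    total number of covered nucleotide sites (variant + invariant, supplied
    by the caller) gives genome-wide pi.  Invariant to how sites are split
    across chromosomes.
    """
    if n_total_sites <= 0:
        raise ValueError("n_total_sites must be positive")
    Lf = np.asarray(folded_saf, dtype=float)
    if Lf.shape[0] > n_total_sites:
        raise ValueError("n_total_sites smaller than the number of variant sites")
    eta = sfs.eta if isinstance(sfs, FoldedSFS) else np.asarray(sfs, dtype=float)
    K = Lf.shape[1]
    n_hap = 2 * (K - 1)
    k = np.arange(K)
    het = k * (n_hap - k) / (n_hap * (n_hap - 1) / 2.0)
    w = Lf * eta[None, :]
    post = w / w.sum(axis=1, keepdims=True)
    t_p = post @ het
    return float(t_p.sum() / n_total_sites)


@dataclass
class FstResult:
    a: np.ndarray          # among-population variance component per site
    b: np.ndarray          # among-individual within-population component
    c: np.ndarray          # within-individual component
    fst_weighted: float
    n_used: int
    n_skipped: int


def weir_cockerham_fst(genotypes: np.ndarray, pop_labels: np.ndarray) -> FstResult:
    """Weir & Cockerham (1984) F_ST from a genotype matrix.

    ``genotypes``: (S, N) with dosages 0/1/2 and -1 for missing;
    ``pop_labels``: (N,) population assignment.  Every population must have
    at least two individuals overall and at least one called genotype per
    used site; sites where any population has no calls (or with fewer than
    two populations represented) are skipped and counted.  Symmetric under
    relabeling of populations.
    """
    g = np.asarray(genotypes)
    labels = np.asarray(pop_labels)
    pops = np.unique(labels)
    r = len(pops)
    if r < 2:
        raise ValueError("need at least two populations")
    for p in pops:
        if (labels == p).sum() < 2:
            raise ValueError(f"population {p!r} has fewer than two individuals")

    called = g >= 0
    S = g.shape[0]
    n_i = np.zeros((S, r))
    p_i = np.zeros((S, r))
    h_i = np.zeros((S, r))
    for k, p in enumerate(pops):
        cols = labels == p
        gc = g[:, cols]
        ok = called[:, cols]
        n = ok.sum(axis=1)
        if not n.any():
            raise ValueError(f"population {p!r} has zero called genotypes at all sites")
        with np.errstate(invalid="ignore", divide="ignore"):
            n_i[:, k] = n
            p_i[:, k] = np.where(ok, gc, 0).sum(axis=1) / (2.0 * np.maximum(n, 1))
            h_i[:, k] = np.where(ok, gc == 1, False).sum(axis=1) / np.maximum(n, 1)

    usable = (n_i >= 1).all(axis=1) & (n_i.sum(axis=1) > r)  # n_bar > 1 needed
    n_used = int(usable.sum())
    n_skipped = S - n_used

    n_i = n_i[usable]
    p_i = p_i[usable]
    h_i = h_i[usable]

    n_bar = n_i.mean(axis=1)
    n_tot = n_i.sum(axis=1)
    n_c = (n_tot - (n_i**2).sum(axis=1) / n_tot) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=1) / n_tot
    s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=1) / n_tot

    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - (r - 1) / r * s2
            - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    finite = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    a, b, c = a[finite], b[finite], c[finite]
    denom = (a + b + c).sum()
    fst = float(a.sum() / denom) if denom != 0 else float("nan")
    return FstResult(a=a, b=b, c=c, fst_weighted=fst, n_used=int(finite.sum()), n_skipped=n_skipped + int((~finite).sum()))
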