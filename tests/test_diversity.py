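"""SAF dynamic programme, folded-SFS EM, pi, and Weir-Cockerham F_ST."""

import itertools

import numpy as np
import pytest

from rohpipe import diversity as dv
from rohpipe import simgenome as sg


def saf_bruteforce(gl_log10):
    """Enumerate all genotype configurations: P(data | alt count j)."""
    L = np.power(10.0, np.asarray(gl_log10, dtype=float))
    N = L.shape[0]
    out = np.zeros(2 * N + 1)
    from math import comb
    for config in itertools.product((0, 1, 2), repeat=N):
        j = sum(config)
        p_cfg = 1.0
        for i, g in enumerate(config):
            p_cfg *= L[i, g] * comb(2, g)
        out[j] += p_cfg
    out /= np.array([comb(2 * N, j) for j in range(2 * N + 1)])
    return out / out.max()


class TestSiteSAF:
    def test_single_certain_homref(self):
        gl = np.array([[[0.0, -99.0, -99.0]]])
        saf = dv.site_saf(gl)
        assert saf[0, 0] == pytest.approx(1.0)
        assert saf[0, 1:] == pytest.approx(0.0, abs=1e-90)

    def test_flat_gls_give_flat_saf(self):
        saf = dv.site_saf(np.zeros((1, 2, 3)))
        assert np.allclose(saf[0], 1.0)

    @pytest.mark.parametrize("N", [1, 2, 3])
    def test_matches_enumeration(self, N):
        rng = np.random.default_rng(N)
        gl = np.log10(rng.random((4, N, 3)) + 1e-3)
        gl -= gl.max(axis=2, keepdims=True)
        saf = dv.site_saf(gl)
        for s in range(4):
            assert np.allclose(saf[s], saf_bruteforce(gl[s]), atol=1e-12)


class TestFoldedSFS:
    def test_fold_adds_mirror_classes(self):
        saf = np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])  # N = 2
        folded = dv.fold_saf(saf)
        assert folded.tolist() == [[6.0, 6.0, 3.0]]

    def test_monomorphic_sites_concentrate_at_zero(self):
        gl = np.tile(np.array([0.0, -20.0, -40.0]), (200, 4, 1))
        sfs = dv.estimate_folded_sfs(dv.fold_saf(dv.site_saf(gl)))
        assert sfs.eta[0] > 0.999
        assert sfs.eta == pytest.approx(sfs.eta / sfs.eta.sum())

    def test_two_site_toy_matches_grid_search(self):
        Lf = np.array([[1.0, 0.2, 0.05], [0.1, 1.0, 0.3]])
        sfs = dv.estimate_folded_sfs(Lf, tol=1e-12, max_iter=20000)

        # dense grid over the 2-simplex as an independent maximizer
        best, best_ll = None, -np.inf
        step = 0.002
        for e0 in np.arange(0, 1 + step, step):
            for e1 in np.arange(0, 1 - e0 + step, step):
                e2 = 1 - e0 - e1
                if e2 < 0:
                    continue
                eta = np.array([e0, e1, e2])
                ll = np.log(Lf @ eta).sum()
                if ll > best_ll:
                    best_ll, best = ll, eta
        assert np.abs(sfs.eta - best).max() < 5e-3  # grid resolution
        assert sfs.loglik >= best_ll - 1e-9

    def test_em_loglik_monotone_by_hand_iteration(self):
        rng = np.random.default_rng(5)
        Lf = rng.random((300, 6)) + 1e-6
        eta = np.full(6, 1 / 6)
        prev = -np.inf
        for _ in range(50):
            w = Lf * eta
            denom = w.sum(1)
            ll = np.log(denom).sum()
            assert ll >= prev - 1e-9
            prev = ll
            eta = (w / denom[:, None]).mean(0)


class TestPi:
    def test_monomorphic_input_gives_zero(self):
        gl = np.tile(np.array([0.0, -20.0, -40.0]), (50, 4, 1))
        folded = dv.fold_saf(dv.site_saf(gl))
        sfs = dv.estimate_folded_sfs(folded)
        assert dv.genomewide_pi(folded, sfs, 1000) == pytest.approx(0.0, abs=1e-6)

    def test_hand_case_two_diploids_minor_count_two(self):
        # N = 2, deep data, two hets -> minor count 2: tP = 2*2/C(4,2) = 2/3
        het = [-99.0, 0.0, -99.0]
        hom = [0.0, -99.0, -99.0]
        gl = np.array([[het, het]] + [[hom, hom]] * 200)
        folded = dv.fold_saf(dv.site_saf(gl))
        sfs = dv.estimate_folded_sfs(folded)
        pi = dv.genomewide_pi(folded, sfs, 1000)
        assert pi == pytest.approx((2 / 3) / 1000, rel=1e-3)

    def test_invariant_to_site_partitioning(self):
        rng = np.random.default_rng(9)
        gl = np.log10(rng.random((400, 5, 3)) + 1e-3)
        gl -= gl.max(axis=2, keepdims=True)
        folded = dv.fold_saf(dv.site_saf(gl))
        sfs = dv.estimate_folded_sfs(folded)
        whole = dv.genomewide_pi(folded, sfs, 10_000)
        halves = (
            dv.genomewide_pi(folded[:137], sfs, 10_000)
            + dv.genomewide_pi(folded[137:], sfs, 10_000)
        )
        assert whole == pytest.approx(halves, abs=1e-12)

    def test_zero_total_sites_rejected(self):
        with pytest.raises(ValueError):
            dv.genomewide_pi(np.ones((1, 3)), np.ones(3) / 3, 0)


def wc_oracle(genotypes, labels):
    """Independent per-site Weir & Cockerham (1984) components, explicit loops."""
    a_l, b_l, c_l = [], [], []
    pops = sorted(set(labels))
    r = len(pops)
    for s in range(genotypes.shape[0]):
        n, p, h = [], [], []
        for pop in pops:
            g = [genotypes[s, i] for i in range(genotypes.shape[1])
                 if labels[i] == pop and genotypes[s, i] >= 0]
            if not g:
                n.append(0)
                p.append(0.0)
                h.append(0.0)
                continue
            n.append(len(g))
            p.append(sum(g) / (2 * len(g)))
            h.append(sum(1 for x in g if x == 1) / len(g))
        if min(n) < 1 or sum(n) <= r:
            continue
        n_bar = sum(n) / r
        n_c = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
        p_bar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
        s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
        h_bar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_l.append(a)
        b_l.append(b)
        c_l.append(c)
    return np.array(a_l), np.array(b_l), np.array(c_l)


class TestWeirCockerham:
    def test_fixed_difference_gives_unity(self):
        g = np.array([[0] * 5 + [2] * 5] * 20)
        labels = np.array(["A"] * 5 + ["B"] * 5)
        res = dv.weir_cockerham_fst(g, labels)
        assert res.fst_weighted == pytest.approx(1.0)

    def test_identical_populations_near_zero_and_match_oracle(self):
        rng = np.random.default_rng(21)
        half = rng.integers(0, 3, size=(100, 8))
        g = np.concatenate([half, half], axis=1)
        labels = np.array(["A"] * 8 + ["B"] * 8)
        res = dv.weir_cockerham_fst(g, labels)
        assert res.fst_weighted <= 0.0  # finite-sample negative bias
        a, b, c = wc_oracle(g, labels)
        assert np.allclose(res.a, a, atol=1e-10)
        assert np.allclose(res.b, b, atol=1e-10)
        assert np.allclose(res.c, c, atol=1e-10)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(22)
        g = rng.integers(0, 3, size=(60, 10))
        l1 = np.array(["A"] * 5 + ["B"] * 5)
        l2 = np.array(["B"] * 5 + ["A"] * 5)
        r1 = dv.weir_cockerham_fst(g, l1)
        r2 = dv.weir_cockerham_fst(g, l2)
        assert r1.fst_weighted == pytest.approx(r2.fst_weighted, abs=1e-12)

    def test_missing_genotypes_skip_sites_without_calls(self):
        g = np.array([[0, 0, -1, -1], [0, 2, 0, 2]])
        labels = np.array(["A", "A", "B", "B"])
        res = dv.weir_cockerham_fst(g, labels)
        assert res.n_skipped == 1

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            dv.weir_cockerham_fst(np.zeros((3, 4), dtype=int), np.array(["A"] * 4))
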