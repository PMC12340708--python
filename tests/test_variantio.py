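"""IO round-trips, EM allele frequencies, HWE exact test, the filter ladder."""

import math

import numpy as np
import pytest

from rohpipe import simgenome as sg
from rohpipe import variantio as vio


def _table_from_gl(gl_log10, pos=None, chrom="chr1", depth=20):
    """Minimal SiteTable around a (S, N, 3) GL array (sharp read counts)."""
    gl = np.asarray(gl_log10, dtype=float)
    S, N, _ = gl.shape
    pos = np.arange(1, S + 1) * 1000 if pos is None else np.asarray(pos)
    d = np.full((S, N), depth, dtype=np.int32)
    return vio.SiteTable(
        samples=[f"s{i}" for i in range(N)],
        chrom=np.array([chrom] * S, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.array(["A"] * S, dtype=object),
        alt=np.array(["G"] * S, dtype=object),
        ad_ref=d,
        ad_alt=np.zeros((S, N), dtype=np.int32),
        gl=gl,
    )


SHARP = {0: [0.0, -5.0, -20.0], 1: [-5.0, 0.0, -5.0], 2: [-20.0, -5.0, 0.0]}


def test_vcf_round_trip_preserves_sites_gls_and_sample_order(tmp_path, small_layout):
    cfg = sg.SimConfig(seed=21, n_individuals=5, snp_spacing_bp=500_000,
                       roh_age_spec=[(10, 0.2)])
    table = sg.simulate_cohort(cfg, small_layout).table
    path = tmp_path / "rt.vcf"
    vio.write_vcf(table, path, contigs=small_layout.chrom_lengths)
    back = vio.read_vcf(path)
    assert back.samples == table.samples
    assert np.array_equal(back.pos, table.pos)
    assert np.array_equal(back.chrom.astype(str), table.chrom.astype(str))
    assert np.array_equal(back.ad_ref, table.ad_ref)
    assert np.array_equal(back.ad_alt, table.ad_alt)
    assert np.allclose(back.gl, table.gl, atol=1e-4)  # printed precision


class TestAlleleFreqEM:
    def test_called_genotypes_give_count_frequency(self):
        gl = np.array([[SHARP[0], SHARP[1], SHARP[2]]])
        q, missing = vio.estimate_allele_freq(_table_from_gl(gl))
        assert not missing[0]
        assert q[0] == pytest.approx(0.5, abs=1e-6)

    def test_all_flat_site_flagged_and_kept_at_init(self):
        gl = np.zeros((1, 4, 3))
        q, missing = vio.estimate_allele_freq(_table_from_gl(gl, depth=0))
        assert missing[0]
        assert q[0] == pytest.approx(0.5)

    def test_noisy_recovery_within_sampling_error(self):
        rng = np.random.default_rng(31)
        N, q_true = 200, 0.3
        geno = rng.binomial(2, q_true, size=N)
        depth = rng.poisson(10, size=N)
        p_read = np.array([0.01, 0.5, 0.99])[geno]
        alt = rng.binomial(depth, p_read)
        gl = sg.genotype_likelihoods(alt, depth, 0.01)[None, :, :]
        table = _table_from_gl(gl)
        table.ad_ref = (depth - alt)[None, :]
        table.ad_alt = alt[None, :]
        q, _ = vio.estimate_allele_freq(table)
        q_oracle = geno.mean() / 2.0  # genotype-count frequency on the truth
        se = np.sqrt(q_true * (1 - q_true) / (2 * N))
        assert abs(q[0] - q_oracle) < 3 * se


class TestHWEExactTest:
    @pytest.mark.parametrize("counts", [(1, 0, 0), (0, 1, 0), (0, 0, 1), (5, 0, 0)])
    def test_degenerate_configurations_have_p_one(self, counts):
        assert vio.hwe_exact_test(*counts) == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            vio.hwe_exact_test(-1, 2, 3)

    def test_matches_big_integer_enumeration_small_totals(self):
        # exhaustive check up to n = 30 here; the full n <= 100 sweep runs in
        # the acceptance suite
        worst = 0.0
        for n in range(1, 31):
            for n1 in range(0, n + 1):
                hets = [h for h in range(n1 % 2, min(n1, 2 * n - n1) + 1, 2)]
                weights = []
                for h in hets:
                    a = (n1 - h) // 2
                    weights.append(math.comb(n, a) * math.comb(n - a, h) * 2**h)
                tot = sum(weights)
                probs = [w / tot for w in weights]
                for h, p in zip(hets, probs):
                    a = (n1 - h) // 2
                    expected = min(1.0, sum(pp for pp in probs if pp <= p * (1 + 1e-12)))
                    got = vio.hwe_exact_test(a, h, n - a - h)
                    worst = max(worst, abs(got - expected))
        assert worst < 1e-12

    def test_symmetric_in_allele_labels(self):
        assert vio.hwe_exact_test(3, 5, 1) == pytest.approx(vio.hwe_exact_test(1, 5, 3), abs=1e-15)


class TestFilterLadder:
    def test_toy_vcf_each_filter_drops_exactly_one(self, toy_vcf_path):
        table = vio.read_vcf(toy_vcf_path)
        out, tally = vio.apply_site_filters(table)
        assert out.n_sites == 4
        assert tally == {"biallelic": 1, "missing": 1, "depth_min": 1,
                         "depth_max": 1, "maf": 1, "hwe": 1}
        assert sum(tally.values()) == table.n_sites - out.n_sites
        assert out.pos.tolist() == [7000, 8000, 9000, 10000]

    def test_vacuous_thresholds_are_identity(self, toy_vcf_path):
        table = vio.read_vcf(toy_vcf_path)
        lax = vio.FilterConfig(maf_min=0.0, gq_min=0, site_mean_depth_min=0.0,
                               max_missing=0.0, hwe_p_min=0.0, site_mean_depth_max=1e9)
        out, tally = vio.apply_site_filters(table, lax)
        # the triallelic record still falls to the structural biallelic rule
        assert out.n_sites == table.n_sites - 1
        assert tally["biallelic"] == 1 and sum(tally.values()) == 1

    def test_empty_input_passes_through(self):
        empty = _table_from_gl(np.zeros((0, 3, 3)))
        out, tally = vio.apply_site_filters(empty)
        assert out.n_sites == 0
        assert sum(tally.values()) == 0

    def test_ladder_is_idempotent(self, toy_vcf_path):
        table = vio.read_vcf(toy_vcf_path)
        once, _ = vio.apply_site_filters(table)
        twice, tally2 = vio.apply_site_filters(once)
        assert twice.n_sites == once.n_sites
        assert sum(tally2.values()) == 0


class TestIndividualDepthFilter:
    def test_hand_computed_means_keep_boundary_individual(self):
        # three individuals with mean depths 4.9, 5.0, 9.7 over ten sites
        depths = np.array([[4, 5, 10]] * 9 + [[13, 5, 7]], dtype=np.int32)
        assert depths.mean(axis=0) == pytest.approx([4.9, 5.0, 9.7])
        gl = np.zeros((10, 3, 3))
        table = _table_from_gl(gl)
        table.ad_ref = depths
        table.ad_alt = np.zeros_like(depths)
        out, kept, means = vio.filter_individuals_by_depth(table, 5.0)
        assert kept == ["s1", "s2"]
        assert out.n_samples == 2

    def test_all_removed_raises(self):
        table = _table_from_gl(np.zeros((2, 2, 3)), depth=1)
        with pytest.raises(ValueError, match="all individuals"):
            vio.filter_individuals_by_depth(table, 99.0)


class TestSubsample:
    def test_identity_empty_and_determinism(self, toy_vcf_path):
        table = vio.read_vcf(toy_vcf_path)
        assert vio.subsample_sites(table, table.n_sites, 1).pos.tolist() == table.pos.tolist()
        assert vio.subsample_sites(table, 0, 1).n_sites == 0
        a = vio.subsample_sites(table, 5, seed=7).pos
        b = vio.subsample_sites(table, 5, seed=7).pos
        c = vio.subsample_sites(table, 5, seed=8).pos
        assert np.array_equal(a, b)
        assert sorted(a.tolist()) == a.tolist()  # order preserved
        assert not np.array_equal(a, c)

    def test_oversampling_rejected(self, toy_vcf_path):
        table = vio.read_vcf(toy_vcf_path)
        with pytest.raises(ValueError):
            vio.subsample_sites(table, table.n_sites + 1, 1)


class TestLinkageMap:
    def test_two_anchor_uniform_chromosome(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chrom\tpos_bp\tcm\nchr1\t1\t0\nchr1\t1000000\t1\n")
        layout = vio.read_linkage_map(p)
        assert layout.chrom_names == ("chr1",)
        assert layout.bp_to_cm("chr1", 500_000) == pytest.approx(0.4999995, abs=1e-3)

    def test_unsorted_rows_sorted_then_validated(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chrom\tpos_bp\tcm\nchr1\t1000000\t1\nchr1\t1\t0\n")
        layout = vio.read_linkage_map(p)
        bp, cm = layout.map_anchors["chr1"]
        assert bp.tolist() == [1.0, 1000000.0]

    def test_decreasing_cm_rejected_with_line(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chrom\tpos_bp\tcm\nchr1\t1\t0\nchr1\t500000\t2\nchr1\t1000000\t1\n")
        with pytest.raises(ValueError, match="chr1"):
            vio.read_linkage_map(p)
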