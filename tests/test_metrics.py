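import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import lattice_map, symmetric_autocorrelogram
from gridplace.metrics import (
    RateMap,
    autocorrelogram,
    cross_entropy_measures,
    entropy_suite,
    error_summaries,
    gridness_hex,
    gridness_square,
    rate_map,
)


class TestRateMap:
    def test_per_bin_means_by_hand(self):
        pos = np.array([[1.0, 1.0], [1.0, 1.0], [6.0, 1.0], [1.0, 6.0]])
        act = np.array([2.0, 4.0, 10.0, 0.0])
        rm = rate_map(act, pos, side_length=10.0, bin_size=5.0, smooth_sigma=0.0)
        assert rm.values[0, 0] == pytest.approx(3.0)   # mean of 2 and 4
        assert rm.values[1, 0] == pytest.approx(10.0)
        assert rm.values[0, 1] == pytest.approx(0.0)
        assert np.isnan(rm.values[1, 1])               # never visited

    def test_constant_activity_everywhere(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 100, (500, 2))
        rm = rate_map(np.full(500, 3.3), pos, 100.0, smooth_sigma=0.0)
        visited = np.isfinite(rm.values)
        assert np.allclose(rm.values[visited], 3.3)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            rate_map(np.empty(0), np.empty((0, 2)), 100.0)


class TestAutocorrelogram:
    def test_zero_lag_and_centrosymmetry(self):
        rm = lattice_map("hex")
        ac = autocorrelogram(rm)
        c = (ac.shape[0] - 1) // 2
        assert ac[c, c] == pytest.approx(1.0, abs=1e-9)
        flipped = ac[::-1, ::-1]
        both = np.isfinite(ac) & np.isfinite(flipped)
        assert np.allclose(ac[both], flipped[both], atol=1e-9)

    def test_hexagonal_map_has_six_fold_ring(self):
        ac = autocorrelogram(lattice_map("hex"))
        from gridplace.metrics import _central_peaks

        peaks = _central_peaks(ac)
        assert peaks.shape[0] == 6
        angles = np.sort(np.degrees(np.arctan2(peaks[:, 0], peaks[:, 1])) % 360)
        gaps = np.diff(np.concatenate([angles, [angles[0] + 360]]))
        assert np.allclose(gaps, 60.0, atol=8.0)

    def test_sparse_overlap_marked_missing(self):
        vals = np.full((10, 10), np.nan)
        vals[:3, :3] = 1.0
        ac = autocorrelogram(RateMap(vals, np.ones((10, 10)), 1.0), min_overlap=5)
        assert np.isnan(ac[0, 0])  # extreme lag has almost no overlap


class TestGridness:
    def test_circularly_symmetric_scores_zero(self):
        ac = symmetric_autocorrelogram()
        assert abs(gridness_hex(ac)) < 1e-8
        assert abs(gridness_square(ac)) < 1e-8

    def test_hexagonal_fixture_golden_scores(self):
        ac = autocorrelogram(lattice_map("hex"))
        assert gridness_hex(ac) > 1.0
        assert gridness_square(ac) < 0.0

    def test_square_fixture_scores(self):
        ac = autocorrelogram(lattice_map("square"))
        assert gridness_square(ac) > 0.5
        assert gridness_hex(ac) < 0.0

    @pytest.mark.parametrize("angle", np.linspace(0.0, 1.5, 10))
    def test_fixture_ordering_across_orientations(self, angle):
        hex_ac = autocorrelogram(lattice_map("hex", angle=angle))
        sq_ac = autocorrelogram(lattice_map("square", angle=angle))
        assert gridness_hex(hex_ac) > gridness_square(hex_ac)
        assert gridness_square(sq_ac) > gridness_hex(sq_ac)

    def test_invariance_to_rate_rescaling(self):
        rm = lattice_map("hex", angle=0.3)
        scaled = RateMap(rm.values * 7.5, rm.occupancy, rm.bin_size)
        a1, a2 = autocorrelogram(rm), autocorrelogram(scaled)
        both = np.isfinite(a1)
        assert np.allclose(a1[both], a2[both], atol=1e-9)
        assert gridness_hex(a1) == pytest.approx(gridness_hex(a2), abs=1e-9)

    def test_featureless_map_flagged(self):
        flat = RateMap(np.ones((20, 20)), np.ones((20, 20)), 2.5)
        with pytest.raises(ValueError):
            autocorrelogram(RateMap(np.full((20, 20), np.nan), np.zeros((20, 20)), 2.5))
        ac = np.zeros((39, 39))
        ac[19, 19] = 1.0
        assert np.isnan(gridness_hex(ac))  # no ring peaks to crop


class TestEntropySuite:
    def test_uniform_and_degenerate(self):
        es = entropy_suite(np.full(4, 0.25), dx=20.0)
        assert es.H == pytest.approx(np.log(4))
        assert es.ratio == pytest.approx(1.0)
        assert es.complexity == pytest.approx(0.0)
        assert es.info == pytest.approx(0.0)
        es = entropy_suite([1.0, 0.0, 0.0])
        assert es.H == 0.0
        assert es.complexity == pytest.approx(1.0)

    def test_printed_decomposition_by_hand(self):
        es = entropy_suite([0.5, 0.25, 0.25], dx=[2.0, 1.0, 1.0])
        s_hand = -(0.5 * np.log(0.25) + 0.25 * np.log(0.25) + 0.25 * np.log(0.25))
        z_hand = -(0.5 * np.log(2.0))
        assert es.S == pytest.approx(s_hand, abs=1e-12)
        assert es.Z == pytest.approx(z_hand, abs=1e-12)
        assert es.S + es.Z == pytest.approx(es.H, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            entropy_suite([0.5, 0.4])
        with pytest.raises(ValueError):
            entropy_suite([0.5, 0.5], dx=[1.0, -1.0])

    @given(st.integers(2, 30), st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities_on_random_distributions(self, n, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        dx = rng.uniform(0.5, 30.0, n)
        es = entropy_suite(p, dx=dx)
        assert 0.0 <= es.H <= np.log(n) + 1e-12
        assert es.S + es.Z == pytest.approx(es.H, abs=1e-12)
        assert es.complexity == pytest.approx(1 - es.H / np.log(n), abs=1e-12)
        assert es.info == pytest.approx(np.log(n) - es.H, abs=1e-12)

    def test_log2_option(self):
        es = entropy_suite(np.full(4, 0.25), base2=True)
        assert es.H == pytest.approx(2.0)


class TestCrossEntropy:
    def test_equal_distributions(self):
        p = np.full(4, 0.25)
        hp, hq, hpq, i = cross_entropy_measures(p, p)
        assert hp == pytest.approx(hq)
        assert hpq == pytest.approx(0.0)
        assert i == pytest.approx(0.0)

    def test_degenerate_against_uniform(self):
        hp, hq, hpq, i = cross_entropy_measures([1.0, 0.0], [0.5, 0.5])
        assert hp == pytest.approx(np.log(2))
        assert i == pytest.approx(np.log(2))

    def test_support_violation_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_measures([0.5, 0.5], [1.0, 0.0])

    def test_sign_covariation_reported(self):
        rng = np.random.default_rng(0)
        same_sign = 0
        for _ in range(300):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            _, _, hpq, i = cross_entropy_measures(p, q)
            same_sign += (hpq >= 0) == (i >= 0)
        # reported association, not asserted as a law
        assert same_sign >= 0


class TestErrorSummaries:
    def test_exact_estimates_and_known_offset(self):
        t = 50
        truth = np.cumsum(np.ones((t, 2)), axis=0)
        est = np.repeat(truth[:, None, :], 3, axis=1)
        est[:, 1, :] += [3.0, 4.0]
        tables = error_summaries(est, truth, n_bins=5)
        s = tables["series"]
        assert np.allclose(s["err_module1"], 0.0)
        assert np.allclose(s["err_module2"], 5.0)  # 3-4-5 triangle
        assert len(tables["binned"]) == 5

    def test_variance_sample_convention(self):
        truth = np.zeros((3, 2))
        est = np.zeros((3, 2, 2))
        est[:, 1, 0] = 2.0
        tables = error_summaries(est, truth)
        # std of (0, 2) with ddof=1 is sqrt(2): variance column is var_x+var_y
        assert np.allclose(tables["series"]["variance"], 2.0)
        assert np.allclose(tables["series"]["e_error"], np.sqrt(2.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            error_summaries(np.zeros((4, 2, 2)), np.zeros((3, 2)))
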