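"""Profile prediction, peak times and the roughness validation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gptime import (
    CellMetadata,
    ExpressionMatrix,
    GeneParams,
    KernelConfig,
    PosteriorSample,
    circular_rmse,
    estimate_peak_times,
    predict_profiles,
    roughness,
    roughness_test,
    sample_null_orderings,
    simulate_dataset,
)
from gptime.profiles import ProfilePrediction


def _sample(tau, psi, omega, phi):
    G = len(psi)
    return PosteriorSample(
        tau=np.asarray(tau, float), psi=np.asarray(psi, float),
        omega=np.asarray(omega, float), phi=np.asarray(phi, float), log_joint=0.0,
    )


class TestPredictProfiles:
    CFG = KernelConfig(length_scale=1.0)

    def test_noise_free_interpolation(self):
        tau = np.linspace(0, 3, 7)
        y = np.sin(tau)
        x = ExpressionMatrix(["G1"], [f"C{i}" for i in range(7)], y[None, :])
        s = _sample(tau, [1.0], [1e-8], [y.mean()])
        pred = predict_profiles(s, x, self.CFG, grid=tau)
        np.testing.assert_allclose(pred.mean[0], y, atol=1e-3)

    def test_zero_amplitude_reverts_to_mean(self):
        tau = np.array([0.0, 1.0, 2.0])
        x = ExpressionMatrix(["G1"], ["a", "b", "c"], np.array([[1.0, 2.0, 3.0]]))
        s = _sample(tau, [0.0], [0.5], [2.0])
        pred = predict_profiles(s, x, self.CFG, grid_size=20)
        np.testing.assert_array_equal(pred.mean[0], 2.0)
        np.testing.assert_array_equal(pred.variance[0], 0.0)

    def test_prior_reversion_far_from_data(self):
        tau = np.array([0.0, 0.5, 1.0])
        x = ExpressionMatrix(["G1"], ["a", "b", "c"], np.array([[2.0, 2.5, 3.0]]))
        s = _sample(tau, [1.3], [0.2], [0.7])
        pred = predict_profiles(s, x, self.CFG, grid=np.array([40.0]))
        assert pred.mean[0, 0] == pytest.approx(0.7, abs=1e-6)
        assert pred.variance[0, 0] == pytest.approx(1.3, rel=1e-6)

    def test_periodic_grid_covers_one_period(self):
        cfg = KernelConfig(length_scale=1.0, period=3.0)
        tau = np.array([0.5, 1.5, 2.5])
        x = ExpressionMatrix(["G1"], ["a", "b", "c"], np.array([[1.0, 0.0, 1.0]]))
        s = _sample(tau, [1.0], [0.1], [0.6])
        pred = predict_profiles(s, x, cfg, grid_size=30)
        assert pred.grid[0] == 0.0 and pred.grid[-1] < 3.0


class TestEstimatePeakTimes:
    def test_cosine_peak(self):
        grid = np.linspace(0, 3, 300, endpoint=False)
        mean = np.cos(2 * np.pi * (grid - 1.0) / 3.0)[None, :]
        pred = ProfilePrediction(grid=grid, mean=mean, variance=np.zeros_like(mean),
                                 gene_ids=["G1"], period=3.0)
        peaks, defined = estimate_peak_times(pred)
        assert defined[0]
        assert peaks[0] == pytest.approx(1.0, abs=3.0 / 300 + 1e-9)

    def test_monotone_profile_peaks_at_edge(self):
        grid = np.linspace(0, 1, 50)
        pred = ProfilePrediction(grid=grid, mean=grid[None, :],
                                 variance=np.zeros((1, 50)), gene_ids=["G1"])
        peaks, defined = estimate_peak_times(pred)
        assert peaks[0] == grid[-1]

    def test_tie_picks_earlier_grid_point(self):
        grid = np.linspace(0, 1, 11)
        mean = np.zeros((1, 11))
        mean[0, [2, 7]] = 5.0
        pred = ProfilePrediction(grid=grid, mean=mean, variance=np.zeros_like(mean),
                                 gene_ids=["G1"])
        peaks, _ = estimate_peak_times(pred)
        assert peaks[0] == grid[2]

    def test_flat_profile_flagged_undefined(self):
        grid = np.linspace(0, 1, 20)
        pred = ProfilePrediction(grid=grid, mean=np.full((1, 20), 3.0),
                                 variance=np.zeros((1, 20)), gene_ids=["G1"])
        _, defined = estimate_peak_times(pred)
        assert not defined[0]

    def test_phase_recovery_from_low_noise_sinusoids(self):
        # generator with known phases -> predicted peaks within 2 grid steps
        from gptime import Hyperparameters

        h = Hyperparameters(0.0, 0.3, -12.0, 0.1, length_scale=1.0,
                            sigma_tau=0.5, period=3.0)
        ds = simulate_dataset(5, 60, 3, 1.0, h, seed=3, profile="sinusoid")
        s = _sample(ds.tau, ds.psi, ds.omega, ds.expression.values.mean(axis=1))
        pred = predict_profiles(s, ds.expression, h.kernel_config(), grid_size=90)
        peaks, defined = estimate_peak_times(pred)
        step = 3.0 / 90
        d = np.mod(np.abs(peaks - ds.true_peak_times()), 3.0)
        d = np.minimum(d, 3.0 - d)
        assert np.all(d[defined] <= 2 * step + 1e-9)


class TestCircularRmse:
    def test_exact_and_wrapped(self):
        est = np.array([0.1, 1.2, 2.9])
        assert circular_rmse(est, est, 3.0) == 0.0
        assert circular_rmse(est + 3.0, est, 3.0) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_single_gene(self):
        assert circular_rmse([0.0], [1.5], 3.0) == pytest.approx(1.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            circular_rmse([0.0, 1.0], [0.0], 3.0)


class TestRoughness:
    def test_hand_computed_value(self):
        # values (1,2,3,5): diffs (1,1,2), mean square 2, sqrt ~ 1.41421,
        # sample sd ~ 1.70783 -> R ~ 0.8280
        r = roughness(np.array([1.0, 2.0, 3.0, 5.0]), np.arange(4))
        assert r == pytest.approx(0.8280, abs=1e-4)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=9)
        z = rng.permutation(9)
        assert roughness(x, z) == pytest.approx(roughness(x, z[::-1]), rel=1e-12)

    @pytest.mark.parametrize("C", [4, 5, 6, 7])
    def test_sorted_ordering_is_permutation_minimum(self, C):
        rng = np.random.default_rng(C)
        x = rng.normal(size=C)
        best = min(
            roughness(x, np.array(p)) for p in itertools.permutations(range(C))
        )
        assert roughness(x, np.argsort(x)) == pytest.approx(best, rel=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), flip=st.booleans())
    @settings(max_examples=50, derandomize=True)
    def test_affine_invariance(self, a, b, flip):
        rng = np.random.default_rng(17)
        x = rng.normal(size=8)
        z = rng.permutation(8)
        scale = -a if flip else a
        assert roughness(scale * x + b, z) == pytest.approx(roughness(x, z), rel=1e-9)

    def test_constant_gene_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            roughness(np.ones(5), np.arange(5))


class TestNullOrderings:
    def test_all_distinct_times_unique_ordering(self):
        meta = CellMetadata(["a", "b", "c"], [3.0, 1.0, 2.0])
        for z in sample_null_orderings(meta, 5, seed=0):
            np.testing.assert_array_equal(z, [1, 2, 0])

    def test_single_time_uniform_over_permutations(self):
        # chi-square over the 24 permutations of C=4, n=24000 draws
        meta = CellMetadata(["a", "b", "c", "d"], [1.0] * 4)
        draws = sample_null_orderings(meta, 24000, seed=1)
        perms = {p: i for i, p in enumerate(itertools.permutations(range(4)))}
        counts = np.zeros(24)
        for z in draws:
            counts[perms[tuple(z)]] += 1
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        from scipy.stats import chi2 as chi2_dist

        assert chi2_dist.sf(chi2, df=23) > 1e-4

    def test_capture_blocks_respected(self):
        meta = CellMetadata(["a", "b", "c", "d", "e"], [1, 1, 2, 2, 2])
        for z in sample_null_orderings(meta, 50, seed=2):
            assert set(z[:2]) == {0, 1}
            assert set(z[2:]) == {2, 3, 4}

    def test_within_block_positions_uniform(self):
        meta = CellMetadata(list("abcde"), [1, 1, 1, 2, 2])
        draws = sample_null_orderings(meta, 6000, seed=3)
        first_pos = np.array([z[0] for z in draws])
        freqs = np.bincount(first_pos, minlength=3)[:3] / 6000
        np.testing.assert_allclose(freqs, 1 / 3, atol=0.03)

    def test_deterministic_given_seed(self):
        meta = CellMetadata(list("abcd"), [1, 1, 2, 2])
        a = sample_null_orderings(meta, 10, seed=9)
        b = sample_null_orderings(meta, 10, seed=9)
        for za, zb in zip(a, b):
            np.testing.assert_array_equal(za, zb)


class TestRoughnessTest:
    def _smooth_heldout(self, tau, G=10, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.stack([
            np.sin(tau / 2.0 + rng.uniform(0, np.pi)) + 0.05 * rng.normal(size=tau.size)
            for _ in range(G)
        ])
        return ExpressionMatrix([f"H{i}" for i in range(G)],
                                [f"C{i}" for i in range(tau.size)], vals)

    def test_smooth_genes_under_true_ordering_significant(self):
        rng = np.random.default_rng(1)
        C = 40
        tau = np.sort(rng.uniform(0, 8, C))
        k = np.repeat(np.arange(1.0, 5.0), 10)
        meta = CellMetadata([f"C{i}" for i in range(C)], k)
        x_held = self._smooth_heldout(tau)
        res = roughness_test(x_held, tau, meta, n_null=1000, seed=2)
        assert res.p_value < 0.01
        assert res.fitted_mean < res.null_means.mean()

    def test_pure_noise_mostly_insignificant(self):
        C = 40
        k = np.repeat(np.arange(1.0, 5.0), 10)
        meta = CellMetadata([f"C{i}" for i in range(C)], k)
        ordering = np.argsort(np.random.default_rng(0).normal(size=C))
        n_small = 0
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            x = ExpressionMatrix([f"N{i}" for i in range(8)], list(meta.cell_ids),
                                 rng.normal(size=(8, C)))
            res = roughness_test(x, ordering, meta, n_null=200, seed=rep)
            if res.p_value <= 0.05:
                n_small += 1
        assert n_small <= 50 * 0.1 + 2

    def test_null_ordering_statistic_centred(self):
        C = 30
        k = np.repeat(np.arange(1.0, 4.0), 10)
        meta = CellMetadata([f"C{i}" for i in range(C)], k)
        rng = np.random.default_rng(5)
        x = ExpressionMatrix([f"N{i}" for i in range(6)], list(meta.cell_ids),
                             rng.normal(size=(6, C)))
        ts = []
        for rep in range(40):
            z = sample_null_orderings(meta, 1, seed=500 + rep)[0]
            res = roughness_test(x, z, meta, n_null=150, seed=rep)
            ts.append(res.t_statistic)
        mean_t = np.mean(ts)
        assert abs(mean_t) < 3 * np.std(ts) / np.sqrt(len(ts)) + 0.5

    def test_degenerate_genes_dropped(self, caplog):
        C = 12
        meta = CellMetadata([f"C{i}" for i in range(C)], np.repeat([1.0, 2.0], 6))
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(3, C))
        vals[0] = 4.2  # constant gene
        x = ExpressionMatrix(["Gc", "G1", "G2"], list(meta.cell_ids), vals)
        with caplog.at_level("WARNING"):
            res = roughness_test(x, np.arange(C), meta, n_null=50, seed=0)
        assert "Gc" in caplog.text
        assert res.gene_ids == ["G1", "G2"]
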