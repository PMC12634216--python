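"""Unit and property tests for the regularized Toeplitz deconvolution core."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.testing import assert_allclose
from scipy.stats import pearsonr

import hrfdeconv as hd
from hrfdeconv.deconv import regularization_matrix
from hrfdeconv.errors import (
    ChannelDroppedError,
    ConditioningError,
    DegenerateHRFError,
    DegenerateSignalWarning,
    DimensionError,
    EdgeClipWarning,
    NoEventsError,
    ValidationError,
)


class TestBuildDesignMatrix:
    def test_impulse_driver_is_shifted_identity(self):
        H = hd.build_design_matrix([1, 0, 0, 0, 0], 3)
        k = np.array([3.0, -1.0, 2.0])
        assert_allclose(H.entries @ k, [3, -1, 2, 0, 0])

    def test_hand_expanded_entries(self):
        H = hd.build_design_matrix([1, 0, 1, 0], 2)
        assert_allclose(H.entries, [[1, 0], [0, 1], [1, 0], [0, 1]])

    def test_matches_brute_force_convolution(self, rng):
        for _ in range(20):
            n, d = 50, 7
            driver = rng.normal(size=n)
            k = rng.normal(size=d)
            H = hd.build_design_matrix(driver, d)
            expected = np.convolve(driver, k)[:n]
            assert np.max(np.abs(H.entries @ k - expected)) < 1e-10

    @pytest.mark.parametrize(
        "driver,d,exc",
        [([1.0, 2.0], 3, DimensionError), ([1.0, np.nan], 1, ValidationError)],
    )
    def test_invalid_inputs(self, driver, d, exc):
        with pytest.raises(exc):
            hd.build_design_matrix(driver, d)

    @given(st.integers(5, 40), st.integers(1, 5), st.integers(0, 2**31 - 1))
    def test_convolution_identity_property(self, n, d, seed):
        rng = np.random.default_rng(seed)
        driver, k = rng.normal(size=n), rng.normal(size=min(d, n))
        H = hd.build_design_matrix(driver, k.size)
        assert np.max(np.abs(H.entries @ k - np.convolve(driver, k)[:n])) < 1e-10


class TestTikhonovSolve:
    def test_ridge_on_identity_shrinks(self):
        H = hd.DesignMatrix(np.eye(2))
        assert_allclose(hd.tikhonov_solve(H, [2, 4], 1.0), [1, 2])

    def test_lam_zero_exact_solve(self, rng):
        A = rng.normal(size=(4, 4)) + 4 * np.eye(4)
        y = rng.normal(size=4)
        x = hd.tikhonov_solve(A, y, 0.0)
        assert_allclose(A @ x, y, atol=1e-10)

    @pytest.mark.parametrize("reg", ["identity", "first_difference"])
    def test_matches_literal_closed_form(self, rng, reg):
        for _ in range(20):
            H = rng.normal(size=(6, 3))
            y = rng.normal(size=6)
            lam = 0.5
            L = regularization_matrix(3, reg)
            expected = np.linalg.pinv(H.T @ H + lam * L.T @ L) @ H.T @ y
            assert np.max(np.abs(hd.tikhonov_solve(H, y, lam, reg) - expected)) < 1e-8

    def test_singular_at_lam_zero_raises(self):
        H = np.ones((3, 2))  # identical columns
        with pytest.raises(ConditioningError):
            hd.tikhonov_solve(H, [1.0, 2.0, 3.0], 0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            hd.tikhonov_solve(np.eye(3), [1.0, 2.0], 1.0)

    def test_solution_minimizes_objective(self, rng):
        """Random perturbations never decrease ||Hx-y||^2 + lam ||x||^2."""
        H = rng.normal(size=(20, 6))
        y = rng.normal(size=20)
        lam = 0.3
        x = hd.tikhonov_solve(H, y, lam)

        def objective(v):
            return np.sum((H @ v - y) ** 2) + lam * np.sum(v**2)

        base = objective(x)
        for _ in range(100):
            assert objective(x + rng.normal(scale=1e-3, size=6)) >= base - 1e-12


class TestZscore:
    def test_two_point_example(self):
        assert_allclose(hd.zscore([0, 2]), [-1, 1])

    def test_constant_signal_returns_zeros_with_warning(self):
        with pytest.warns(DegenerateSignalWarning):
            out = hd.zscore(np.full(10, 3.7))
        assert_allclose(out, 0)

    def test_population_moments(self, rng):
        out = hd.zscore(rng.normal(2.0, 5.0, size=1000))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1) < 1e-9

    def test_too_short(self):
        with pytest.raises(ValidationError):
            hd.zscore([1.0])


class TestExpandEdges:
    def test_default_quarter_pad(self):
        ev = hd.EventTrain(impulses=np.eye(1000)[500], sfreq=10.0)
        shifted, d_exp = hd.expand_edges(ev, 10.0, 0.25, 10.0)
        assert d_exp == 150
        assert shifted.onset_indices.tolist() == [475]

    def test_zero_fraction_is_noop(self):
        ev = hd.EventTrain(impulses=np.eye(100)[50], sfreq=10.0)
        shifted, d_exp = hd.expand_edges(ev, 5.0, 0.0, 10.0)
        assert d_exp == 50
        assert_allclose(shifted.impulses, ev.impulses)

    def test_event_shifted_negative_is_dropped(self):
        imp = np.zeros(1000)
        imp[10] = 1.0
        ev = hd.EventTrain(impulses=imp, sfreq=10.0)
        with pytest.raises(NoEventsError), pytest.warns(EdgeClipWarning):
            hd.expand_edges(ev, 10.0, 0.25, 10.0)

    def test_partial_drop_keeps_remaining(self):
        imp = np.zeros(1000)
        imp[10] = 1.0
        imp[500] = 2.0
        ev = hd.EventTrain(impulses=imp, sfreq=10.0)
        with pytest.warns(EdgeClipWarning):
            shifted, _ = hd.expand_edges(ev, 10.0, 0.25, 10.0)
        assert shifted.onset_indices.tolist() == [475]
        assert shifted.impulses[475] == 2.0


class TestAssessConditioning:
    def test_identity_design(self):
        passed, cond = hd.assess_conditioning(np.eye(4), 10.0, lam=0.0)
        assert passed and abs(cond - 1) < 1e-12

    def test_rank_deficient_fails_at_lam_zero(self):
        H = np.ones((5, 2))
        passed, cond = hd.assess_conditioning(H, 1e8, lam=0.0)
        assert not passed and cond > 1e8

    def test_boundary_equality_passes(self):
        _, cond = hd.assess_conditioning(np.diag([2.0, 1.0]), 1.0, lam=0.0)
        passed, _ = hd.assess_conditioning(np.diag([2.0, 1.0]), cond, lam=0.0)
        assert passed


class TestEstimateChannelHRF:
    def test_noiseless_recovery(self):
        spec = hd.SimulationSpec(
            n_subjects=1, duration_s=560.0, n_events=20, noise=[],
            white_noise_sd=0.0, drift_slope_per_s=0.0, target_snr=None, seed=3,
        )
        recs, evs, truth = hd.simulate_cohort(spec)
        est = hd.estimate_channel_hrf(
            recs[0], evs[0], 30.0, hd.DeconvConfig(lam=1e-6)
        )
        assert pearsonr(est.kernel, truth.kernel)[0] > 0.999

    def test_empty_event_train(self):
        rec = hd.ChannelRecording("c", "hbo", 10.0, np.zeros(100) + np.arange(100), [0, 0, 0])
        ev = hd.EventTrain(impulses=np.zeros(100), sfreq=10.0)
        with pytest.raises(NoEventsError):
            hd.estimate_channel_hrf(rec, ev, 5.0, hd.DeconvConfig())

    def test_kernel_length_contract(self):
        spec = hd.SimulationSpec(n_subjects=1, duration_s=300.0, n_events=8, seed=4)
        recs, evs, _ = hd.simulate_cohort(spec)
        est = hd.estimate_channel_hrf(recs[0], evs[0], 30.0, hd.DeconvConfig())
        assert est.kernel.size == 300

    def test_ill_conditioned_channel_dropped(self):
        # a single repeated instantaneous event pair makes columns collide
        rec = hd.ChannelRecording("c", "hbo", 10.0, np.arange(200.0), [0, 0, 0])
        ev = hd.EventTrain(impulses=np.ones(200), sfreq=10.0)  # event every sample
        with pytest.raises(ChannelDroppedError):
            hd.estimate_channel_hrf(
                rec, ev, 10.0, hd.DeconvConfig(lam=0.0, edge_fraction=0.0,
                                               cond_threshold=1.0)
            )


class TestPoolHRFs:
    def _estimates(self, stack):
        return [
            hd.HRFEstimate(kernel=k, duration_s=len(k) / 10.0, sfreq=10.0)
            for k in stack
        ]

    def test_zero_trim_is_arithmetic_mean(self, rng):
        stack = rng.normal(size=(7, 30))
        pool = hd.pool_hrfs(self._estimates(stack), 0.0)
        assert_allclose(pool.mean_kernel, stack.mean(axis=0))

    def test_identical_kernels(self, rng):
        k = rng.normal(size=30)
        pool = hd.pool_hrfs(self._estimates([k] * 5), 0.1)
        assert_allclose(pool.mean_kernel, k)
        assert_allclose(pool.std_kernel, 0, atol=1e-12)

    def test_outlier_matches_sort_and_discard_oracle(self, rng):
        stack = rng.normal(size=(10, 20))
        stack[3] += 50.0  # gross outlier subject
        pool = hd.pool_hrfs(self._estimates(stack), 0.1)
        k = int(np.floor(0.1 * 10))
        expected = np.sort(stack, axis=0)[k : 10 - k].mean(axis=0)
        assert_allclose(pool.mean_kernel, expected)
        # spread uses all (untrimmed) subjects
        assert_allclose(pool.std_kernel, stack.std(axis=0, ddof=1))

    def test_permutation_invariance(self, rng):
        stack = rng.normal(size=(9, 15))
        ests = self._estimates(stack)
        a = hd.pool_hrfs(ests, 0.1).mean_kernel
        order = rng.permutation(9)
        b = hd.pool_hrfs([ests[i] for i in order], 0.1).mean_kernel
        assert_allclose(a, b)

    def test_mixed_lengths_rejected(self):
        ests = self._estimates([np.zeros(10), np.zeros(20)])
        with pytest.raises(ValidationError):
            hd.pool_hrfs(ests, 0.1)


class TestScaleHRF:
    def _h(self, kernel):
        return hd.HRFEstimate(
            kernel=np.asarray(kernel, float), duration_s=len(kernel) / 10.0, sfreq=10.0
        )

    def test_positive_peak(self):
        out = hd.scale_hrf(self._h([0, 2, -1]))
        assert_allclose(out.kernel, [0, 1, -0.5], atol=1e-6)

    def test_idempotent_within_eps(self):
        h = hd.scale_hrf(self._h([0.0, 5.0, -2.0, 1.0]))
        twice = hd.scale_hrf(h)
        assert np.max(np.abs(twice.kernel - h.kernel)) < 1e-6

    def test_peak_in_unit_band(self, rng):
        for _ in range(10):
            out = hd.scale_hrf(self._h(np.abs(rng.normal(size=12)) + 0.1))
            assert 1 - 1e-6 <= out.kernel.max() <= 1

    def test_negative_going_hbr_scaled_by_trough(self):
        out = hd.scale_hrf(self._h([0.0, -4.0, -1.0, 0.0]))
        assert_allclose(out.kernel.min(), -1, atol=1e-6)
        assert out.kernel.max() <= 0

    def test_all_zero_kernel_degenerate(self):
        with pytest.raises(DegenerateHRFError):
            hd.scale_hrf(self._h([0.0, 0.0, 0.0, 0.0]))


class TestEstimateActivity:
    @pytest.fixture(scope="class")
    def spike_setup(self):
        rng = np.random.default_rng(3)
        n = 3000
        h = hd.double_gamma_hrf()
        idx = (np.arange(10) * 270 + 100 + rng.integers(0, 40, 10)).astype(int)
        spikes = np.zeros(n)
        spikes[idx] = np.tile([1.0, -1.0], 5)
        y = np.convolve(spikes, h.kernel)[:n]
        rec = hd.ChannelRecording("c", "hbo", 10.0, y, [0, 0, 0])
        return rec, h, spikes, idx

    def test_recovers_spike_train_at_small_lam(self, spike_setup):
        rec, h, spikes, _ = spike_setup
        act = hd.estimate_activity(rec, h, hd.DeconvConfig(lam=1e-6, cond_threshold=1e15))
        assert pearsonr(act, spikes)[0] > 0.8

    def test_activity_peaks_align_with_onsets(self, spike_setup):
        rec, h, spikes, idx = spike_setup
        act = hd.estimate_activity(rec, h, hd.DeconvConfig(lam=0.01, cond_threshold=1e15))
        for i in idx:
            window = act[i - 10 : i + 11] * np.sign(spikes[i])
            assert abs(int(np.argmax(window)) - 10) <= 1

    def test_output_length_and_shrinkage_monotonicity(self, spike_setup):
        rec, h, _, _ = spike_setup
        norms = []
        for lam in (1e-4, 1e-2, 1.0):
            act = hd.estimate_activity(rec, h, hd.DeconvConfig(lam=lam, cond_threshold=1e15))
            assert act.size == rec.n_samples
            norms.append(np.linalg.norm(act))
        assert norms[0] >= norms[1] >= norms[2]

    def test_unscaled_hrf_rejected(self, spike_setup):
        rec, h, _, _ = spike_setup
        bad = hd.HRFEstimate(kernel=h.kernel * 3, duration_s=h.duration_s, sfreq=h.sfreq)
        with pytest.raises(ValidationError):
            hd.estimate_activity(rec, bad, hd.DeconvConfig())

    def test_roundtrip_residual_noiseless(self, spike_setup):
        rec, h, _, _ = spike_setup
        act = hd.estimate_activity(rec, h, hd.DeconvConfig(lam=1e-6, cond_threshold=1e15))
        yz = hd.zscore(rec.samples)
        recon = np.convolve(act, h.kernel)[: rec.n_samples]
        assert np.linalg.norm(recon - yz) / np.linalg.norm(yz) < 1e-3
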