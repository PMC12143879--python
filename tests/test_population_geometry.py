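import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter1d

from dualpop.population_geometry import (
    N_ROWS,
    cca_align,
    lag_scan,
    per_neuron_onset,
    pls_svd,
    population_onset,
    premovement_variance_fraction,
    shifted_time_control,
    trial_average_matrix,
)
from dualpop.synthetic_data import SynthConfig, generate_session
from dualpop.trialdata import session_rates


def _qualifying_trials(n=16, spacing=3000.0, t0=2000.0):
    onsets = t0 + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "reach_onset_ms": onsets,
            "onset_ms": onsets,
            "grasp_ms": onsets + 300.0,
            "spout": (np.arange(n) % 4) + 1,
        }
    )


def _smooth_rates(rng, n_units, T, sd=20.0):
    return gaussian_filter1d(rng.normal(10, 3, (n_units, T)), sd, axis=1)


class TestTrialAverageMatrix:
    def test_1600_rows(self, rng):
        trials = _qualifying_trials()
        rates = _smooth_rates(rng, 5, 60000)
        X = trial_average_matrix(rates, trials)
        assert X.values.shape == (N_ROWS, 5)
        assert X.values.shape[0] == 8 * 200

    def test_constant_neuron_constant_column(self, rng):
        trials = _qualifying_trials()
        rates = _smooth_rates(rng, 3, 60000)
        rates[1] = 7.5
        X = trial_average_matrix(rates, trials)
        assert np.allclose(X.values[:, 1], 7.5)

    def test_single_trial_reproduces_segments(self, rng):
        trials = _qualifying_trials(4)  # one per spout
        rates = _smooth_rates(rng, 3, 20000)
        X = trial_average_matrix(rates, trials)
        ev = int(trials["reach_onset_ms"].iloc[0])
        np.testing.assert_allclose(
            X.values[:200], rates[:, ev - 99 : ev + 101].T
        )

    def test_missing_spout_errors(self, rng):
        trials = _qualifying_trials(8)
        trials["spout"] = 1
        rates = _smooth_rates(rng, 3, 40000)
        with pytest.raises(ValueError, match="spout 2"):
            trial_average_matrix(rates, trials)


class TestCCA:
    def test_identity_all_correlations_one(self, rng):
        X = rng.normal(size=(400, 30))
        res = cca_align(X, X.copy(), k=25)
        np.testing.assert_allclose(res.pair_correlation, 1.0, atol=1e-8)

    def test_rotation_invariance(self, rng):
        X = rng.normal(size=(400, 30))
        Q, _ = np.linalg.qr(rng.normal(size=(30, 30)))
        res = cca_align(X, X @ Q, k=25)
        np.testing.assert_allclose(res.pair_correlation, 1.0, atol=1e-8)

    def test_independent_noise_low_correlation(self, rng):
        A = rng.normal(size=(1600, 40))
        B = rng.normal(size=(1600, 40))
        matched = cca_align(A, A + 0.1 * rng.normal(size=A.shape), k=25)
        indep = cca_align(A, B, k=25)
        # null level for two independent pairs is the chance baseline
        C = rng.normal(size=(1600, 40))
        baseline = cca_align(A, C, k=25).weighted_mean_correlation
        assert indep.weighted_mean_correlation < 0.3
        assert abs(indep.weighted_mean_correlation - baseline) < 0.1
        assert matched.weighted_mean_correlation > 0.9

    def test_low_rank_reduces_k_with_warning(self, rng):
        X = rng.normal(size=(100, 10))
        with pytest.warns(UserWarning, match="rank"):
            res = cca_align(X, X, k=25)
        assert res.pair_correlation.size <= 10

    def test_orthogonalized_capture_bounded_by_pca(self, rng):
        A = gaussian_filter1d(rng.normal(size=(800, 30)), 10, axis=0)
        B = gaussian_filter1d(rng.normal(size=(800, 30)), 10, axis=0)
        res = cca_align(A, B, k=20)
        assert np.all(
            res.cumulative_capture_a <= np.cumsum(res.pca_capture_a) + 1e-9
        )


class TestPLS:
    def test_identity_c_half(self, rng):
        X = rng.normal(size=(300, 20))
        res = pls_svd(X, X.copy())
        assert res.c == pytest.approx(0.5, abs=1e-12)

    def test_sign_symmetry(self, rng):
        X = rng.normal(size=(300, 20))
        assert pls_svd(X, -X).c == pytest.approx(0.5, abs=1e-12)

    def test_independent_noise_small_c(self, rng):
        # 20 columns: the nuclear norm of a random cross-covariance grows
        # with column count, so the sub-10% null level requires a modest
        # neuron count relative to the 1600 rows
        A = rng.normal(size=(1600, 20))
        B = rng.normal(size=(1600, 20))
        c_matched = pls_svd(A, A + 0.05 * rng.normal(size=A.shape)).c
        c_null = pls_svd(A, B).c
        assert c_null < 0.1 * c_matched

    def test_c_bounded_by_half_property(self, rng):
        for _ in range(10):
            A = rng.normal(size=(150, rng.integers(5, 30)))
            B = rng.normal(size=(150, rng.integers(5, 30)))
            assert pls_svd(A, B).c <= 0.5 + 1e-12

    def test_projection_covariance_is_diag_s(self, rng):
        A = rng.normal(size=(200, 15))
        B = rng.normal(size=(200, 12))
        res = pls_svd(A, B)
        Ac = A - A.mean(axis=0)
        Bc = B - B.mean(axis=0)
        got = np.diag((Ac @ res.weights_a).T @ (Bc @ res.weights_b))
        np.testing.assert_allclose(got, res.pair_covariance, rtol=1e-9)


class TestLagScan:
    def test_self_alignment_peaks_at_zero(self, rng):
        trials = _qualifying_trials(16)
        rates = _smooth_rates(rng, 20, 60000)
        scan = lag_scan(rates, rates, trials, lags_ms=np.arange(-15, 16, 3), k=10)
        best = scan.loc[scan["pls_c"].idxmax(), "lag_ms"]
        assert best == 0.0

    def test_delayed_copy_peaks_at_delay(self, rng):
        trials = _qualifying_trials(16)
        rates = _smooth_rates(rng, 20, 60000)
        delayed = np.roll(rates, 10, axis=1)  # B lags A by 10 ms
        scan = lag_scan(rates, delayed, trials, lags_ms=np.arange(-20, 21, 2), k=10)
        best_pls = scan.loc[scan["pls_c"].idxmax(), "lag_ms"]
        best_cca = scan.loc[scan["cca_weighted_corr"].idxmax(), "lag_ms"]
        assert abs(best_pls - 10.0) <= 2.0
        assert abs(best_cca - 10.0) <= 2.0

    def test_generator_shared_latent_delay_recovered(self):
        cfg = SynthConfig(
            n_units_per_region=25,
            n_trials=64,
            n_across_latents=1,
            n_within_latents=0,
            latent_delays=(-12.0,),
            latent_timescales=30.0,
            loading_scale=12.0,
            event_amplitude=8.0,
            event_lead_ms=12.0,
            seed=71,
        )
        bundle, _ = generate_session(cfg)
        rates = session_rates(bundle)
        trials = bundle.trials.copy()
        trials["onset_ms"] = trials["reach_onset_ms"]
        idx_a, idx_b = bundle.units_in("A"), bundle.units_in("B")
        scan = lag_scan(
            rates[idx_a], rates[idx_b], trials, lags_ms=np.arange(-24, 25, 2), k=15
        )
        best = scan.loc[scan["pls_c"].idxmax(), "lag_ms"]
        assert abs(best - 12.0) <= 2.0


class TestShiftedControl:
    def test_control_destroys_alignment(self, rng):
        cfg = SynthConfig(
            n_units_per_region=20,
            n_trials=60,
            loading_scale=2.0,
            event_amplitude=20.0,
            event_center_ms=0.0,  # bump inside the alignment segments
            seed=73,
        )
        bundle, truth = generate_session(cfg)
        rates = session_rates(bundle)
        trials = bundle.trials.copy()
        trials["onset_ms"] = trials["reach_onset_ms"]
        idx_a, idx_b = bundle.units_in("A"), bundle.units_in("B")
        X_a = trial_average_matrix(rates[idx_a], trials, region="A")
        X_b = trial_average_matrix(rates[idx_b], trials, region="B")
        X_b_ctrl = shifted_time_control(rates[idx_b], trials, region="B", seed=1)
        c_true = pls_svd(X_a, X_b).c
        c_ctrl = pls_svd(X_a, X_b_ctrl).c
        assert c_ctrl < 0.5 * c_true
        # shifted epochs land between trials: per-neuron means track the
        # units' baseline rates in expectation
        assert np.allclose(
            X_b_ctrl.values.mean(axis=0), truth.baselines["B"], rtol=0.5, atol=2.0
        )

    def test_no_placement_raises(self, rng):
        trials = _qualifying_trials(8, spacing=1200.0)
        rates = _smooth_rates(rng, 4, 14000)  # too short for 5-10 s shifts
        with pytest.raises(RuntimeError):
            shifted_time_control(rates, trials, seed=0)


class TestOnsets:
    def test_step_onset_recovered(self, rng):
        t = np.arange(-200.0, 200.0)
        X = np.full((t.size, 12), 5.0) + rng.normal(0, 1e-4, (t.size, 12))
        X[t >= 20.0] += 4.0
        onset, _ = population_onset(X, t)
        assert abs(onset - 20.0) <= 2.0

    def test_flat_activity_missing(self, rng):
        t = np.arange(-200.0, 200.0)
        X = np.full((t.size, 5), 3.0) + rng.normal(0, 1e-6, (t.size, 5))
        onset, _ = population_onset(X, t)
        assert np.isnan(onset)

    def test_generator_lead_recovered(self):
        # trial-averaged generating intensities: the 11-SD rule on a 50 ms
        # baseline is too noise-sensitive for desk-scale spike counts, so
        # recovery is checked on the generator's rate functions
        from dualpop.synthetic_data.latents import generate_latents
        from dualpop.synthetic_data.spikes import (
            draw_baselines,
            draw_event_amplitudes,
            draw_loadings,
            intensity_matrices,
        )

        cfg = SynthConfig(
            n_units_per_region=30,
            n_trials=5,
            trial_window=(-200.0, 400.0),
            loading_scale=0.0,
            event_amplitude=10.0,
            event_lead_ms=50.0,
            event_center_ms=200.0,
            event_sd_ms=30.0,
            baseline_rate_range=(6.0, 12.0),
            seed=79,
        )
        lat = generate_latents(cfg)
        r = np.random.default_rng(5)
        intens = intensity_matrices(
            lat,
            draw_loadings(cfg, r),
            draw_baselines(cfg, r),
            cfg,
            draw_event_amplitudes(cfg, r),
        )
        t = np.arange(-200.0, 400.0)
        noise = np.random.default_rng(105)
        onsets = {}
        for region in ("A", "B"):
            # matched estimation noise in both regions
            avg = intens[region].mean(axis=0).T + noise.normal(0, 0.05, (600, 30))
            onsets[region], _ = population_onset(avg, t)
        lead = onsets["B"] - onsets["A"]
        assert abs(lead - 50.0) <= 10.0

    def test_higher_threshold_variant(self, rng):
        t = np.arange(-200.0, 200.0)
        X = np.full((t.size, 6), 5.0) + rng.normal(0, 1e-3, (t.size, 6))
        X[t >= 0.0] += np.linspace(0, 5, (t >= 0).sum())[:, None]
        _, thr = population_onset(X, t)
        # a much higher absolute threshold (as when applying the higher of
        # two regions' thresholds to both) crosses later on the ramp
        onset_hi, _ = population_onset(X, t, abs_threshold=max(200 * thr, 1.0))
        onset_lo, _ = population_onset(X, t, abs_threshold=thr)
        assert onset_hi > onset_lo


class TestPremovementVariance:
    def test_post_only_zero(self):
        t = np.arange(-150.0, 150.0)
        X = np.zeros((t.size, 4))
        X[t >= 0] = np.sin(t[t >= 0] / 20.0)[:, None]
        assert premovement_variance_fraction(X, t) == pytest.approx(0.0, abs=1e-12)

    def test_pre_only_one(self):
        t = np.arange(-150.0, 150.0)
        X = np.zeros((t.size, 4))
        X[t < 0] = np.cos(t[t < 0] / 15.0)[:, None]
        assert premovement_variance_fraction(X, t) == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_half(self, rng):
        t = np.arange(-150.0, 150.0)
        fracs = [
            premovement_variance_fraction(rng.normal(size=(t.size, 30)), t)
            for _ in range(20)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.05


class TestPerNeuronOnset:
    def test_step_neuron_recovered(self, rng):
        t = np.arange(-200.0, 200.0)
        X = np.full((t.size, 10), 2.0) + rng.normal(0, 1e-4, (t.size, 10))
        X[t >= 30.0, 4] += 5.0
        rates = np.ones(10)
        rates[4] = 50.0
        onsets = per_neuron_onset(X, t, rates, rate_percentile=80)
        assert abs(onsets[4] - 30.0) <= 2.0

    def test_flat_neuron_missing(self, rng):
        t = np.arange(-200.0, 200.0)
        X = np.full((t.size, 5), 2.0) + rng.normal(0, 1e-6, (t.size, 5))
        rates = np.array([1.0, 1.0, 1.0, 1.0, 9.0])
        onsets = per_neuron_onset(X, t, rates, rate_percentile=75)
        assert np.isnan(onsets[4]) or np.isnan(onsets).all()

    def test_low_rate_neurons_skipped(self, rng):
        t = np.arange(-200.0, 200.0)
        X = rng.normal(size=(t.size, 4))
        rates = np.array([1.0, 2.0, 3.0, 10.0])
        onsets = per_neuron_onset(X, t, rates, rate_percentile=90)
        assert np.isnan(onsets[:3]).all()
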