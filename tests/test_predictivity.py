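import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from dualpop.predictivity import (
    CCMParams,
    binarize,
    ccm_skill,
    circular_perm_pvalue,
    concatenate_epochs,
    false_null_fraction,
    match_rate_distributions,
    movement_epochs,
    pp_granger,
    prune_low_rate_pairs,
    simplex_optimal_E,
    top_pairs,
    transfer_entropy,
)


def _unit_table(rates_a, rates_b, session=0):
    rows = []
    for region, rates in (("A", rates_a), ("B", rates_b)):
        for i, r in enumerate(rates):
            rows.append(
                {
                    "unit_id": f"{region}{i}",
                    "region": region,
                    "session": session,
                    "mean_rate": r,
                    "width_class": "wide",
                    "peak_sign": -1,
                }
            )
    return pd.DataFrame(rows)


class TestTopPairs:
    def test_two_units_one_pair(self):
        tab = _unit_table([5.0], [7.0])
        pairs = top_pairs(tab, n=100)
        assert len(pairs) == 1
        assert pairs["product"].iloc[0] == pytest.approx(35.0)

    def test_rank_invariant_to_rescaling(self, rng):
        ra, rb = rng.uniform(1, 30, 6), rng.uniform(1, 30, 6)
        p1 = top_pairs(_unit_table(ra, rb), n=10)
        p2 = top_pairs(_unit_table(3 * ra, 3 * rb), n=10)
        assert list(p1["unit_A"]) == list(p2["unit_A"])
        assert list(p1["unit_B"]) == list(p2["unit_B"])

    def test_matches_bruteforce_ranking(self, rng):
        ra, rb = rng.uniform(1, 30, 5), rng.uniform(1, 30, 4)
        pairs = top_pairs(_unit_table(ra, rb), n=8)
        brute = sorted(
            ((a * b, i, j) for i, a in enumerate(ra) for j, b in enumerate(rb)),
            reverse=True,
        )[:8]
        got = list(zip(pairs["unit_A"], pairs["unit_B"]))
        want = [(f"A{i}", f"B{j}") for _, i, j in brute]
        assert got == want


class TestMatchRates:
    def test_already_matched_zero_swaps(self):
        rates = [5.0, 10.0, 20.0]
        tab = _unit_table(rates, rates)
        pairs = top_pairs(tab, n=3)
        out = match_rate_distributions(pairs, tab, seed=0)
        assert out.attrs["n_swaps"] == 0

    def test_constructed_mismatch_resolved(self):
        # A-side rates all high; same-session replacements exist in the
        # B-side bins
        tab = _unit_table([20.0, 20.0, 5.0, 5.0], [5.0, 5.0, 20.0, 20.0])
        pairs = pd.DataFrame(
            {
                "session": [0, 0],
                "unit_A": ["A0", "A1"],
                "unit_B": ["B0", "B1"],
                "rate_A": [20.0, 20.0],
                "rate_B": [5.0, 5.0],
                "product": [100.0, 100.0],
            }
        )
        out = match_rate_distributions(pairs, tab, seed=1)
        from dualpop.predictivity.pairs import _bin_index

        ba = np.sort(_bin_index(out["rate_A"].to_numpy()))
        bb = np.sort(_bin_index(out["rate_B"].to_numpy()))
        np.testing.assert_array_equal(ba, bb)
        assert out.attrs["n_swaps"] > 0

    def test_terminates_without_replacements(self):
        # no same-session A cells in the B bins: no legal swap
        tab = _unit_table([20.0, 25.0], [5.0, 6.0])
        pairs = top_pairs(tab, n=4)
        out = match_rate_distributions(pairs, tab, seed=2)
        assert out.attrs["n_swaps"] == 0
        assert len(out) == len(pairs)


class TestMovementEpochs:
    def test_square_wave_exact_boundaries(self):
        env = np.zeros(5000)
        env[1000:1500] = 10.0
        env[3000:3800] = 10.0
        eps = movement_epochs(env, quiescent_mean=0.0, quiescent_sd=0.1)
        assert eps == [(1000, 1500), (3000, 3800)]

    def test_all_quiescent_errors(self):
        with pytest.raises(ValueError):
            movement_epochs(np.zeros(2000), 0.0, 0.1)

    def test_gap_merging_boundary(self):
        env = np.zeros(5000)
        env[1000:1200] = 10.0
        env[1290:1500] = 10.0  # 90 ms dip: merged
        env[3000:3200] = 10.0
        env[3320:3500] = 10.0  # 120 ms dip: split
        eps = movement_epochs(env, 0.0, 0.1)
        assert (1000, 1500) in eps
        assert (3000, 3200) in eps and (3320, 3500) in eps

    def test_short_epoch_dropped(self):
        env = np.zeros(3000)
        env[1000:1005] = 10.0  # 5 ms: dropped
        env[2000:2100] = 10.0
        eps = movement_epochs(env, 0.0, 0.1)
        assert eps == [(2000, 2100)]

    def test_concatenation_pads(self):
        spikes = np.array([1.0501, 2.0002])  # inside the two epochs
        train = concatenate_epochs(spikes, [(1000, 1100), (2000, 2100)], pad_ms=50)
        assert train.size == 100 + 50 + 100
        assert train[50] == 1  # 1050.1 ms -> index 50 in epoch 1
        assert train[150] == 1  # epoch 2 starts at 100 + 50


def _entropy_bits(p):
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


class TestTransferEntropy:
    def test_deterministic_copy(self, rng):
        src = (rng.uniform(size=200_000) < 0.2).astype(np.int8)
        tgt = np.roll(src, 7)
        te, best, _ = transfer_entropy(src, tgt)
        assert best == 7
        assert te == pytest.approx(_entropy_bits(0.2), rel=0.02)

    def test_independent_at_bias_level(self, rng):
        src = (rng.uniform(size=20_000) < 0.05).astype(np.int8)
        tgt = (rng.uniform(size=20_000) < 0.05).astype(np.int8)
        metric = lambda s, t: transfer_entropy(s, t)[0]
        res = circular_perm_pvalue(metric, src, tgt, n_perm=60, seed=0)
        assert abs(res["observed"] - res["null_mean"]) < 3 * res["null_sd"]

    def test_markov_chain_closed_form(self):
        rng = np.random.default_rng(5)
        n = 1_000_000
        pj = 0.4
        p_table = np.array([[0.05, 0.5], [0.1, 0.7]])  # p(i=1 | i_t, j)
        d_true = 3
        j = (rng.uniform(size=n) < pj).astype(np.int8)
        i = np.zeros(n, dtype=np.int8)
        u = rng.uniform(size=n)
        for t in range(d_true, n - 1):
            i[t + 1] = u[t] < p_table[i[t], j[t + 1 - d_true]]
        te, best, _ = transfer_entropy(j, i)

        # independent oracle: enumerate the stationary joint distribution
        a = (1 - pj) * p_table[0, 0] + pj * p_table[0, 1]
        b = (1 - pj) * p_table[1, 0] + pj * p_table[1, 1]
        pi1 = a / (1 + a - b)
        te_exact = 0.0
        for h, pih in ((0, 1 - pi1), (1, pi1)):
            p_marg = (1 - pj) * p_table[h, 0] + pj * p_table[h, 1]
            for s, ps in ((0, 1 - pj), (1, pj)):
                for x in (0, 1):
                    pxs = p_table[h, s] if x else 1 - p_table[h, s]
                    pxm = p_marg if x else 1 - p_marg
                    te_exact += pih * ps * pxs * np.log2(pxs / pxm)
        assert best == d_true
        assert te == pytest.approx(te_exact, rel=0.05)

    def test_binarize_roundtrip(self):
        train = binarize(np.array([0.0015, 0.5004]), 1.0)
        assert train.sum() == 2
        assert train[1] == 1 and train[500] == 1


class TestCircularPermutation:
    def test_coupled_pair_minimal_p(self, rng):
        src = (rng.uniform(size=20_000) < 0.1).astype(np.int8)
        tgt = np.roll(src, 5)
        metric = lambda s, t: transfer_entropy(s, t)[0]
        res = circular_perm_pvalue(metric, src, tgt, n_perm=50, seed=1)
        assert res["p_raw"] == 0.0
        assert res["p"] == pytest.approx(1 / 51)

    def test_shift_preserves_counts(self, rng):
        src = (rng.uniform(size=10_000) < 0.1).astype(np.int8)
        assert np.roll(src, 4321).sum() == src.sum()

    def test_short_series_rejected(self, rng):
        src = np.zeros(5000, dtype=np.int8)
        with pytest.raises(ValueError):
            circular_perm_pvalue(lambda s, t: 0.0, src, src)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _simulate_ensemble(rng, n_units=3, n_trials=20, T=600, couple=None):
    """Binary point-process ensemble; couple=(src, tgt, lag, weight)."""
    base = -4.0  # ~ 18 spikes/s
    bump = 1.2 * np.exp(-0.5 * ((np.arange(T) - 300) / 80.0) ** 2)
    trains = np.zeros((n_units, n_trials, T), dtype=np.int8)
    for tr in range(n_trials):
        for t in range(T):
            for u in range(n_units):
                drive = base + bump[t]
                if couple is not None and u == couple[1] and t >= couple[2]:
                    drive += couple[3] * trains[couple[0], tr, t - couple[2]]
                trains[u, tr, t] = rng.uniform() < _sigmoid(drive)
    return trains


class TestGranger:
    def test_true_coupling_detected(self):
        rng = np.random.default_rng(11)
        trains = _simulate_ensemble(rng, couple=(0, 1, 5, 3.0))
        res = pp_granger(
            trains, n_trials=20, exog_bins_ms=(25,), seed=0
        ).set_index(["source", "target"])
        assert res.loc[(0, 1), "p"] < 0.01
        assert res.loc[(1, 0), "p"] > 0.01  # reverse direction null

    def test_null_stat_near_df(self):
        rng = np.random.default_rng(12)
        trains = _simulate_ensemble(rng)
        res = pp_granger(trains, n_trials=20, exog_bins_ms=(25,), seed=0)
        ok = res[res["excluded"] == ""]
        assert ok["stat"].between(5, 80).all()  # chi2(30)-scale values

    def test_prune_low_rate_pairs(self):
        res = pd.DataFrame({"p": [0.99, 0.99, 0.2], "stat": [1.0, 1.0, 40.0]})
        products = np.array([0.3, 50.0, 10.0])
        out = prune_low_rate_pairs(res, products)
        # only the low-rate p>0.95 pair is dropped
        assert len(out) == 2
        assert set(out["stat"]) == {1.0, 40.0}


class TestSimplexAndCCM:
    def test_sine_small_E_high_skill(self):
        t = np.arange(3000)
        y = np.sin(2 * np.pi * t / 90.0)
        E, skills = simplex_optimal_E(y, E_candidates=range(1, 8))
        assert E <= 3
        assert max(skills.values()) > 0.99

    def test_white_noise_no_skill(self, rng):
        y = rng.normal(size=3000)
        _, skills = simplex_optimal_E(y, E_candidates=range(1, 6))
        assert max(skills.values()) < 0.2

    def test_logistic_map_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        y = np.empty(2000)
        y[0] = 0.4
        for t in range(1999):
            y[t + 1] = 3.9 * y[t] * (1 - y[t])
        E, _ = simplex_optimal_E(y, E_candidates=range(1, 6))

        def brute_skill(series, E):
            pts = np.stack([series[:-1][E - 1 - k : len(series) - 1 - k] for k in range(E)], axis=1)
            targets = series[E:]
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            idx = np.argsort(d, axis=1)[:, : E + 1]
            dd = np.take_along_axis(d, idx, axis=1)
            w = np.exp(-dd / np.maximum(dd[:, :1], 1e-12))
            w /= w.sum(axis=1, keepdims=True)
            pred = (w * targets[idx]).sum(axis=1)
            return np.corrcoef(pred, targets)[0, 1]

        series = y[:400]
        brute = {E_: brute_skill(series, E_) for E_ in range(1, 6)}
        E_small, _ = simplex_optimal_E(series, E_candidates=range(1, 6))
        assert E_small == max(brute, key=brute.get)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            simplex_optimal_E(np.ones(500))

    def _coupled_maps(self, n=6000, beta=0.32):
        x = np.empty(n)
        y = np.empty(n)
        x[0], y[0] = 0.4, 0.2
        for t in range(n - 1):
            x[t + 1] = x[t] * (3.8 - 3.8 * x[t])  # autonomous driver
            y[t + 1] = y[t] * (3.5 - 3.5 * y[t] - beta * x[t])  # driven
        return x, y

    def test_unidirectional_coupling_sign_pattern(self):
        x, y = self._coupled_maps()
        trials_x = [x[i : i + 200] for i in range(1000, 5800, 200)]
        trials_y = [y[i : i + 200] for i in range(1000, 5800, 200)]
        params = CCMParams(E=3, K=4, delay_grid_ms=(0,), n_trials=20)
        # driver x cross-mapped from driven y's manifold: high skill
        fwd = ccm_skill(trials_x, trials_y, params, seed=0)["skill"]
        rev = ccm_skill(trials_y, trials_x, params, seed=0)["skill"]
        assert fwd > 0.8
        assert fwd > rev + 0.2

    def test_self_target_near_perfect(self, rng):
        trials = [
            gaussian_filter1d(rng.normal(size=300), 10) for _ in range(10)
        ]
        res = ccm_skill(trials, trials, CCMParams(n_trials=10), seed=0)
        # zero-delay self-prediction is essentially perfect; smoothness can
        # leave nearby delays within rounding of it
        assert res["curve"][0] > 0.98
        assert res["skill"] > 0.98

    def test_independent_noise_low_skill(self, rng):
        a = [gaussian_filter1d(rng.normal(size=300), 10) for _ in range(10)]
        b = [gaussian_filter1d(rng.normal(size=300), 10) for _ in range(10)]
        res = ccm_skill(a, b, CCMParams(n_trials=10), seed=0)
        assert res["skill"] < 0.4


class TestFalseNullFraction:
    def test_uniform_p_near_zero(self, rng):
        p = rng.uniform(size=10_000)
        out = false_null_fraction(p)
        assert abs(out["false_null_fraction"]) < 0.05

    def test_all_zero_p_near_one(self):
        p = np.zeros(500)
        out = false_null_fraction(p)
        assert out["false_null_fraction"] == pytest.approx(1.0, abs=0.01)

    def test_known_mixture(self, rng):
        p = np.concatenate(
            [rng.uniform(size=7000), rng.beta(0.05, 10.0, size=3000)]
        )
        out = false_null_fraction(p)
        assert out["false_null_fraction"] == pytest.approx(0.30, abs=0.05)

    def test_fdr_threshold_monotone(self, rng):
        p = np.concatenate([rng.uniform(size=500), np.full(100, 1e-4)])
        out = false_null_fraction(p, fdr=0.10)
        assert out["fdr_threshold"] >= 1e-4
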