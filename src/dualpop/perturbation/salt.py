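"""Modified stimulus-associated spike-latency test.

First-spike-latency histograms (1 ms resolution, 5 ms windows) are built
for the post-light test epoch and for many baseline epochs drawn from
non-stimulus periods. Jensen-Shannon divergences between the test histogram
and each baseline histogram form the observed set; the null is built from
baseline-vs-baseline divergences. The p-value is the rank of ONE randomly
sampled test-vs-baseline divergence within the null — this replaces the
original method's median step, which does not give uniform p-values under
the null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WINDOW_MS = 5.0
RESOLUTION_MS = 1.0
MIN_SEP_MS = 500.0
BASELINE_FACTOR = 10
N_NULL = 1000


def _latency_histogram(
    spikes_ms: np.ndarray, epoch_starts_ms: np.ndarray, window_ms: float, res_ms: float
) -> np.ndarray:
    """First-spike-latency histogram over epochs; last bin counts no-spike."""
    n_bins = int(round(window_ms / res_ms))
    starts = np.asarray(epoch_starts_ms, dtype=float)
    if spikes_ms.size == 0:
        hist = np.zeros(n_bins + 1)
        hist[-1] = 1.0
        return hist
    idx = np.searchsorted(spikes_ms, starts)
    first = np.full(starts.size, n_bins)  # last bin = no spike in window
    has = idx < spikes_ms.size
    lat = np.where(has, spikes_ms[np.minimum(idx, spikes_ms.size - 1)] - starts, np.inf)
    in_win = lat < window_ms
    first[in_win] = (lat[in_win] // res_ms).astype(int)
    hist = np.bincount(first, minlength=n_bins + 1).astype(float)
    return hist / hist.sum()


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def salt_modified(
    spike_times_s: list[np.ndarray],
    light_onsets_s: np.ndarray,
    duration_s: float,
    window_ms: float = WINDOW_MS,
    resolution_ms: float = RESOLUTION_MS,
    baseline_factor: int = BASELINE_FACTOR,
    n_null: int = N_NULL,
    min_sep_ms: float = MIN_SEP_MS,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-neuron p-value for a direct effect of light on spike latency.

    Parameters
    ----------
    spike_times_s
        One spike-time array (seconds) per neuron.
    light_onsets_s
        Light-onset times; at least 50 events are required.
    duration_s
        Session duration; baseline epochs are drawn at least
        ``min_sep_ms`` away from any light onset.

    Returns
    -------
    DataFrame with columns neuron, p (NaN when the neuron never spikes in
    any epoch, in which case it is excluded from inference).
    """
    onsets_ms = np.sort(np.asarray(light_onsets_s, dtype=float)) * 1000.0
    if onsets_ms.size < 50:
        raise ValueError("need at least 50 light events")
    rng = np.random.default_rng(seed)

    n_events = onsets_ms.size
    n_baseline_epochs = baseline_factor * n_events
    candidates = []
    total_ms = duration_s * 1000.0
    while len(candidates) < n_baseline_epochs:
        t = rng.uniform(0.0, total_ms - window_ms, size=n_baseline_epochs)
        sep = np.min(np.abs(t[:, None] - onsets_ms[None, :]), axis=1)
        candidates.extend(t[sep >= min_sep_ms].tolist())
    baseline_starts = np.array(candidates[:n_baseline_epochs])
    baseline_groups = baseline_starts.reshape(baseline_factor, n_events)

    rows = []
    for i, st in enumerate(spike_times_s):
        sp = np.asarray(st, dtype=float) * 1000.0
        test_hist = _latency_histogram(sp, onsets_ms, window_ms, resolution_ms)
        base_hists = [
            _latency_histogram(sp, grp, window_ms, resolution_ms)
            for grp in baseline_groups
        ]
        n_spk = test_hist[:-1].sum() + sum(h[:-1].sum() for h in base_hists)
        if n_spk == 0:
            rows.append({"neuron": i, "p": np.nan})
            continue
        obs_divs = np.array([_js_divergence(test_hist, b) for b in base_hists])
        obs = rng.choice(obs_divs)
        pair_divs = np.array(
            [
                _js_divergence(base_hists[a], base_hists[b])
                for a in range(baseline_factor)
                for b in range(a + 1, baseline_factor)
            ]
        )
        null = pair_divs[rng.integers(0, pair_divs.size, size=n_null)]
        p = (1.0 + np.sum(null >= obs)) / (n_null + 1.0)
        rows.append({"neuron": i, "p": p})
    return pd.DataFrame(rows)
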