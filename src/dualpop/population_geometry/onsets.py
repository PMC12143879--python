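"""Population and single-neuron activity-onset timing."""

from __future__ import annotations

import numpy as np

BASELINE_MS = (-150.0, -100.0)
K_SD = 11.0
VAR_THRESHOLD = 0.95


def population_onset(
    trial_avg: np.ndarray,
    time_ms: np.ndarray,
    var_threshold: float = VAR_THRESHOLD,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    k_sd: float = K_SD,
    abs_threshold: float | None = None,
) -> tuple[float, float]:
    """Onset of population activity change from a pre-reach baseline.

    Projects the trial-averaged activity (time x neurons) onto the top
    principal components capturing at least ``var_threshold`` of the
    variance, sums the absolute deviation from the baseline-epoch mean
    across those components, and reports the first time after the baseline
    epoch at which that summed deviation exceeds baseline mean + 11 SD
    (or ``abs_threshold`` when provided — used to apply the higher of two
    regions' thresholds to both).

    Returns (onset_ms, threshold); onset is NaN when never crossed.
    """
    X = np.asarray(trial_avg, dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    frac = np.cumsum(s**2) / np.sum(s**2)
    k = int(np.searchsorted(frac, var_threshold) + 1)
    proj = X @ Vt[:k].T  # (T, k)

    base = (time_ms >= baseline_ms[0]) & (time_ms < baseline_ms[1])
    if not base.any():
        raise ValueError("baseline window outside the supplied time axis")
    dev = np.abs(proj - proj[base].mean(axis=0)).sum(axis=1)

    thr = (
        abs_threshold
        if abs_threshold is not None
        else float(dev[base].mean() + k_sd * dev[base].std(ddof=0))
    )
    after = time_ms >= baseline_ms[1]
    crossed = np.flatnonzero(after & (dev > thr))
    onset = float(time_ms[crossed[0]]) if crossed.size else float("nan")
    return onset, thr


def premovement_variance_fraction(
    trial_avg: np.ndarray,
    time_ms: np.ndarray,
    muscle_onset_ms: float = 0.0,
    half_window_ms: float = 150.0,
) -> float:
    """Fraction of activity variance occurring before muscle onset.

    Summed (across neurons) squared deviation from each window's own mean,
    in the 150 ms before onset, divided by the same quantity over the full
    +/-150 ms window split at onset. White-noise activity gives ~0.5;
    activity confined to after onset gives 0.
    """
    X = np.asarray(trial_avg, dtype=float)
    pre = (time_ms >= muscle_onset_ms - half_window_ms) & (time_ms < muscle_onset_ms)
    post = (time_ms >= muscle_onset_ms) & (time_ms < muscle_onset_ms + half_window_ms)
    if not pre.any() or not post.any():
        raise ValueError("window extends beyond the supplied time axis")

    def _ss(mask):
        seg = X[mask]
        return ((seg - seg.mean(axis=0)) ** 2).sum()

    ss_pre, ss_post = _ss(pre), _ss(post)
    total = ss_pre + ss_post
    if total == 0:
        return float("nan")
    return float(ss_pre / total)


def per_neuron_onset(
    trial_avg: np.ndarray,
    time_ms: np.ndarray,
    mean_rates: np.ndarray,
    rate_percentile: float = 90.0,
    baseline_ms: tuple[float, float] = BASELINE_MS,
    k_sd: float = K_SD,
) -> np.ndarray:
    """Onset per qualifying high-rate neuron (same threshold rule).

    Neurons with mean rate above the ``rate_percentile`` value qualify;
    others get NaN. Onset uses the absolute deviation of the single
    neuron's trial average from its baseline mean.
    """
    X = np.asarray(trial_avg, dtype=float)
    mean_rates = np.asarray(mean_rates, dtype=float)
    cutoff = np.percentile(mean_rates, rate_percentile)
    base = (time_ms >= baseline_ms[0]) & (time_ms < baseline_ms[1])
    after = time_ms >= baseline_ms[1]

    onsets = np.full(X.shape[1], np.nan)
    for n in range(X.shape[1]):
        if mean_rates[n] <= cutoff:
            continue
        dev = np.abs(X[:, n] - X[base, n].mean())
        thr = dev[base].mean() + k_sd * dev[base].std(ddof=0)
        crossed = np.flatnonzero(after & (dev > thr))
        if crossed.size:
            onsets[n] = time_ms[crossed[0]]
    return onsets
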