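"""Chance-corrected inactivation-effect time series and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE_MS = 20
DEFAULT_WINDOWS_MS = ((10, 25), (10, 50), (10, 100))


@dataclass
class EffectSeries:
    """Baseline-corrected |difference| between control and light averages."""

    time_ms: np.ndarray  # relative to light/trial onset
    delta: np.ndarray  # (n_channels, T) corrected |difference|
    sem: np.ndarray  # (T,) SEM across channels
    window_summaries: dict = field(default_factory=dict)  # (lo, hi) -> mean

    @property
    def mean(self) -> np.ndarray:
        return self.delta.mean(axis=0)


def _summaries(time_ms, series, windows):
    out = {}
    for lo, hi in windows:
        m = (time_ms >= lo) & (time_ms <= hi)
        out[(lo, hi)] = float(series[m].mean())
    return out


def inactivation_emg_effect(
    control: np.ndarray,
    light: np.ndarray,
    onset_idx: int,
    n_resample: int = 1000,
    seed: int = 0,
    windows_ms=DEFAULT_WINDOWS_MS,
) -> EffectSeries:
    """Chance-corrected |control - light| EMG time series.

    Parameters
    ----------
    control, light
        (n_trials, n_muscles, T) trial-aligned envelopes at 1 kHz.
    onset_idx
        Sample index of light/trial onset within T.

    The raw |difference| of condition means is corrected by the mean of
    ``n_resample`` split-half |difference| series computed from control
    trials only (the difference expected by chance from using disjoint trial
    sets), then the mean over the 20 ms preceding onset is subtracted.
    Values below zero are expected and preserved.
    """
    control = np.asarray(control, dtype=float)
    light = np.asarray(light, dtype=float)
    if control.shape[0] < 4:
        raise ValueError("need at least 4 control trials")
    rng = np.random.default_rng(seed)
    n_c = control.shape[0]
    if n_c % 2:
        drop = rng.integers(n_c)
        control = np.delete(control, drop, axis=0)
        n_c -= 1

    obs = np.abs(control.mean(axis=0) - light.mean(axis=0))  # (muscles, T)

    half = n_c // 2
    chance = np.zeros_like(obs)
    for _ in range(n_resample):
        perm = rng.permutation(n_c)
        a, b = control[perm[:half]], control[perm[half:]]
        chance += np.abs(a.mean(axis=0) - b.mean(axis=0))
    chance /= n_resample

    corrected = obs - chance
    base = corrected[:, onset_idx - BASELINE_MS : onset_idx].mean(axis=1, keepdims=True)
    corrected = corrected - base

    time_ms = np.arange(corrected.shape[1], dtype=float) - onset_idx
    mean = corrected.mean(axis=0)
    sem = corrected.std(axis=0, ddof=1) / np.sqrt(corrected.shape[0])
    return EffectSeries(
        time_ms=time_ms,
        delta=corrected,
        sem=sem,
        window_summaries=_summaries(time_ms, mean, windows_ms),
    )


def per_neuron_effect(
    control: np.ndarray,
    light: np.ndarray,
    session_mean: np.ndarray,
    session_sd: np.ndarray,
    onset_idx: int,
    window_ms: tuple[float, float] = (45.0, 55.0),
    top_n: int = 50,
) -> pd.DataFrame:
    """Per-neuron z-scored control-minus-light difference around +50 ms.

    ``control``/``light`` are (n_trials, n_neurons, T) rate arrays;
    z-scoring uses each neuron's session-wide rate mean/SD. The result is
    restricted to the ``top_n`` neurons by session mean rate; neurons with
    zero session SD are excluded.
    """
    session_mean = np.asarray(session_mean, dtype=float)
    session_sd = np.asarray(session_sd, dtype=float)
    valid = session_sd > 0
    lo = onset_idx + int(window_ms[0])
    hi = onset_idx + int(window_ms[1])

    c = control[:, :, lo:hi].mean(axis=(0, 2))
    l = light[:, :, lo:hi].mean(axis=(0, 2))
    delta_z = (c - l) / np.where(valid, session_sd, np.nan)

    order = np.argsort(session_mean)[::-1]
    order = order[valid[order]][:top_n]
    return pd.DataFrame(
        {
            "neuron": order,
            "session_mean_rate": session_mean[order],
            "delta_z": delta_z[order],
        }
    ).reset_index(drop=True)


def abs_effect_timeseries(
    controls: list[np.ndarray],
    lights: list[np.ndarray],
    onset_idx: int,
    seed: int = 0,
    windows_ms=DEFAULT_WINDOWS_MS,
) -> EffectSeries:
    """Across-animal average |per-neuron rate difference| time series.

    ``controls``/``lights`` are per-animal (n_trials, n_neurons, T) arrays.
    Each animal contributes the same number of neurons (subsampled to the
    minimum, seeded) so no animal dominates. Per neuron,
    ``|mean_control(t) - mean_light(t)|`` is computed, averaged across
    neurons and animals, then corrected by its 20 ms pre-onset mean.
    """
    rng = np.random.default_rng(seed)
    n_min = min(c.shape[1] for c in controls)
    per_neuron = []
    for c, l in zip(controls, lights):
        keep = rng.choice(c.shape[1], size=n_min, replace=False)
        diff = np.abs(c[:, keep].mean(axis=0) - l[:, keep].mean(axis=0))
        per_neuron.append(diff)  # (n_min, T)
    stacked = np.concatenate(per_neuron, axis=0)
    base = stacked[:, onset_idx - BASELINE_MS : onset_idx].mean(axis=1, keepdims=True)
    stacked = stacked - base

    time_ms = np.arange(stacked.shape[1], dtype=float) - onset_idx
    mean = stacked.mean(axis=0)
    sem = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    return EffectSeries(
        time_ms=time_ms,
        delta=stacked,
        sem=sem,
        window_summaries=_summaries(time_ms, mean, windows_ms),
    )
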