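"""Circular-shift significance of neuron-muscle rate correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd

FS_HZ = 1000
N_PERM = 300
MIN_SHIFT_S = 10.0
P_THRESHOLD = 0.05


def _pearson(x: np.ndarray, y2d: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    yc = y2d - y2d.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (yc @ xc) / denom


def muscle_correlation(
    rates: np.ndarray,
    emg: np.ndarray,
    n_perm: int = N_PERM,
    min_shift_s: float = MIN_SHIFT_S,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-neuron significance of correlation with any muscle.

    Observed Pearson r of each neuron's 1 kHz rate series with each muscle
    envelope is compared with a null built from ``n_perm`` circular shifts
    of the rate series by at least ``min_shift_s`` (and at most
    T - ``min_shift_s``). Two-tailed p per muscle; a neuron is flagged when
    any muscle's p falls below 0.05.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    emg = np.atleast_2d(np.asarray(emg, dtype=float))
    if rates.shape[1] != emg.shape[1]:
        raise ValueError("rate and EMG series must have equal length")
    n = rates.shape[1]
    min_shift = int(min_shift_s * FS_HZ)
    if n <= 2 * min_shift:
        raise ValueError("series too short for the required circular shifts")

    rng = np.random.default_rng(seed)
    rows = []
    for i, r in enumerate(rates):
        obs = _pearson(r, emg)
        shifts = rng.integers(min_shift, n - min_shift, size=n_perm)
        null = np.empty((n_perm, emg.shape[0]))
        for k, s in enumerate(shifts):
            null[k] = _pearson(np.roll(r, s), emg)
        # two-tailed with add-one smoothing to avoid exact zeros
        p = (1.0 + (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)) / (n_perm + 1.0)
        rows.append(
            {
                "neuron": i,
                **{f"r_m{m}": obs[m] for m in range(emg.shape[0])},
                **{f"p_m{m}": p[m] for m in range(emg.shape[0])},
                "significant": bool((p < P_THRESHOLD).any()),
            }
        )
    return pd.DataFrame(rows)
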