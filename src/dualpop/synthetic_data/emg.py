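"""Reach-locked EMG envelopes with known burst onsets."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import EMGParams

FS_HZ = 1000


def burst_template(params: EMGParams) -> np.ndarray:
    """Single-burst envelope shape starting at sample 0, 1 kHz."""
    rise = int(round(params.burst_rise_ms))
    hold = int(round(params.burst_hold_ms))
    fall = int(round(params.burst_fall_ms))
    shape = np.concatenate(
        [
            np.linspace(0.0, 1.0, rise, endpoint=False),
            np.ones(hold),
            np.linspace(1.0, 0.0, fall),
        ]
    )
    return params.burst_amplitude * shape


def generate_emg(
    onsets_ms: np.ndarray,
    duration_s: float,
    params: EMGParams,
    seed: int = 0,
    smooth_ms: float = 3.0,
) -> np.ndarray:
    """Per-muscle 1 kHz envelopes: clipped baseline noise plus reach bursts.

    Parameters
    ----------
    onsets_ms
        True reach-onset times on the session clock (ms). Bursts must not
        overlap; overlapping onsets raise ``ValueError``.
    duration_s
        Session duration in seconds.

    Returns
    -------
    (n_muscles, n_samples) nonnegative envelope array.
    """
    onsets = np.sort(np.asarray(onsets_ms, dtype=float))
    tmpl = burst_template(params)
    if onsets.size > 1 and np.any(np.diff(onsets) < tmpl.size):
        raise ValueError("overlapping trials: reach bursts collide")
    n = int(round(duration_s * FS_HZ))
    if onsets.size and onsets[-1] + tmpl.size > n:
        raise ValueError("trial onset outside session duration")

    rng = np.random.default_rng(seed)
    gains = rng.uniform(0.6, 1.0, size=params.n_muscles)
    emg = np.empty((params.n_muscles, n))
    for m in range(params.n_muscles):
        base = rng.normal(params.baseline_mean, params.baseline_sd, size=n)
        emg[m] = np.clip(base, 0.0, None)
        for t in onsets:
            i = int(round(t))
            emg[m, i : i + tmpl.size] += gains[m] * tmpl
        if smooth_ms > 0:
            emg[m] = gaussian_filter1d(emg[m], smooth_ms)
    return emg
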