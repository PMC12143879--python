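"""Trial-aligned extraction of rate and EMG segments from session bundles."""

from __future__ import annotations

import numpy as np

from .preprocess.units import firing_rate
from .synthetic_data.session import SessionBundle

FS_HZ = 1000


def session_rates(
    bundle: SessionBundle, units: np.ndarray | None = None, sigma_ms: float = 10.0
) -> np.ndarray:
    """(n_units, T) kernel-smoothed rate series at 1 kHz for the session."""
    if units is None:
        units = np.arange(bundle.n_units)
    return np.stack(
        [firing_rate(bundle.spike_times[u], bundle.duration_s, sigma_ms) for u in units]
    )


def _slice_segments(
    series: np.ndarray, events_ms: np.ndarray, window_ms: tuple[float, float]
) -> np.ndarray:
    """(n_events, n_channels, T_win) slices of a (n_channels, T) series."""
    w0, w1 = int(round(window_ms[0])), int(round(window_ms[1]))
    n_win = w1 - w0
    out = np.zeros((events_ms.size, series.shape[0], n_win))
    for i, ev in enumerate(events_ms):
        lo = int(round(ev)) + w0
        src_lo, src_hi = max(lo, 0), min(lo + n_win, series.shape[1])
        out[i, :, src_lo - lo : src_hi - lo] = series[:, src_lo:src_hi]
    return out


def rate_segments(
    bundle: SessionBundle,
    window_ms: tuple[float, float] = (-200.0, 800.0),
    units: np.ndarray | None = None,
    align: str = "reach_onset_ms",
    trial_mask: np.ndarray | None = None,
    sigma_ms: float = 10.0,
    rates: np.ndarray | None = None,
) -> np.ndarray:
    """(n_trials, n_units, T_win) rate segments aligned on a trial event.

    Pass a precomputed ``rates`` array (from :func:`session_rates`) to avoid
    re-smoothing when slicing the same session repeatedly.
    """
    if rates is None:
        rates = session_rates(bundle, units, sigma_ms)
    events = bundle.trials[align].to_numpy(dtype=float)
    if trial_mask is not None:
        events = events[trial_mask]
    return _slice_segments(rates, events, window_ms)


def emg_segments(
    bundle: SessionBundle,
    window_ms: tuple[float, float],
    align: str = "reach_onset_ms",
    trial_mask: np.ndarray | None = None,
) -> np.ndarray:
    """(n_trials, n_muscles, T_win) EMG segments aligned on a trial event."""
    events = bundle.trials[align].to_numpy(dtype=float)
    if trial_mask is not None:
        events = events[trial_mask]
    return _slice_segments(bundle.emg, events, window_ms)
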