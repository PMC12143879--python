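"""Post-sorting unit curation and kernel rate estimation."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

ISI_STAT_THRESHOLD = 0.18
WIDTH_THRESHOLD_MS = 0.417
DEPTH_LIMIT_UM = 1500.0
VIOL_WINDOW_MS = (0.3, 1.0)  # closed left, open right
NORM_WINDOW_MS = (10.0, 50.0)


def isi_violation_statistic(spike_times_s: np.ndarray) -> float:
    """Refractory-violation statistic from the spike-train autocorrelogram.

    Mass of the autocorrelogram (0.1 ms bins) in [0.3, 1.0) ms divided by the
    mass in [10, 50) ms; the denominator normalizes for overall rate. NaN if
    the normalizing window is empty.
    """
    t = np.sort(np.asarray(spike_times_s, dtype=float)) * 1000.0  # ms
    if t.size < 2:
        return np.nan
    lo_v, hi_v = VIOL_WINDOW_MS
    lo_n, hi_n = NORM_WINDOW_MS
    # pair counts with forward lags in each window (autocorrelogram mass)
    n_viol = (
        np.searchsorted(t, t + hi_v, side="left")
        - np.searchsorted(t, t + lo_v, side="left")
    ).sum()
    n_norm = (
        np.searchsorted(t, t + hi_n, side="left")
        - np.searchsorted(t, t + lo_n, side="left")
    ).sum()
    if n_norm == 0:
        return np.nan
    return float(n_viol) / float(n_norm)


def curate_units(
    spike_times: list[np.ndarray],
    depths_um: np.ndarray,
    widths_ms: np.ndarray,
    peak_signs: np.ndarray,
    regions: np.ndarray,
    duration_s: float,
) -> pd.DataFrame:
    """Build the curated unit table.

    A unit is kept when its ISI-violation statistic is defined and not above
    0.18 and it lies within 1500 um of the most superficial unit of its
    region. Width class is wide iff trough-to-peak width exceeds 0.417 ms.
    """
    n = len(spike_times)
    stat = np.array([isi_violation_statistic(st) for st in spike_times])
    undefined = ~np.isfinite(stat)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} unit(s) with empty normalizing window; "
            "statistic undefined, excluded"
        )
    depths = np.asarray(depths_um, dtype=float)
    regions = np.asarray(regions)
    rel_depth = np.empty(n)
    for r in np.unique(regions):
        m = regions == r
        rel_depth[m] = depths[m] - depths[m].min()

    keep_isi = np.isfinite(stat) & (stat <= ISI_STAT_THRESHOLD)
    keep_depth = rel_depth <= DEPTH_LIMIT_UM
    widths = np.asarray(widths_ms, dtype=float)
    return pd.DataFrame(
        {
            "unit_id": np.arange(n),
            "region": regions,
            "depth_um": rel_depth,
            "isi_stat": stat,
            "width_ms": widths,
            "width_class": np.where(widths > WIDTH_THRESHOLD_MS, "wide", "narrow"),
            "peak_sign": np.asarray(peak_signs),
            "mean_rate": np.array([st.size / duration_s for st in spike_times]),
            "keep_isi": keep_isi,
            "keep_depth": keep_depth,
            "keep": keep_isi & keep_depth,
        }
    )


def firing_rate(
    spike_times_s: np.ndarray,
    duration_s: float,
    sigma_ms: float = 10.0,
) -> np.ndarray:
    """1 ms-resolution rate series: a sum of Gaussians centered on spikes.

    The output is in spikes/s; its integral over the session equals the
    spike count (edge mass is only lost within ~4 sigma of the boundaries).
    """
    n = int(round(duration_s * 1000))
    counts = np.zeros(n)
    idx = np.floor(np.asarray(spike_times_s) * 1000).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(counts, idx, 1.0)
    return gaussian_filter1d(counts, sigma_ms, mode="constant") * 1000.0
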