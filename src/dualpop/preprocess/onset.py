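"""Double-threshold reach-onset detection from summed EMG."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FS_HZ = 1000
BASELINE_WINDOW_MS = (-500.0, -100.0)  # relative to the Go tone
UPPER_PERCENTILE = 30.0
LOWER_K_SD = 7.0
QUIESCENT_WIN_MS = 1000


def find_quiescent_epoch(
    summed_env: np.ndarray, window_ms: int = QUIESCENT_WIN_MS
) -> tuple[int, float]:
    """Locate the 1 s window with minimal envelope variance.

    Returns (start index, SD within the window). The global quiescent SD is
    used to set per-trial lower thresholds.
    """
    x = np.asarray(summed_env, dtype=float)
    if x.size < window_ms:
        raise ValueError("series shorter than the quiescent window")
    c1 = np.cumsum(np.insert(x, 0, 0.0))
    c2 = np.cumsum(np.insert(x**2, 0, 0.0))
    n = window_ms
    s1 = c1[n:] - c1[:-n]
    s2 = c2[n:] - c2[:-n]
    var = s2 / n - (s1 / n) ** 2
    start = int(np.argmin(var))
    return start, float(np.sqrt(max(var[start], 0.0)))


def detect_reach_onset(
    summed_env: np.ndarray,
    trials: pd.DataFrame,
    global_sd: float | None = None,
    search_back_ms: float = 1000.0,
) -> pd.DataFrame:
    """Detect reach onset per successful trial with a double threshold.

    The per-trial baseline is the mean summed EMG from 500 to 100 ms before
    the Go tone; the lower threshold is baseline + 7x the global quiescent
    SD; the upper threshold is the 30th percentile of summed EMG over
    tone-to-beam-break epochs of all successful trials. Onset is the last
    lower-threshold upward crossing preceding the first upper-threshold
    crossing after the tone — this skips sub-threshold twitches that return
    below the lower threshold before the reach.

    Returns a copy of ``trials`` with columns ``onset_ms``, ``baseline_mean``,
    ``baseline_sd``, ``ramp_ms``, ``flag_no_upper`` added.
    """
    env = np.asarray(summed_env, dtype=float)
    if global_sd is None:
        _, global_sd = find_quiescent_epoch(env)

    out = trials.copy()
    success = out["success"].to_numpy().astype(bool)

    # upper threshold from tone -> beam break epochs of successful trials
    segs = []
    for _, tr in out[success].iterrows():
        i0, i1 = int(tr["go_ms"]), int(tr["grasp_ms"])
        segs.append(env[i0:i1])
    if not segs:
        raise ValueError("no successful trials to set the upper threshold")
    upper = float(np.percentile(np.concatenate(segs), UPPER_PERCENTILE))

    onset = np.full(len(out), np.nan)
    base_mean = np.full(len(out), np.nan)
    base_sd = np.full(len(out), np.nan)
    ramp = np.full(len(out), np.nan)
    no_upper = np.zeros(len(out), dtype=bool)

    for i, (_, tr) in enumerate(out.iterrows()):
        if not success[i]:
            continue
        go = int(tr["go_ms"])
        b0 = max(go + int(BASELINE_WINDOW_MS[0]), 0)
        b1 = max(go + int(BASELINE_WINDOW_MS[1]), 1)
        base = env[b0:b1]
        base_mean[i] = base.mean()
        base_sd[i] = base.std()
        lower = base_mean[i] + LOWER_K_SD * global_sd

        stop = int(tr["grasp_ms"])
        seg = env[go:stop]
        above_upper = np.flatnonzero(seg >= upper)
        if above_upper.size == 0:
            no_upper[i] = True
            continue
        iu = go + int(above_upper[0])
        lo = max(go - int(search_back_ms), 0)
        below = np.flatnonzero(env[lo:iu] < lower)
        if below.size == 0:
            warnings.warn(
                f"trial {i}: no lower-threshold crossing before the upper "
                "crossing; using the upper crossing as onset"
            )
            onset[i] = float(iu)
        else:
            onset[i] = float(lo + below[-1] + 1)  # last upward crossing
        ramp[i] = float(iu) - onset[i]

    out["onset_ms"] = onset
    out["baseline_mean"] = base_mean
    out["baseline_sd"] = base_sd
    out["ramp_ms"] = ramp
    out["flag_no_upper"] = no_upper
    out["upper_threshold"] = upper
    return out
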