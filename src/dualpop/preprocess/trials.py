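"""Outlier-trial exclusion among successful reaches.

All inequalities are strict (">" / "<"), so trials exactly at a threshold
are retained. Flags are independent booleans; the qualifying set is the
successful trials carrying no flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

K_SD = 3.0
REACTION_FLOOR_MS = -50.0


def exclude_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag outlying successful trials.

    Expects columns ``onset_ms``, ``grasp_ms``, ``go_ms``, ``ramp_ms``,
    ``baseline_sd``, ``success`` and (optionally) ``flag_no_upper``. Adds
    ``duration_ms``, ``reaction_ms``, the four outlier flags and a
    ``qualifying`` column.

    Flags, computed over successful trials of the session:
      * duration (onset to beam break) > mean + 3 SD
      * reaction (reward to onset) < -50 ms
      * ramp time > mean + 3 SD
      * baseline SD > mean + 3 SD
    """
    out = trials.copy()
    success = out["success"].to_numpy().astype(bool) & np.isfinite(
        out["onset_ms"].to_numpy()
    )
    if success.sum() < 2:
        raise ValueError("need at least 2 successful trials with onsets")

    out["duration_ms"] = out["grasp_ms"] - out["onset_ms"]
    # reward (solenoid) is dispensed at the Go tone
    out["reaction_ms"] = out["onset_ms"] - out["go_ms"]

    def _flag_high(col: str) -> np.ndarray:
        v = out[col].to_numpy(dtype=float)
        ref = v[success]
        thr = ref.mean() + K_SD * ref.std(ddof=0)
        return success & (v > thr)

    out["flag_duration"] = _flag_high("duration_ms")
    out["flag_reaction"] = success & (
        out["reaction_ms"].to_numpy(dtype=float) < REACTION_FLOOR_MS
    )
    out["flag_ramp"] = _flag_high("ramp_ms")
    out["flag_baseline"] = _flag_high("baseline_sd")
    if "flag_no_upper" not in out.columns:
        out["flag_no_upper"] = False

    flag_cols = [
        "flag_duration",
        "flag_reaction",
        "flag_ramp",
        "flag_baseline",
        "flag_no_upper",
    ]
    out["qualifying"] = success & ~out[flag_cols].to_numpy().any(axis=1)
    return out
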