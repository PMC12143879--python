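"""Go and light input signals built from concatenated sigmoids."""

from __future__ import annotations

import numpy as np

GRID_MS = np.arange(-50.0, 100.0)  # 150 samples
GO_K = 0.3
GO_RAMP_START_MS = -40.0
LIGHT_RISE_K = 0.5
LIGHT_ON_MS = 0.0
LIGHT_PLATEAU_END_MS = 50.0
LIGHT_FALL_K = 1.0
RAMP_EPS = 0.01

CONDITIONS = ("control", "inactivate_A", "inactivate_B")


def _rising(t: np.ndarray, k: float, start_ms: float) -> np.ndarray:
    """Rising sigmoid 1/(1+exp(-k(t-c))) that first exceeds 0.01 at start_ms."""
    center = start_ms + np.log((1 - RAMP_EPS) / RAMP_EPS) / k
    return 1.0 / (1.0 + np.exp(-k * (t - center)))


def sigmoid_span_ms(k: float, lo: float = RAMP_EPS, hi: float = 0.95) -> float:
    """Time for a rising sigmoid with slope k to go from first exceeding
    ``lo`` to first reaching ``hi`` (closed form)."""
    return (np.log(hi / (1 - hi)) - np.log(lo / (1 - lo))) / k


def falling_below_ms(k: float, eps: float = RAMP_EPS) -> int:
    """Smallest integer t (ms from plateau end) with 1/(1+exp(k t)) < eps."""
    t = 0
    while 1.0 / (1.0 + np.exp(k * t)) >= eps:
        t += 1
    return t


def input_signals(
    condition: str, t_ms: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Go and light time series for one condition.

    The go signal (k = 0.3) starts ramping 40 ms before reach onset and is
    delivered to all units in every condition. The light signal rises with
    k = 0.5 from reach onset, holds its plateau of 1 until +50 ms, and then
    falls with k = 1; it is nonzero only on inactivation conditions and is
    routed (by the simulator) to the inactivated region's inhibitory units.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = GRID_MS if t_ms is None else np.asarray(t_ms, dtype=float)
    go = _rising(t, GO_K, GO_RAMP_START_MS)
    if condition == "control":
        light = np.zeros_like(t)
    else:
        rise = _rising(t, LIGHT_RISE_K, LIGHT_ON_MS)
        fall = 1.0 / (1.0 + np.exp(LIGHT_FALL_K * (t - LIGHT_PLATEAU_END_MS)))
        light = np.where(t < LIGHT_PLATEAU_END_MS, np.minimum(rise, 1.0), fall)
        light[t < LIGHT_ON_MS] = 0.0
    return {"go": go, "light": light, "condition": condition}
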