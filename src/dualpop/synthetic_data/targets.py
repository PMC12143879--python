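"""Smooth target traces for network-model fitting.

Produces muscle and per-region summed-activity traces on a 150 ms grid
(50 ms before to 100 ms after reach onset) for the three fitting conditions:
no inactivation, inactivate-A, inactivate-B. Region A leads region B by the
configured lead; inactivation-condition traces are suppressed according to
the session config's inactivation spec.
"""

from __future__ import annotations

import numpy as np

from .config import SynthConfig, InactivationSpec

GRID_MS = np.arange(-50.0, 100.0)  # 150 samples, 1 ms
LIGHT_ON_MS = 0.0
LIGHT_OFF_MS = 50.0


def _rise(t: np.ndarray, onset: float, k: float = 0.15) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-k * (t - onset)))


def _bump(t: np.ndarray, center: float, sd: float = 15.0) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def _suppress(trace: np.ndarray, t: np.ndarray, fraction: float, start: float) -> np.ndarray:
    out = trace.copy()
    out[t >= start] *= 1.0 - fraction
    return out


def generate_network_targets(config: SynthConfig) -> dict[str, dict[str, np.ndarray]]:
    """Target traces per condition.

    Returns ``{condition: {"muscle": .., "region_A": .., "region_B": ..}}``
    with conditions 'control', 'inactivate_A', 'inactivate_B', each trace on
    :data:`GRID_MS`.
    """
    t = GRID_MS
    lead = config.network_lead_ms
    spec = config.inactivation or InactivationSpec()

    # transient bumps keep the cross-correlation peak of the two region
    # traces at exactly the configured lead on the short grid
    base_a = 0.1 + _bump(t, center=40.0 - lead)
    base_b = 0.1 + _bump(t, center=40.0)
    muscle = _rise(t, onset=10.0, k=0.2)

    out: dict[str, dict[str, np.ndarray]] = {
        "control": {"muscle": muscle, "region_A": base_a, "region_B": base_b}
    }
    for target in ("A", "B"):
        other = "B" if target == "A" else "A"
        traces = {"region_A": base_a.copy(), "region_B": base_b.copy()}
        if target == spec.target_region:
            direct, down, lat = (
                spec.direct_fraction,
                spec.downstream_fraction,
                spec.downstream_latency_ms,
            )
        else:  # mirror-image experiment: swap the roles
            direct, down, lat = (
                spec.direct_fraction,
                spec.downstream_fraction / 2.0,
                spec.downstream_latency_ms,
            )
        traces[f"region_{target}"] = _suppress(
            traces[f"region_{target}"], t, direct, LIGHT_ON_MS
        )
        traces[f"region_{other}"] = _suppress(
            traces[f"region_{other}"], t, down, LIGHT_ON_MS + lat
        )
        out[f"inactivate_{target}"] = {"muscle": muscle.copy(), **traces}
    return out
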