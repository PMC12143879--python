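"""Leaky rate dynamics and readouts."""

from __future__ import annotations

import numpy as np

from .build import NetworkInstance
from .inputs import GRID_MS, input_signals


def simulate(
    instance: NetworkInstance,
    condition: str = "control",
    t_ms: np.ndarray | None = None,
    noise_sd: float | None = None,
    seed: int = 0,
    return_state: bool = False,
) -> dict:
    """Run the discrete-time leaky rate network for one condition.

    x_{t+1} = (1 - a) x_t + a (W r_t + go_t w_go + light_t w_light^region
    + b) with a = dt / tau and r = relu(x). The light input reaches only
    the inactivated region's inhibitory units. Muscle readout is the
    trainable weighted sum over the 200 designated units; per-region
    neural readouts are fixed-weight means over each region's designated
    units.
    """
    t = GRID_MS if t_ms is None else np.asarray(t_ms, dtype=float)
    sig = input_signals(condition, t)
    spec = instance.spec
    a = spec.dt_ms / spec.tau_ms
    N = instance.n_units
    T = t.size
    rng = np.random.default_rng(seed)
    sd = spec.noise_sd if noise_sd is None else noise_sd

    light_gate = np.zeros(N)
    if condition == "inactivate_A":
        light_gate[instance.region == "A"] = 1.0
    elif condition == "inactivate_B":
        light_gate[instance.region == "B"] = 1.0
    w_light = instance.w_light * light_gate

    x = np.zeros((T, N))
    r = np.zeros((T, N))
    xt = np.zeros(N)
    for k in range(T):
        rt = np.maximum(xt, 0.0)
        r[k] = rt
        x[k] = xt
        drive = (
            instance.W @ rt
            + sig["go"][k] * instance.w_go
            + sig["light"][k] * w_light
            + instance.bias
        )
        if sd > 0:
            drive = drive + rng.normal(0.0, sd, size=N)
        xt = (1.0 - a) * xt + a * drive
        if not np.all(np.isfinite(xt)):
            raise RuntimeError("numerical divergence during simulation")

    muscle = r[:, instance.muscle_subset] @ instance.muscle_w
    neural_a = r[:, instance.neural_subset_a].mean(axis=1)
    neural_b = r[:, instance.neural_subset_b].mean(axis=1)
    out = {
        "time_ms": t,
        "muscle": muscle,
        "neural_A": neural_a,
        "neural_B": neural_b,
        "rates": r,
    }
    if return_state:
        out["x"] = x
        out["signals"] = sig
        out["w_light_effective"] = w_light
    return out
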