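"""Gradient training of the constrained network (manual BPTT + Adam).

Trainable parameters are the recurrent weights (under zero and Dale-sign
masks, re-imposed by projection after every update) and the muscle-readout
weights. Biases, input weights and neural-readout weights stay fixed.
"""

from __future__ import annotations

import numpy as np

from .build import NetworkInstance
from .inputs import GRID_MS, input_signals
from .spec import TrainingConfig

LOSS_CONDITIONS = {
    "control": ("A", "B"),
    "inactivate_A": ("B",),  # only the non-inactivated region enters the loss
    "inactivate_B": ("A",),
}


def _forward(inst: NetworkInstance, condition: str, t: np.ndarray):
    sig = input_signals(condition, t)
    spec = inst.spec
    a = spec.dt_ms / spec.tau_ms
    N, T = inst.n_units, t.size
    light_gate = np.zeros(N)
    if condition == "inactivate_A":
        light_gate[inst.region == "A"] = 1.0
    elif condition == "inactivate_B":
        light_gate[inst.region == "B"] = 1.0
    w_light = inst.w_light * light_gate

    x = np.zeros((T, N))
    for k in range(T - 1):
        r = np.maximum(x[k], 0.0)
        drive = inst.W @ r + sig["go"][k] * inst.w_go + sig["light"][k] * w_light + inst.bias
        x[k + 1] = (1.0 - a) * x[k] + a * drive
    r = np.maximum(x, 0.0)
    return x, r


def _condition_loss_and_grads(inst, condition, targets, t):
    spec = inst.spec
    a = spec.dt_ms / spec.tau_ms
    T, N = t.size, inst.n_units
    x, r = _forward(inst, condition, t)

    muscle = r[:, inst.muscle_subset] @ inst.muscle_w
    neural = {
        "A": r[:, inst.neural_subset_a].mean(axis=1),
        "B": r[:, inst.neural_subset_b].mean(axis=1),
    }
    tgt = targets[condition]

    loss = float(np.mean((muscle - tgt["muscle"]) ** 2))
    var = float(np.var(tgt["muscle"]))
    dL_dr = np.zeros((T, N))
    e_m = 2.0 * (muscle - tgt["muscle"]) / T
    dL_dr[:, inst.muscle_subset] += e_m[:, None] * inst.muscle_w[None, :]
    d_muscle_w = e_m @ r[:, inst.muscle_subset]

    for region in LOSS_CONDITIONS[condition]:
        sub = inst.neural_subset_a if region == "A" else inst.neural_subset_b
        target = tgt[f"region_{region}"]
        err = neural[region] - target
        loss += float(np.mean(err**2))
        var += float(np.var(target))
        dL_dr[:, sub] += (2.0 * err / (T * sub.size))[:, None]

    # backward through x_{k+1} = (1-a) x_k + a (W r_k + inputs)
    delta = np.zeros((T, N))  # dL/dx_k
    for k in range(T - 1, -1, -1):
        g_r = dL_dr[k].copy()
        if k + 1 < T:
            g_r += a * (inst.W.T @ delta[k + 1])
        delta[k] = g_r * (x[k] > 0)
        if k + 1 < T:
            delta[k] += (1.0 - a) * delta[k + 1]
    dW = a * delta[1:].T @ r[:-1]
    return loss, var, dW, d_muscle_w


def train(
    inst: NetworkInstance,
    targets: dict[str, dict[str, np.ndarray]],
    config: TrainingConfig,
    t_ms: np.ndarray | None = None,
) -> tuple[NetworkInstance, np.ndarray]:
    """Minimize summed readout MSE over the three conditions.

    Each iteration is a full batch of the three conditions (three
    "trials"); training stops at ``max_trials`` presentations, when the
    normalized error falls below ``target_error``, or when the error has
    plateaued. With ``symmetry_lambda > 0`` the absolute difference between
    the summed across-region weights in the two directions is penalized.
    Returns the trained instance and the normalized-error trace.
    """
    t = GRID_MS if t_ms is None else np.asarray(t_ms, dtype=float)
    mask_ab = inst.across_mask("A")  # A -> B entries
    mask_ba = inst.across_mask("B")

    mW = np.zeros_like(inst.W)
    vW = np.zeros_like(inst.W)
    mu = np.zeros_like(inst.muscle_w)
    vu = np.zeros_like(inst.muscle_w)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = config.learning_rate

    max_iters = max(config.max_trials // len(LOSS_CONDITIONS), 1)
    trace = []
    best = np.inf
    since_best = 0
    for it in range(1, max_iters + 1):
        loss_sum, var_sum = 0.0, 0.0
        dW = np.zeros_like(inst.W)
        du = np.zeros_like(inst.muscle_w)
        for condition in LOSS_CONDITIONS:
            loss, var, dW_c, du_c = _condition_loss_and_grads(
                inst, condition, targets, t
            )
            loss_sum += loss
            var_sum += var
            dW += dW_c
            du += du_c
        if not np.isfinite(loss_sum):
            raise RuntimeError("non-finite loss during training")

        if config.symmetry_lambda > 0:
            gap = inst.W[mask_ab].sum() - inst.W[mask_ba].sum()
            s = config.symmetry_lambda * np.sign(gap)
            dW[mask_ab] += s
            dW[mask_ba] -= s

        err = loss_sum / var_sum
        trace.append(err)
        if err < best - 1e-6:
            best = err
            since_best = 0
        else:
            since_best += 1
        if err < config.target_error or since_best >= config.plateau_iters:
            break

        mW = b1 * mW + (1 - b1) * dW
        vW = b2 * vW + (1 - b2) * dW**2
        mu = b1 * mu + (1 - b1) * du
        vu = b2 * vu + (1 - b2) * du**2
        corr1 = 1 - b1**it
        corr2 = 1 - b2**it
        inst.W -= lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
        inst.muscle_w -= lr * (mu / corr1) / (np.sqrt(vu / corr2) + eps)
        inst.project_constraints()

    inst.history["error_trace"] = np.asarray(trace)
    return inst, np.asarray(trace)
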