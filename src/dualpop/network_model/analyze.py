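"""Across-region input and within-region inhibition analyses."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .build import NetworkInstance


def across_region_input(
    instance: NetworkInstance,
    rates: np.ndarray,
    windows_ms: dict[str, tuple[float, float]] | None = None,
    t_ms: np.ndarray | None = None,
) -> dict:
    """Summed directed input (weight x presynaptic activity) per epoch.

    ``rates`` is the (T, N) rate array from a simulation. For each
    direction, the product of every across-region weight with its
    presynaptic unit's activity is summed over units and over each
    requested window.
    """
    if t_ms is None:
        t_ms = np.arange(rates.shape[0], dtype=float)
    if windows_ms is None:
        windows_ms = {"all": (t_ms[0], t_ms[-1] + 1)}
    out = {}
    for direction, src in (("A_to_B", "A"), ("B_to_A", "B")):
        mask = instance.across_mask(src)
        col_weight = mask.astype(float) * instance.W  # (tgt, src)
        per_source = col_weight.sum(axis=0)  # total outgoing across weight
        drive = rates @ per_source  # (T,)
        out[direction] = {
            name: float(drive[(t_ms >= lo) & (t_ms < hi)].sum())
            for name, (lo, hi) in windows_ms.items()
        }
    return out


def inhibitory_weight_stats(instances: list[NetworkInstance]) -> dict:
    """Within-region inhibitory weight magnitudes and a two-sample test."""
    if len(instances) < 2:
        raise ValueError("need at least 2 instances")
    pooled = {"A": [], "B": []}
    for inst in instances:
        inh = ~inst.excitatory
        for region in ("A", "B"):
            src = (inst.region == region) & inh
            tgt = inst.region == region
            mask = inst.zero_mask & np.outer(tgt, src)
            pooled[region].append(np.abs(inst.W[mask]))
    a = np.concatenate(pooled["A"])
    b = np.concatenate(pooled["B"])
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "mean_abs_A": float(a.mean()),
        "mean_abs_B": float(b.mean()),
        "t": float(t),
        "p": float(p),
        "weights_A": a,
        "weights_B": b,
    }
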