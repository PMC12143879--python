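"""Convergent cross mapping and simplex-projection embedding choice."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class CCMParams:
    E: int = 4  # embedding dimension
    tau: int = 1  # lag step, ms
    K: int = 5  # neighbors (E + 1 by default)
    delay_grid_ms: tuple[int, ...] = tuple(range(0, 31, 3))
    history_span_ms: int = 500
    n_trials: int = 30

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1 ms")


def _embed(series: np.ndarray, E: int, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Delay embedding [y(t), y(t-tau), ..., y(t-(E-1)tau)]; returns
    (points, anchor times t)."""
    T = series.size
    t0 = (E - 1) * tau
    anchors = np.arange(t0, T)
    pts = np.stack([series[anchors - k * tau] for k in range(E)], axis=1)
    return pts, anchors


def simplex_optimal_E(
    series: np.ndarray,
    E_candidates=range(1, 11),
    tau: int = 1,
) -> tuple[int, dict[int, float]]:
    """Embedding dimension maximizing leave-one-out self-forecast skill.

    For each candidate E the series' own next value is predicted from the
    E+1 nearest delay-embedding neighbors (excluding the point itself);
    skill is the Pearson correlation between predictions and actual values.
    Constant series are rejected.
    """
    y = np.asarray(series, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant series: embedding undefined")
    skills: dict[int, float] = {}
    for E in E_candidates:
        pts, anchors = _embed(y[:-1], E, tau)
        targets = y[anchors + 1]
        if pts.shape[0] <= E + 2:
            continue
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=E + 2)
        dist, idx = dist[:, 1:], idx[:, 1:]  # drop self-match
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.exp(-dist / np.maximum(dist[:, :1], 1e-12))
        w /= w.sum(axis=1, keepdims=True)
        pred = (w * targets[idx]).sum(axis=1)
        if np.std(pred) == 0 or np.std(targets) == 0:
            skills[E] = 0.0
        else:
            skills[E] = float(np.corrcoef(pred, targets)[0, 1])
    best = max(skills, key=skills.get)
    return best, skills


def _cross_map_skill(
    source_trials: list[np.ndarray],
    target_trials: list[np.ndarray],
    params: CCMParams,
    delay: int,
) -> float:
    """Skill of predicting source(t - delay) from the target manifold."""
    pts_all, vals_all, trial_id = [], [], []
    for k, (src, tgt) in enumerate(zip(source_trials, target_trials)):
        pts, anchors = _embed(tgt, params.E, params.tau)
        ok = anchors - delay >= 0
        pts_all.append(pts[ok])
        vals_all.append(src[anchors[ok] - delay])
        trial_id.append(np.full(ok.sum(), k))
    pts = np.concatenate(pts_all)
    vals = np.concatenate(vals_all)
    if pts.shape[0] < params.K + 1:
        raise ValueError("too few manifold points: pair excluded")
    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=params.K + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-dist / np.maximum(dist[:, :1], 1e-12))
    w /= w.sum(axis=1, keepdims=True)
    pred = (w * vals[idx]).sum(axis=1)
    if np.std(pred) == 0 or np.std(vals) == 0:
        return 0.0
    return float(np.corrcoef(pred, vals)[0, 1])


def ccm_skill(
    source_trials: list[np.ndarray],
    target_trials: list[np.ndarray],
    params: CCMParams | None = None,
    seed: int = 0,
) -> dict:
    """Cross-map skill of the source from the target's shadow manifold.

    ``source_trials`` / ``target_trials`` are per-trial smoothed rate
    series (1 ms bins, Gaussian SD 10 ms). ``params.n_trials`` trials are
    sampled (seeded) and shadow-manifold points are built strictly within
    trial; skill is maximized over the delay grid (0..30 ms, step 3).

    Returns dict with skill, best_delay_ms, the sampled trial indices and
    the per-delay curve.
    """
    params = params or CCMParams()
    rng = np.random.default_rng(seed)
    n = len(source_trials)
    sel = (
        rng.choice(n, size=params.n_trials, replace=False)
        if n > params.n_trials
        else np.arange(n)
    )
    src = [np.asarray(source_trials[i], dtype=float) for i in sel]
    tgt = [np.asarray(target_trials[i], dtype=float) for i in sel]
    curve = {
        d: _cross_map_skill(src, tgt, params, d) for d in params.delay_grid_ms
    }
    best_d = max(curve, key=curve.get)
    return {
        "skill": curve[best_d],
        "best_delay_ms": int(best_d),
        "trials": sel,
        "curve": curve,
    }
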