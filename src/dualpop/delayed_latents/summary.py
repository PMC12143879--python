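"""Variance capture and cross-session lag summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DelayedLatentModel, fit

LAG_WINDOW_MS = 60.0


def variance_capture(model: DelayedLatentModel) -> pd.DataFrame:
    """Fractional variance captured per latent per region.

    With unit-variance latent priors, latent j captures ``||c_j||^2`` of a
    region's modeled variance; fractions are normalized by across + within
    + noise so they sum to 1 per region.
    """
    rows = []
    for region, Ca, Cw, rows_slice in (
        ("A", model.C_a_across, model.C_a_within, slice(0, model.q_a)),
        ("B", model.C_b_across, model.C_b_within, slice(model.q_a, None)),
    ):
        across = (Ca**2).sum(axis=0)
        within = (Cw**2).sum(axis=0)
        noise = model.R[rows_slice].sum()
        total = across.sum() + within.sum() + noise
        for j, v in enumerate(across):
            rows.append(
                {
                    "region": region,
                    "kind": "across",
                    "latent": j,
                    "fraction": v / total,
                    "delay_ms": model.delays_ms[j],
                    "boundary": bool(model.boundary_flags[j])
                    if model.boundary_flags.size
                    else False,
                }
            )
        for k, v in enumerate(within):
            rows.append(
                {
                    "region": region,
                    "kind": "within",
                    "latent": k,
                    "fraction": v / total,
                    "delay_ms": np.nan,
                    "boundary": False,
                }
            )
        rows.append(
            {
                "region": region,
                "kind": "noise",
                "latent": -1,
                "fraction": noise / total,
                "delay_ms": np.nan,
                "boundary": False,
            }
        )
    return pd.DataFrame(rows)


def lag_summary(
    models: list[DelayedLatentModel],
    significant: list[np.ndarray],
    window_ms: float = LAG_WINDOW_MS,
) -> dict:
    """Pooled lag statistics over sessions.

    Uses only significant, non-boundary across-latents with |lag| within
    ``window_ms``. Variance-weighted means use each region's fractional
    capture of the latent as the weight.
    """
    lags, w_a, w_b, per_session_median = [], [], [], []
    for model, sig in zip(models, significant):
        vc = variance_capture(model)
        keep = (
            sig
            & ~model.boundary_flags
            & (np.abs(model.delays_ms) <= window_ms)
        )
        sess_lags = model.delays_ms[keep]
        if sess_lags.size:
            per_session_median.append(float(np.median(sess_lags)))
        for j in np.flatnonzero(keep):
            lags.append(model.delays_ms[j])
            for region, acc in (("A", w_a), ("B", w_b)):
                frac = vc.query(
                    "region == @region and kind == 'across' and latent == @j"
                )["fraction"].iloc[0]
                acc.append(frac)
    lags = np.asarray(lags)
    w_a, w_b = np.asarray(w_a), np.asarray(w_b)
    if lags.size == 0:
        raise ValueError("no significant lags within the window")
    return {
        "lags_ms": lags,
        "median_lag_ms": float(np.median(lags)),
        "per_session_median_ms": per_session_median,
        "weighted_mean_lag_a_ms": float(np.sum(lags * w_a) / np.sum(w_a)),
        "weighted_mean_lag_b_ms": float(np.sum(lags * w_b) / np.sum(w_b)),
    }


def sweep_dimensionalities(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    vary: str = "within",
    values: tuple[int, ...] = (2, 3, 4, 5, 6),
    fixed: int = 4,
    **fit_kwargs,
) -> pd.DataFrame:
    """Refit while sweeping one dimensionality, the other held fixed."""
    rows = []
    for v in values:
        n_across, n_within = (fixed, v) if vary == "within" else (v, fixed)
        model = fit(counts_a, counts_b, n_across=n_across, n_within=n_within, **fit_kwargs)
        vc = variance_capture(model)
        across_frac = vc.query("kind == 'across'")["fraction"].sum() / 2.0
        rows.append(
            {
                "vary": vary,
                "value": v,
                "n_across": n_across,
                "n_within": n_within,
                "mean_across_fraction": across_frac,
                "delays_ms": model.delays_ms.copy(),
            }
        )
    return pd.DataFrame(rows)
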