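"""False-null-fraction estimation from a p-value distribution."""

from __future__ import annotations

import numpy as np
from scipy.interpolate import UnivariateSpline


def false_null_fraction(
    pvalues: np.ndarray,
    lambdas: np.ndarray | None = None,
    fdr: float = 0.10,
) -> dict:
    """Estimate the fraction of false null hypotheses as 1 - pi0.

    pi0 (the a priori fraction of true nulls) is estimated by the
    tail-uniformity method: pi0(lambda) = #{p > lambda} / (m (1 - lambda))
    over a lambda grid, smoothed with a cubic spline and read off at the
    largest lambda. Also returns the p-value threshold that controls the
    false discovery rate at ``fdr`` given the pi0 estimate.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if lambdas is None:
        lambdas = np.arange(0.01, 0.90, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_l, k=3)
    pi0 = float(np.clip(spline(lambdas[-1]), 0.0, 1.0))

    # largest threshold t with estimated FDR = pi0 * m * t / #{p <= t} <= fdr
    order = np.sort(p)
    n_le = np.arange(1, m + 1)
    est_fdr = np.where(n_le > 0, pi0 * m * order / n_le, np.inf)
    ok = np.flatnonzero(est_fdr <= fdr)
    threshold = float(order[ok[-1]]) if ok.size else 0.0
    return {
        "pi0": pi0,
        "false_null_fraction": 1.0 - pi0,
        "fdr_threshold": threshold,
        "pi0_lambda": pi0_l,
    }
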