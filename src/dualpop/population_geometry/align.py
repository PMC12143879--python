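"""CCA and PLS-SVD alignment of two population activity matrices."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import ActivityMatrix, trial_average_matrix

DEFAULT_K = 25


@dataclass
class AlignmentResult:
    """Paired component weights and similarity summaries.

    ``weights_a`` / ``weights_b`` map (centered) neuron space to component
    time courses; ``pair_correlation`` holds per-pair Pearson r and
    ``pair_covariance`` the per-pair covariances (the diagonal of S for
    PLS-SVD). ``capture_a`` / ``capture_b`` are per-pair *additional*
    variance captures from orthogonalized weights, as fractions of each
    region's total variance.
    """

    method: str
    weights_a: np.ndarray
    weights_b: np.ndarray
    pair_correlation: np.ndarray
    pair_covariance: np.ndarray
    scores_a: np.ndarray
    scores_b: np.ndarray
    capture_a: np.ndarray
    capture_b: np.ndarray
    pca_capture_a: np.ndarray = field(default_factory=lambda: np.empty(0))
    pca_capture_b: np.ndarray = field(default_factory=lambda: np.empty(0))
    c: float = np.nan  # trace(S) / (v_A + v_B), PLS-SVD only

    @property
    def cumulative_capture_a(self) -> np.ndarray:
        return np.cumsum(self.capture_a)

    @property
    def cumulative_capture_b(self) -> np.ndarray:
        return np.cumsum(self.capture_b)

    @property
    def weighted_mean_correlation(self) -> float:
        """Pair correlations weighted by the mean additional variance
        captured by the corresponding orthogonalized pair in each region."""
        w = 0.5 * (self.capture_a + self.capture_b)
        return float(np.sum(self.pair_correlation * w) / np.sum(w))


def _orthogonal_capture(Xc: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Additional variance captured by successive orthogonalized weights.

    Fractions of total variance of ``Xc`` (centered data)."""
    Q, _ = np.linalg.qr(W)
    proj = Xc @ Q
    total = (Xc**2).sum()
    return (proj**2).sum(axis=0) / total


def _pca_capture(Xc: np.ndarray, k: int) -> np.ndarray:
    sv = np.linalg.svd(Xc, compute_uv=False)
    frac = sv**2 / (sv**2).sum()
    return frac[:k]


def cca_align(
    X_a: ActivityMatrix | np.ndarray,
    X_b: ActivityMatrix | np.ndarray,
    k: int = DEFAULT_K,
) -> AlignmentResult:
    """Canonical correlation on rank-reduced activity matrices.

    Each matrix is reduced to its first ``k`` principal components (to
    mitigate rank deficiency) before extracting canonical pairs. When a
    matrix has fewer than ``k`` informative components, ``k`` is reduced
    with a warning.
    """
    A = X_a.centered if isinstance(X_a, ActivityMatrix) else np.asarray(X_a, float)
    B = X_b.centered if isinstance(X_b, ActivityMatrix) else np.asarray(X_b, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    Ua, sa, Vta = np.linalg.svd(A, full_matrices=False)
    Ub, sb, Vtb = np.linalg.svd(B, full_matrices=False)
    tol_a = sa.max() * max(A.shape) * np.finfo(float).eps
    tol_b = sb.max() * max(B.shape) * np.finfo(float).eps
    k_eff = min(k, int((sa > tol_a).sum()), int((sb > tol_b).sum()))
    if k_eff < k:
        warnings.warn(f"rank below requested components; using k={k_eff}")

    # PC scores with unit norm per column = whitened bases
    Za, Zb = Ua[:, :k_eff], Ub[:, :k_eff]
    U, r, Vt = np.linalg.svd(Za.T @ Zb)
    r = np.clip(r, -1.0, 1.0)

    # canonical weights in (centered) neuron space
    Wa = Vta[:k_eff].T @ (U / sa[:k_eff, None])
    Wb = Vtb[:k_eff].T @ (Vt.T / sb[:k_eff, None])
    scores_a, scores_b = A @ Wa, B @ Wb

    cap_a = _orthogonal_capture(A, Wa)
    cap_b = _orthogonal_capture(B, Wb)
    covs = np.array(
        [np.cov(scores_a[:, i], scores_b[:, i])[0, 1] for i in range(k_eff)]
    )
    return AlignmentResult(
        method="cca",
        weights_a=Wa,
        weights_b=Wb,
        pair_correlation=r,
        pair_covariance=covs,
        scores_a=scores_a,
        scores_b=scores_b,
        capture_a=cap_a,
        capture_b=cap_b,
        pca_capture_a=_pca_capture(A, k_eff),
        pca_capture_b=_pca_capture(B, k_eff),
    )


def pls_svd(
    X_a: ActivityMatrix | np.ndarray, X_b: ActivityMatrix | np.ndarray
) -> AlignmentResult:
    """PLS-SVD: singular value decomposition of the cross-covariance.

    ``U S V^T = A^T B`` on column-centered matrices; projections ``A U`` and
    ``B V`` have pairwise covariance ``diag(S)``, and
    ``c = trace(S) / (v_A + v_B)`` normalizes total captured covariation by
    total variance (so identical matrices give exactly 0.5).
    """
    A = X_a.centered if isinstance(X_a, ActivityMatrix) else np.asarray(X_a, float)
    B = X_b.centered if isinstance(X_b, ActivityMatrix) else np.asarray(X_b, float)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    U, S, Vt = np.linalg.svd(A.T @ B, full_matrices=False)
    v_a, v_b = (A**2).sum(), (B**2).sum()
    c = float(S.sum() / (v_a + v_b))

    scores_a, scores_b = A @ U, B @ Vt.T
    with np.errstate(invalid="ignore"):
        r = np.array(
            [np.corrcoef(scores_a[:, i], scores_b[:, i])[0, 1] for i in range(S.size)]
        )
    return AlignmentResult(
        method="pls",
        weights_a=U,
        weights_b=Vt.T,
        pair_correlation=r,
        pair_covariance=S,
        scores_a=scores_a,
        scores_b=scores_b,
        capture_a=_orthogonal_capture(A, U),
        capture_b=_orthogonal_capture(B, Vt.T),
        pca_capture_a=_pca_capture(A, S.size),
        pca_capture_b=_pca_capture(B, S.size),
        c=c,
    )


def lag_scan(
    rates_a: np.ndarray,
    rates_b: np.ndarray,
    trials: pd.DataFrame,
    lags_ms: np.ndarray | None = None,
    k: int = DEFAULT_K,
) -> pd.DataFrame:
    """Alignment quality versus temporal lag of region B's events.

    ``X_A`` is built once; ``X_B`` is rebuilt from events shifted by each
    lag. Returns a frame with columns lag_ms, cca_weighted_corr, pls_c.
    """
    if lags_ms is None:
        lags_ms = np.arange(-30, 31)
    X_a = trial_average_matrix(rates_a, trials, region="A")
    rows = []
    for lag in lags_ms:
        X_b = trial_average_matrix(rates_b, trials, region="B", lag_ms=float(lag))
        res_c = cca_align(X_a, X_b, k=k)
        res_p = pls_svd(X_a, X_b)
        rows.append(
            {
                "lag_ms": float(lag),
                "cca_weighted_corr": res_c.weighted_mean_correlation,
                "pls_c": res_p.c,
            }
        )
    return pd.DataFrame(rows)
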