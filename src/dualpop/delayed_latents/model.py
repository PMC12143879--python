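"""EM fitting of the delayed two-population latent factor model.

Observation model per trial, with y_t stacking both regions' binned
(square-root-stabilized) counts at time bin t:

    y_t = C x_t + d + eps,   eps ~ N(0, diag(R))

Across-region latents appear in both regions as the same smooth process
offset by a continuous per-latent delay D_j (negative = region A leads);
within-region latents are private. Latent priors are unit-variance
squared-exponential Gaussian processes on the bin grid. The E-step exploits
the fact that the observation-information term of the posterior precision
is a Kronecker product (loading cross-products x identity over time), so a
single Cholesky factorization per EM iteration serves every trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .counts import BIN_MS, N_BINS

DELAY_BOUND_MS = 200.0
JITTER = 1e-6
MIN_TIMESCALE_MS = 5.0
MAX_TIMESCALE_MS = 500.0


@dataclass
class DelayedLatentModel:
    """Fitted parameters of the delayed-latent model."""

    C_a_across: np.ndarray  # (q_A, n_across)
    C_b_across: np.ndarray  # (q_B, n_across)
    C_a_within: np.ndarray  # (q_A, n_within_a)
    C_b_within: np.ndarray  # (q_B, n_within_b)
    d: np.ndarray  # (q,)
    R: np.ndarray  # (q,) diagonal observation noise
    delays_ms: np.ndarray  # (n_across,), negative = region A leads
    across_timescales_ms: np.ndarray
    within_timescales_a_ms: np.ndarray
    within_timescales_b_ms: np.ndarray
    bin_ms: float = BIN_MS
    n_bins: int = N_BINS
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    boundary_flags: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    converged: bool = True
    sqrt_transformed: bool = True

    @property
    def q_a(self) -> int:
        return self.C_a_across.shape[0]

    @property
    def q_b(self) -> int:
        return self.C_b_across.shape[0]

    @property
    def n_across(self) -> int:
        return self.C_a_across.shape[1]

    @property
    def n_within(self) -> tuple[int, int]:
        return self.C_a_within.shape[1], self.C_b_within.shape[1]

    def swap_regions(self) -> "DelayedLatentModel":
        """Relabel regions; all delays change sign."""
        return DelayedLatentModel(
            C_a_across=self.C_b_across,
            C_b_across=self.C_a_across,
            C_a_within=self.C_b_within,
            C_b_within=self.C_a_within,
            d=np.concatenate([self.d[self.q_a :], self.d[: self.q_a]]),
            R=np.concatenate([self.R[self.q_a :], self.R[: self.q_a]]),
            delays_ms=-self.delays_ms,
            across_timescales_ms=self.across_timescales_ms,
            within_timescales_a_ms=self.within_timescales_b_ms,
            within_timescales_b_ms=self.within_timescales_a_ms,
            bin_ms=self.bin_ms,
            n_bins=self.n_bins,
            sqrt_transformed=self.sqrt_transformed,
        )


# ---------------------------------------------------------------------------
# structure helpers


def _se(tau: np.ndarray, ell: float) -> np.ndarray:
    return np.exp(-0.5 * (tau / ell) ** 2)


def _across_block(T: int, bin_ms: float, ell: float, delay: float) -> np.ndarray:
    """2T x 2T joint kernel of (x^A(1..T), x^B(1..T)).

    Cov(x_A(t), x_B(t')) = k(t - t' - D): positive D means region B leads.
    """
    t = bin_ms * np.arange(T)
    dt = t[:, None] - t[None, :]
    K = np.empty((2 * T, 2 * T))
    K[:T, :T] = _se(dt, ell)
    K[T:, T:] = _se(dt, ell)
    K[:T, T:] = _se(dt - delay, ell)
    K[T:, :T] = _se(dt + delay, ell)
    return K + JITTER * np.eye(2 * T)


def _within_block(T: int, bin_ms: float, ell: float) -> np.ndarray:
    t = bin_ms * np.arange(T)
    return _se(t[:, None] - t[None, :], ell) + JITTER * np.eye(T)


def _compact_loading(m: DelayedLatentModel) -> np.ndarray:
    """(q, L) loading onto the per-time-step latent coordinates.

    Coordinate order: for each across latent j the pair (A_j, B_j), then
    within-A, then within-B coordinates.
    """
    n_a = m.n_across
    n_wa, n_wb = m.n_within
    L = 2 * n_a + n_wa + n_wb
    q = m.q_a + m.q_b
    W = np.zeros((q, L))
    for j in range(n_a):
        W[: m.q_a, 2 * j] = m.C_a_across[:, j]
        W[m.q_a :, 2 * j + 1] = m.C_b_across[:, j]
    W[: m.q_a, 2 * n_a : 2 * n_a + n_wa] = m.C_a_within
    W[m.q_a :, 2 * n_a + n_wa :] = m.C_b_within
    return W


def _prior_blocks(m: DelayedLatentModel) -> list[np.ndarray]:
    """Kernel blocks in coordinate order (across pairs, then withins)."""
    T = m.n_bins
    blocks = [
        _across_block(T, m.bin_ms, m.across_timescales_ms[j], m.delays_ms[j])
        for j in range(m.n_across)
    ]
    blocks += [_within_block(T, m.bin_ms, e) for e in m.within_timescales_a_ms]
    blocks += [_within_block(T, m.bin_ms, e) for e in m.within_timescales_b_ms]
    return blocks


def _block_spans(m: DelayedLatentModel) -> list[tuple[int, int]]:
    T = m.n_bins
    spans, start = [], 0
    for _ in range(m.n_across):
        spans.append((start, start + 2 * T))
        start += 2 * T
    for _ in range(m.n_within[0] + m.n_within[1]):
        spans.append((start, start + T))
        start += T
    return spans


def _estep(m: DelayedLatentModel, Y: np.ndarray):
    """Posterior moments and per-trial log-likelihoods.

    Y: (n_trials, q, T). Returns (Mu (n_tr, L, T), Sigma (p, p), ll (n_tr,)).
    """
    n_tr, q, T = Y.shape
    W = _compact_loading(m)
    L = W.shape[1]
    p = L * T

    blocks = _prior_blocks(m)
    spans = _block_spans(m)
    Kinv = np.zeros((p, p))
    logdetK = 0.0
    for (a, b), K in zip(spans, blocks):
        cK = cho_factor(K, lower=True)
        Kinv[a:b, a:b] = cho_solve(cK, np.eye(b - a))
        logdetK += 2.0 * np.sum(np.log(np.diag(cK[0])))

    H = (W / m.R[:, None]).T @ W  # (L, L)
    P = Kinv
    idx = np.arange(T)
    for a in range(L):
        for b in range(L):
            P[a * T + idx, b * T + idx] += H[a, b]
    cP = cho_factor(P, lower=True)
    logdetP = 2.0 * np.sum(np.log(np.diag(cP[0])))
    Sigma = cho_solve(cP, np.eye(p))

    Yc = Y - m.d[None, :, None]
    B = np.einsum("ql,tqs->tls", W / m.R[:, None], Yc)  # (n_tr, L, T)
    Bflat = B.reshape(n_tr, p).T
    Mu = cho_solve(cP, Bflat).T.reshape(n_tr, L, T)

    quad = (Yc**2 / m.R[None, :, None]).sum(axis=(1, 2))
    bmu = np.einsum("tp,tp->t", Bflat.T, Mu.reshape(n_tr, p))
    logdetR = T * np.sum(np.log(m.R))
    ll = -0.5 * (
        q * T * np.log(2 * np.pi) + logdetR + logdetK + logdetP + quad - bmu
    )
    return Mu, Sigma, ll


def loglik(m: DelayedLatentModel, Y: np.ndarray) -> np.ndarray:
    """Per-trial marginal log-likelihood of (q, T) observations."""
    _, _, ll = _estep(m, Y)
    return ll


# ---------------------------------------------------------------------------
# fitting


def _init_model(
    Ya: np.ndarray, Yb: np.ndarray, n_across: int, n_within: int, sqrt_transformed: bool
) -> DelayedLatentModel:
    n_tr, q_a, T = Ya.shape
    q_b = Yb.shape[1]
    Y = np.concatenate([Ya, Yb], axis=1)
    flat = Y.transpose(1, 0, 2).reshape(q_a + q_b, -1)
    d = flat.mean(axis=1)
    Xc = flat - d[:, None]
    N = flat.shape[1]

    # across loadings from CCA between the regions: each canonical mode is
    # one shared latent, which (unlike a joint SVD) does not mix latents
    # carrying different delays
    Za, Zb = Xc[:q_a], Xc[q_a:]
    ridge = 1e-3
    Saa = Za @ Za.T / N + ridge * np.eye(q_a)
    Sbb = Zb @ Zb.T / N + ridge * np.eye(q_b)
    Sab = Za @ Zb.T / N
    La = np.linalg.cholesky(Saa)
    Lb = np.linalg.cholesky(Sbb)
    Mw = np.linalg.solve(La, np.linalg.solve(Lb, Sab.T).T)
    Uc, sc, Vct = np.linalg.svd(Mw)
    k = min(n_across, sc.size)
    wa = np.linalg.solve(La.T, Uc[:, :k])  # canonical weights, unit variance
    wb = np.linalg.solve(Lb.T, Vct.T[:, :k])
    C_across = np.zeros((q_a + q_b, n_across))
    C_across[:q_a, :k] = Saa @ wa
    C_across[q_a:, :k] = Sbb @ wb

    proj = np.vstack([wa.T @ Za, wb.T @ Zb])  # (2k, N)
    recon = np.vstack(
        [C_across[:q_a, :k] @ proj[:k], C_across[q_a:, :k] @ proj[k:]]
    )
    resid = Xc - recon

    def _within_init(rows: slice) -> np.ndarray:
        if n_within == 0:
            return np.zeros((rows.stop - rows.start, 0))
        sub = resid[rows]
        Uw, sw, _ = np.linalg.svd(sub, full_matrices=False)
        k = min(n_within, sw.size)
        C = np.zeros((sub.shape[0], n_within))
        C[:, :k] = Uw[:, :k] * (sw[:k] / np.sqrt(sub.shape[1]))
        return C

    C_a_w = _within_init(slice(0, q_a))
    C_b_w = _within_init(slice(q_a, q_a + q_b))
    R = np.maximum(resid.var(axis=1), 1e-3)

    # initial delays from the lagged cross-correlation of each across
    # latent's two regional projections: a zero-delay start perfectly
    # correlates the two latent copies, gluing the posterior and trapping
    # EM at D = 0
    delays0 = np.zeros(n_across)
    Yac = Ya - d[None, :q_a, None]
    Ybc = Yb - d[None, q_a:, None]
    max_lag_bins = min(10, T - 2)
    for j in range(k):
        pa = np.einsum("q,tqs->ts", wa[:, j], Yac)
        pb = np.einsum("q,tqs->ts", wb[:, j], Ybc)
        best, best_lag = -np.inf, 0
        for lag in range(-max_lag_bins, max_lag_bins + 1):
            if lag >= 0:
                v = np.mean(pa[:, : T - lag] * pb[:, lag:]) if lag < T else -np.inf
            else:
                v = np.mean(pa[:, -lag:] * pb[:, : T + lag])
            if v > best:
                best, best_lag = v, lag
        # pb lagging pa by `lag` bins means region A leads: negative delay
        delays0[j] = -best_lag * BIN_MS

    return DelayedLatentModel(
        C_a_across=C_across[:q_a],
        C_b_across=C_across[q_a:],
        C_a_within=C_a_w,
        C_b_within=C_b_w,
        d=d,
        R=R,
        delays_ms=delays0,
        across_timescales_ms=np.full(n_across, 2 * BIN_MS),
        within_timescales_a_ms=np.full(n_within, 2 * BIN_MS),
        within_timescales_b_ms=np.full(n_within, 2 * BIN_MS),
        n_bins=T,
        sqrt_transformed=sqrt_transformed,
    )


def _coord_sets(m: DelayedLatentModel):
    """Latent-coordinate indices visible to each region."""
    n_a = m.n_across
    n_wa, n_wb = m.n_within
    coords_a = [2 * j for j in range(n_a)] + list(range(2 * n_a, 2 * n_a + n_wa))
    coords_b = [2 * j + 1 for j in range(n_a)] + list(
        range(2 * n_a + n_wa, 2 * n_a + n_wa + n_wb)
    )
    return np.array(coords_a, dtype=int), np.array(coords_b, dtype=int)


def _mstep_observation(m: DelayedLatentModel, Y: np.ndarray, Mu, Sigma):
    """Closed-form update of loadings, offsets and noise variances."""
    n_tr, q, T = Y.shape
    L = Mu.shape[1]
    SigT = Sigma.reshape(L, T, L, T)
    S_same_t = np.einsum("atbt->ab", SigT)  # sum over t of same-time blocks
    Mxx = np.einsum("tas,tbs->ab", Mu, Mu) + n_tr * S_same_t
    sx = Mu.sum(axis=(0, 2))  # (L,)
    N = n_tr * T
    Mxy = np.einsum("tas,tqs->aq", Mu, Y)  # (L, q)
    sy = Y.sum(axis=(0, 2))  # (q,)

    coords_a, coords_b = _coord_sets(m)
    new_C = {}
    new_d = np.empty(q)
    new_R = np.empty(q)
    for region, coords, rows in (
        ("a", coords_a, slice(0, m.q_a)),
        ("b", coords_b, slice(m.q_a, q)),
    ):
        nc = coords.size
        XtX = np.empty((nc + 1, nc + 1))
        XtX[:nc, :nc] = Mxx[np.ix_(coords, coords)]
        XtX[:nc, nc] = sx[coords]
        XtX[nc, :nc] = sx[coords]
        XtX[nc, nc] = N
        XtY = np.vstack([Mxy[np.ix_(coords, range(rows.start, rows.stop))], sy[rows]])
        sol = np.linalg.solve(XtX, XtY)  # (nc+1, q_region)
        C_region = sol[:nc].T
        d_region = sol[nc]
        new_C[region] = C_region
        new_d[rows] = d_region
        yy = (Y[:, rows] ** 2).sum(axis=(0, 2))
        # exact M-step residual: R = (yy - sol . XtY) / N
        new_R[rows] = np.maximum((yy - np.einsum("kq,kq->q", sol, XtY)) / N, 1e-6)

    n_a = m.n_across
    n_wa, n_wb = m.n_within
    m.C_a_across = new_C["a"][:, :n_a]
    m.C_a_within = new_C["a"][:, n_a:]
    m.C_b_across = new_C["b"][:, :n_a]
    m.C_b_within = new_C["b"][:, n_a:]
    m.d = new_d
    m.R = new_R


def _mstep_kernels(m, Y, Mu, Sigma, delay_bound: float) -> None:
    """Numerically maximize the expected latent prior per kernel block."""
    n_tr = Y.shape[0]
    T = m.n_bins
    L = Mu.shape[1]
    spans = _block_spans(m)

    def _suff(span):
        a, b = span
        S = n_tr * Sigma[a:b, a:b]
        sub = Mu.reshape(n_tr, L * T)[:, a:b]
        return S + sub.T @ sub

    def _neg_ell(K, S):
        cK = cho_factor(K, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cK[0])))
        return n_tr * logdet + np.trace(cho_solve(cK, S))

    for j in range(m.n_across):
        S = _suff(spans[j])

        def obj(theta, S=S, j=j):
            return _neg_ell(
                _across_block(T, m.bin_ms, np.exp(theta[0]), m.delays_ms[j]), S
            )

        res = optimize.minimize(
            obj,
            x0=[np.log(m.across_timescales_ms[j])],
            method="L-BFGS-B",
            bounds=[(np.log(MIN_TIMESCALE_MS), np.log(MAX_TIMESCALE_MS))],
        )
        m.across_timescales_ms[j] = np.exp(res.x[0])

    w_spans = spans[m.n_across :]
    ells = np.concatenate([m.within_timescales_a_ms, m.within_timescales_b_ms])
    for k, span in enumerate(w_spans):
        S = _suff(span)

        def obj(theta, S=S):
            return _neg_ell(_within_block(T, m.bin_ms, np.exp(theta[0])), S)

        res = optimize.minimize(
            obj,
            x0=[np.log(ells[k])],
            method="L-BFGS-B",
            bounds=[(np.log(MIN_TIMESCALE_MS), np.log(MAX_TIMESCALE_MS))],
        )
        ells[k] = np.exp(res.x[0])
    n_wa = m.n_within[0]
    m.within_timescales_a_ms = ells[:n_wa]
    m.within_timescales_b_ms = ells[n_wa:]


def _update_delays_marginal(
    m: DelayedLatentModel,
    Y: np.ndarray,
    delay_bound: float,
    steps: tuple[float, ...] = (32.0, 16.0, 8.0, 4.0, 2.0, 1.0),
) -> float:
    """Coordinate hill-climb of each delay on the marginal likelihood.

    The expected-complete-likelihood delay update is frozen by the
    near-deterministic across-pair prior (the posterior reproduces the
    current delay exactly), so delays are instead moved directly against
    the data likelihood. Only improvements are accepted, so the overall
    objective remains monotone.
    """
    best = float(loglik(m, Y).sum())
    for j in range(m.n_across):
        for step in steps:
            improved = True
            while improved:
                improved = False
                for cand in (m.delays_ms[j] - step, m.delays_ms[j] + step):
                    if abs(cand) > delay_bound:
                        continue
                    old = m.delays_ms[j]
                    m.delays_ms[j] = cand
                    ll = float(loglik(m, Y).sum())
                    if ll > best + 1e-9:
                        best = ll
                        improved = True
                    else:
                        m.delays_ms[j] = old
    return best


def fit(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_across: int = 4,
    n_within: int = 4,
    max_iter: int = 200,
    tol: float = 1e-6,
    delay_bound_ms: float = DELAY_BOUND_MS,
    sqrt_transform: bool = True,
) -> DelayedLatentModel:
    """Fit the delayed-latent model by expectation-maximization.

    Parameters
    ----------
    counts_a, counts_b
        (n_trials, q_region, n_bins) binned counts per region.
    sqrt_transform
        Square-root-stabilize counts before fitting (tempers Poisson
        heteroscedasticity); disable for data already on a Gaussian scale.

    Latents whose fitted delay reaches the +/-200 ms bound are flagged in
    ``boundary_flags``; ``converged`` records whether the log-likelihood
    plateaued within ``max_iter`` iterations.
    """
    Ya = np.sqrt(counts_a) if sqrt_transform else np.asarray(counts_a, float)
    Yb = np.sqrt(counts_b) if sqrt_transform else np.asarray(counts_b, float)
    Y = np.concatenate([Ya, Yb], axis=1)

    m = _init_model(Ya, Yb, n_across, n_within, sqrt_transform)
    trace = []
    prev = -np.inf
    converged = False
    # marginal-likelihood delay searches: one full hill-climb early, then
    # fine refinements as the other parameters settle
    delay_schedule = {2: (32.0, 16.0, 8.0, 4.0, 2.0, 1.0)}
    for it in (7, 15, 25, 40, 60, 90, 130, 180):
        delay_schedule[it] = (2.0, 1.0)
    for it in range(max_iter):
        Mu, Sigma, ll_t = _estep(m, Y)
        ll = float(ll_t.sum())
        trace.append(ll)
        if np.isfinite(prev) and abs(ll - prev) < tol * abs(prev):
            converged = True
            break
        prev = ll
        _mstep_observation(m, Y, Mu, Sigma)
        _mstep_kernels(m, Y, Mu, Sigma, delay_bound_ms)
        if n_across and it in delay_schedule:
            _update_delays_marginal(m, Y, delay_bound_ms, steps=delay_schedule[it])
    m.loglik_trace = np.array(trace)
    m.converged = converged
    m.boundary_flags = np.abs(m.delays_ms) >= delay_bound_ms - 1e-6
    return m


# ---------------------------------------------------------------------------
# sampling (for recovery tests and bootstrap machinery)


def sample_from_model(
    m: DelayedLatentModel, n_trials: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (counts_a-like, counts_b-like) Gaussian observations.

    Returns arrays on the model's observation scale (no inverse sqrt
    transform is applied).
    """
    rng = np.random.default_rng(seed)
    T = m.n_bins
    W = _compact_loading(m)
    L = W.shape[1]
    blocks = _prior_blocks(m)
    spans = _block_spans(m)
    p = L * T

    chols = [np.linalg.cholesky(K) for K in blocks]
    Y = np.empty((n_trials, W.shape[0], T))
    for tr in range(n_trials):
        z = np.empty(p)
        for (a, b), cK in zip(spans, chols):
            z[a:b] = cK @ rng.standard_normal(b - a)
        X = z.reshape(L, T)
        noise = rng.standard_normal((W.shape[0], T)) * np.sqrt(m.R)[:, None]
        Y[tr] = W @ X + m.d[:, None] + noise
    return Y[:, : m.q_a], Y[:, m.q_a :]
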