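"""Delayed transfer entropy on 1 ms binary spike trains.

Plug-in estimator with single-bin source and target histories:

    TE(d) = I( i_{t+1} ; j_{t+1-d} | i_t )   [bits]

evaluated for d = 0..30 ms; the reported value is the maximum over d and
the delay at which it occurs. Estimator bias is not corrected here — the
circular-permutation null (which shares the bias) absorbs it.
"""

from __future__ import annotations

import numpy as np

D_MAX_MS = 30


def binarize(spike_times_s: np.ndarray, duration_s: float) -> np.ndarray:
    """1 ms binary train over [0, duration)."""
    n = int(round(duration_s * 1000))
    out = np.zeros(n, dtype=np.int8)
    idx = np.floor(np.asarray(spike_times_s) * 1000.0).astype(int)
    out[idx[(idx >= 0) & (idx < n)]] = 1
    return out


def _te_single(x: np.ndarray, h: np.ndarray, s: np.ndarray) -> float:
    """I(x; s | h) for three binary arrays of equal length, in bits."""
    joint = np.bincount(4 * x + 2 * h + s, minlength=8).astype(float)
    n = joint.sum()
    p = joint / n
    p_hs = p.reshape(2, 2, 2).sum(axis=0)  # (h, s)
    p_xh = p.reshape(2, 2, 2).sum(axis=2)  # (x, h)
    p_h = p_hs.sum(axis=1)  # (h,)
    te = 0.0
    for xi in range(2):
        for hi in range(2):
            for si in range(2):
                pj = p.reshape(2, 2, 2)[xi, hi, si]
                if pj <= 0:
                    continue
                num = pj / p_hs[hi, si]  # p(x | h, s)
                den = p_xh[xi, hi] / p_h[hi]  # p(x | h)
                te += pj * np.log2(num / den)
    return float(te)


def transfer_entropy(
    source: np.ndarray, target: np.ndarray, d_max: int = D_MAX_MS
) -> tuple[float, int, np.ndarray]:
    """Max-over-delay transfer entropy from source to target.

    Parameters
    ----------
    source, target
        Binary 1 ms trains of equal length (concatenated movement epochs).

    Returns
    -------
    (te_max, best_delay_ms, curve) where curve[d] = TE at delay d.
    """
    src = np.asarray(source, dtype=np.int64)
    tgt = np.asarray(target, dtype=np.int64)
    if src.size != tgt.size:
        raise ValueError("trains must have equal length")
    if src.size == 0 or tgt.sum() == 0:
        raise ValueError("empty train: pair excluded")
    n = src.size
    curve = np.zeros(d_max + 1)
    for d in range(d_max + 1):
        lo = max(1, d)
        x = tgt[lo:]  # i_{t+1}
        h = tgt[lo - 1 : n - 1]  # i_t
        s = src[lo - d : n - d]  # j_{t+1-d}
        curve[d] = _te_single(x, h, s)
    best = int(np.argmax(curve))
    return float(curve[best]), best, curve
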