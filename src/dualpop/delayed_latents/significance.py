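"""Bootstrap test of whether fitted delays differ from zero."""

from __future__ import annotations

from copy import deepcopy

import numpy as np

from .model import DelayedLatentModel, loglik


def delay_significance(
    model: DelayedLatentModel,
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    n_resamples: int = 100,
    trials_per_resample: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-across-latent significance of the fitted delay.

    For each across-region latent, the data likelihood under the fitted
    model is compared with the same model with that latent's delay set to
    zero, over bootstrap resamples of ``trials_per_resample`` trials drawn
    with replacement. The latent's delay is significant when fewer than
    ``alpha`` of the resamples score the zero-delay model at least as well.
    """
    if n_resamples < 20:
        raise ValueError("n_resamples below 20 gives a meaningless test")
    Ya = np.sqrt(counts_a) if model.sqrt_transformed else np.asarray(counts_a, float)
    Yb = np.sqrt(counts_b) if model.sqrt_transformed else np.asarray(counts_b, float)
    Y = np.concatenate([Ya, Yb], axis=1)
    n_tr = Y.shape[0]
    rng = np.random.default_rng(seed)

    ll_full = loglik(model, Y)
    flags = np.zeros(model.n_across, dtype=bool)
    for j in range(model.n_across):
        if model.delays_ms[j] == 0.0:
            continue  # zero-delay model is identical: never significant
        m0 = deepcopy(model)
        m0.delays_ms = model.delays_ms.copy()
        m0.delays_ms[j] = 0.0
        ll_zero = loglik(m0, Y)
        wins = 0
        for _ in range(n_resamples):
            pick = rng.integers(0, n_tr, size=trials_per_resample)
            if ll_zero[pick].sum() >= ll_full[pick].sum():
                wins += 1
        flags[j] = wins / n_resamples < alpha
    return flags
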