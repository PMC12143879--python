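"""Smooth latent time courses shared between regions at known delays.

Each latent is a unit-variance stationary Gaussian process with a
squared-exponential kernel ``K(dt) = exp(-dt^2 / (2 * ell^2))``, sampled on a
1 ms grid by Gaussian-filtering white noise (filter sigma ``ell / sqrt(2)``
yields exactly that kernel in the continuum limit). An across-region latent
appears in both regions as the same sample path offset by its configured
delay; within-region latents are private.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import SynthConfig


@dataclass
class LatentSet:
    """Latent time courses for every trial of one synthetic session.

    Arrays are shaped (n_trials, n_latents, n_samples) on the 1 ms grid of
    the trial window. ``delays_ms`` holds the grid-rounded delay actually
    applied per across-region latent (negative = region A leads).
    """

    time_ms: np.ndarray
    across_a: np.ndarray
    across_b: np.ndarray
    within_a: np.ndarray
    within_b: np.ndarray
    delays_ms: np.ndarray
    timescales_ms: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.across_a.shape[0]


def _sample_se_process(rng: np.random.Generator, n: int, ell: float) -> np.ndarray:
    """One unit-variance squared-exponential GP sample path on a 1 ms grid."""
    sigma = ell / np.sqrt(2.0)
    pad = int(np.ceil(6 * sigma)) + 1
    noise = rng.standard_normal(n + 2 * pad)
    smooth = gaussian_filter1d(noise, sigma, mode="constant")
    # variance of filtered unit white noise = sum of squared kernel weights
    half = np.arange(-pad, pad + 1)
    w = np.exp(-0.5 * (half / sigma) ** 2)
    w = w / w.sum()
    smooth /= np.sqrt(np.sum(w**2))
    return smooth[pad:-pad]


def generate_latents(config: SynthConfig, seed: int | None = None) -> LatentSet:
    """Draw latent time courses for every trial.

    Parameters
    ----------
    config
        Generator configuration; delays are validated against the trial
        window at construction time.
    seed
        Overrides ``config.seed`` when given. Same seed, same latents.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_samples
    t0 = config.trial_window[0]
    time_ms = t0 + np.arange(n, dtype=float)

    delays = np.round(config.delays).astype(int)
    n_tr = config.n_trials
    n_a, n_w = config.n_across_latents, config.n_within_latents

    across_a = np.zeros((n_tr, n_a, n))
    across_b = np.zeros((n_tr, n_a, n))
    within_a = np.zeros((n_tr, n_w, n))
    within_b = np.zeros((n_tr, n_w, n))

    max_d = int(np.max(np.abs(delays))) if n_a else 0
    for tr in range(n_tr):
        for j in range(n_a):
            ell = config.timescale_for("across", j)
            base = _sample_se_process(rng, n + 2 * max_d, ell)
            # region A reads the shared path at t; region B at t + delay,
            # so a negative delay makes region A lead.
            d = delays[j]
            across_a[tr, j] = base[max_d : max_d + n]
            across_b[tr, j] = base[max_d + d : max_d + d + n]
        for k in range(n_w):
            ell = config.timescale_for("within", k)
            within_a[tr, k] = _sample_se_process(rng, n, ell)
            within_b[tr, k] = _sample_se_process(rng, n, ell)

    return LatentSet(
        time_ms=time_ms,
        across_a=across_a,
        across_b=across_b,
        within_a=within_a,
        within_b=within_b,
        delays_ms=delays.astype(float),
        timescales_ms=np.array(
            [config.timescale_for("across", j) for j in range(n_a)]
            + [config.timescale_for("within", k) for k in range(n_w)]
        ),
    )


def se_autocorrelation(dt_ms: np.ndarray, ell: float) -> np.ndarray:
    """Closed-form autocorrelation of the latent kernel."""
    dt = np.asarray(dt_ms, dtype=float)
    return np.exp(-0.5 * (dt / ell) ** 2)


def se_half_width(ell: float) -> float:
    """Lag (ms) at which the kernel autocorrelation falls to one half."""
    return float(ell * np.sqrt(2.0 * np.log(2.0)))
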