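"""Inhomogeneous-Poisson spike emission from latent drives.

Per-unit intensity is ``max(0, baseline + loadings @ latents)`` (rectified
linear link). Optional directed pairwise coupling adds an alpha-function
hazard increment (2 ms rise) to the target unit at a fixed delay after each
source spike, which produces a sharp, recoverable cross-correlogram peak.
"""

from __future__ import annotations

import numpy as np

from .config import SynthConfig, PairCoupling
from .latents import LatentSet

ALPHA_TAU_MS = 2.0
DT_S = 1e-3


def draw_loadings(config: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Loading matrices mapping latents to per-unit rate drive (spikes/s).

    Returns a dict with keys 'across_a', 'across_b', 'within_a', 'within_b',
    each (n_units, n_latents).
    """
    n_u = config.n_units_per_region
    n_a, n_w = config.n_across_latents, config.n_within_latents

    def _draw(n_lat: int) -> np.ndarray:
        if n_lat == 0:
            return np.zeros((n_u, 0))
        scale = config.loading_scale / np.sqrt(max(n_a + n_w, 1))
        return rng.normal(0.0, scale, size=(n_u, n_lat))

    return {
        "across_a": _draw(n_a),
        "across_b": _draw(n_a),
        "within_a": _draw(n_w),
        "within_b": _draw(n_w),
    }


def draw_baselines(config: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    lo, hi = config.baseline_rate_range
    return {
        "A": rng.uniform(lo, hi, size=config.n_units_per_region),
        "B": rng.uniform(lo, hi, size=config.n_units_per_region),
    }


def draw_event_amplitudes(
    config: SynthConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-unit amplitudes of the reach-locked rate bump (spikes/s)."""
    return {
        r: config.event_amplitude
        * rng.uniform(0.5, 1.5, size=config.n_units_per_region)
        for r in ("A", "B")
    }


def event_bump(config: SynthConfig, region: str) -> np.ndarray:
    """Reach-locked Gaussian bump on the trial grid, peak 1."""
    t = config.trial_window[0] + np.arange(config.n_samples, dtype=float)
    center = config.event_center_ms - (config.event_lead_ms if region == "A" else 0.0)
    return np.exp(-0.5 * ((t - center) / config.event_sd_ms) ** 2)


def intensity_matrices(
    latents: LatentSet,
    loadings: dict[str, np.ndarray],
    baselines: dict[str, np.ndarray],
    config: SynthConfig | None = None,
    event_amps: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Rectified per-trial intensities, (n_trials, n_units, n_samples), spikes/s."""
    out = {}
    for region, lab in (("A", "a"), ("B", "b")):
        ac = latents.__dict__[f"across_{lab}"]
        wi = latents.__dict__[f"within_{lab}"]
        drive = np.einsum("ul,tln->tun", loadings[f"across_{lab}"], ac)
        if wi.shape[1]:
            drive = drive + np.einsum("ul,tln->tun", loadings[f"within_{lab}"], wi)
        if config is not None and event_amps is not None and config.event_amplitude:
            bump = event_bump(config, region)
            drive = drive + event_amps[region][None, :, None] * bump[None, None, :]
        out[region] = np.maximum(0.0, baselines[region][None, :, None] + drive)
    return out


def _poisson_spikes_from_rate(
    rate: np.ndarray, rng: np.random.Generator, t0_ms: float
) -> np.ndarray:
    """Spike times (ms) from a 1 ms-binned rate series (spikes/s)."""
    lam = rate * DT_S
    counts = rng.poisson(lam)
    idx = np.nonzero(counts)[0]
    if idx.size == 0:
        return np.empty(0)
    reps = counts[idx]
    bins = np.repeat(idx, reps)
    return t0_ms + bins + rng.uniform(0.0, 1.0, size=bins.size)


def alpha_hazard(t_ms: np.ndarray, delay_ms: float, gain: float) -> np.ndarray:
    """Alpha-function hazard increment peaking at ``gain`` spikes/s.

    Peak occurs ``delay_ms`` after the source spike (rise time ALPHA_TAU_MS).
    """
    u = np.asarray(t_ms, dtype=float) - (delay_ms - ALPHA_TAU_MS)
    h = np.zeros_like(u)
    pos = u > 0
    h[pos] = gain * (u[pos] / ALPHA_TAU_MS) * np.exp(1.0 - u[pos] / ALPHA_TAU_MS)
    return h


def generate_spikes(
    latents: LatentSet,
    config: SynthConfig,
    seed: int | None = None,
    loadings: dict[str, np.ndarray] | None = None,
    baselines: dict[str, np.ndarray] | None = None,
    rate_scale: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, list[list[np.ndarray]]], dict]:
    """Draw spike trains for every unit and trial.

    Parameters
    ----------
    rate_scale
        Optional per-region multiplicative profiles (n_trials, n_samples)
        applied to intensities (used for inactivation trials).

    Returns
    -------
    spikes
        ``spikes[region][trial][unit]`` = spike times in ms on the trial
        clock (relative to reach onset).
    info
        Loadings, baselines and per-trial intensities used.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    if loadings is None:
        loadings = draw_loadings(config, rng)
    if baselines is None:
        baselines = draw_baselines(config, rng)
    for key in ("across_a", "within_a"):
        if loadings[key].shape[1] != latents.__dict__[key].shape[1]:
            raise ValueError("loading matrix shape does not match latent count")

    event_amps = draw_event_amplitudes(config, rng)
    intens = intensity_matrices(latents, loadings, baselines, config, event_amps)
    if rate_scale is not None:
        for region in ("A", "B"):
            if region in rate_scale:
                intens[region] = intens[region] * rate_scale[region][:, None, :]

    t0 = config.trial_window[0]
    n = config.n_samples
    spikes: dict[str, list[list[np.ndarray]]] = {"A": [], "B": []}
    for region in ("A", "B"):
        for tr in range(config.n_trials):
            trial_spikes = [
                _poisson_spikes_from_rate(intens[region][tr, u], rng, t0)
                for u in range(config.n_units_per_region)
            ]
            spikes[region].append(trial_spikes)

    # additive coupling: superpose extra target spikes driven by source spikes
    grid = t0 + np.arange(n, dtype=float)
    for c in config.pair_coupling:
        for tr in range(config.n_trials):
            src = spikes[c.source_region][tr][c.source_unit]
            if src.size == 0:
                continue
            hazard = np.zeros(n)
            for s in src:
                hazard += alpha_hazard(grid - s, c.delay_ms, c.gain)
            extra = _poisson_spikes_from_rate(hazard, rng, t0)
            tgt = spikes[c.target_region][tr][c.target_unit]
            spikes[c.target_region][tr][c.target_unit] = np.sort(
                np.concatenate([tgt, extra])
            )

    info = {
        "loadings": loadings,
        "baselines": baselines,
        "intensity": intens,
        "event_amplitudes": event_amps,
    }
    return spikes, info
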