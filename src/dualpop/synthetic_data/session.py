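"""Assembly of full synthetic sessions with ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SynthConfig
from .emg import generate_emg, burst_template
from .latents import LatentSet, generate_latents
from .spikes import generate_spikes, draw_loadings, draw_baselines


@dataclass
class SessionBundle:
    """All measured quantities for one recording session.

    Spike times are in seconds on the session clock; trial-event columns are
    in milliseconds on the same clock. EMG envelopes are sampled at 1 kHz.
    """

    spike_times: list[np.ndarray]  # seconds, one array per unit
    unit_region: np.ndarray  # 'A' or 'B' per unit
    unit_depth: np.ndarray  # um below most-superficial unit
    unit_width: np.ndarray  # trough-to-peak, ms
    unit_peak_sign: np.ndarray  # +1 / -1
    emg: np.ndarray  # (n_muscles, n_samples) at 1 kHz
    trials: pd.DataFrame  # cue_ms, go_ms, reach_onset_ms, grasp_ms, spout, success, light
    duration_s: float

    def __post_init__(self) -> None:
        for st in self.spike_times:
            if st.size and (st[0] < 0 or st[-1] > self.duration_s):
                raise ValueError("spike times outside [0, duration]")
        ev = self.trials[["cue_ms", "go_ms", "reach_onset_ms", "grasp_ms"]].to_numpy()
        if not np.all(np.diff(ev, axis=1) > 0):
            raise ValueError("trial events must be strictly ordered")

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def units_in(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.unit_region == region)


@dataclass
class GroundTruth:
    """Generator-side truth for every configured latent, pair and trial."""

    latents: LatentSet
    delays_ms: np.ndarray
    couplings: list
    reach_onsets_ms: np.ndarray
    loadings: dict
    baselines: dict
    suppression: dict = field(default_factory=dict)  # region -> (n_trials, n_samples)
    light_trials: np.ndarray | None = None


def _schedule_trials(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    w0, w1 = config.trial_window
    span = w1 - w0
    gap_ms = config.inter_trial_gap_s * 1000.0
    onsets = np.empty(config.n_trials)
    t = 1000.0 - w0
    for k in range(config.n_trials):
        onsets[k] = t
        t += span + gap_ms + rng.uniform(0.0, 500.0)
    # short reactions and longer reach-to-grasp keep movement dominant in
    # tone-to-beam-break epochs (the upper onset threshold depends on this)
    reaction = rng.uniform(60.0, 140.0, size=config.n_trials)
    grasp_lat = rng.uniform(250.0, 350.0, size=config.n_trials)
    return pd.DataFrame(
        {
            "cue_ms": onsets - reaction - 800.0,
            "go_ms": onsets - reaction,
            "reach_onset_ms": onsets,
            "grasp_ms": onsets + grasp_lat,
            "spout": (np.arange(config.n_trials) % 4) + 1,
            "success": np.ones(config.n_trials, dtype=bool),
            "light": np.zeros(config.n_trials, dtype=bool),
        }
    )


def _suppression_profiles(
    config: SynthConfig, light: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-region multiplicative rate profiles, (n_trials, n_samples)."""
    spec = config.inactivation
    n = config.n_samples
    t = config.trial_window[0] + np.arange(n)
    prof = {r: np.ones((config.n_trials, n)) for r in ("A", "B")}
    if spec is None:
        return prof
    if not (config.trial_window[0] < 0.0 < config.trial_window[1]):
        raise ValueError("light onset (t=0) lies outside the trial window")
    other = "B" if spec.target_region == "A" else "A"
    direct = np.where(t >= 0.0, 1.0 - spec.direct_fraction, 1.0)
    down = np.where(t >= spec.downstream_latency_ms, 1.0 - spec.downstream_fraction, 1.0)
    prof[spec.target_region][light] = direct
    prof[other][light] = down
    return prof


def _assemble(
    config: SynthConfig, seed: int, with_light: bool
) -> tuple[SessionBundle, GroundTruth]:
    rng = np.random.default_rng(seed)
    trials = _schedule_trials(config, rng)
    if with_light:
        if config.inactivation is None:
            raise ValueError("config.inactivation must be set for a light dataset")
        n_light = int(round(config.light_fraction * config.n_trials))
        light_idx = rng.choice(config.n_trials, size=n_light, replace=False)
        light = np.zeros(config.n_trials, dtype=bool)
        light[light_idx] = True
        trials["light"] = light
    else:
        light = np.zeros(config.n_trials, dtype=bool)

    latents = generate_latents(config, seed=int(rng.integers(2**31)))
    loadings = draw_loadings(config, rng)
    baselines = draw_baselines(config, rng)
    suppression = _suppression_profiles(config, light)
    spikes, info = generate_spikes(
        latents,
        config,
        seed=int(rng.integers(2**31)),
        loadings=loadings,
        baselines=baselines,
        rate_scale=suppression if with_light else None,
    )

    onsets = trials["reach_onset_ms"].to_numpy()
    w0, w1 = config.trial_window
    tmpl_len = burst_template(config.emg_params).size
    duration_s = (
        onsets[-1] + max(w1, tmpl_len) + 1000.0
    ) / 1000.0 + config.tail_padding_s

    # background spiking between trials at each unit's baseline rate
    spike_times: list[np.ndarray] = []
    regions: list[str] = []
    for region in ("A", "B"):
        for u in range(config.n_units_per_region):
            rate = baselines[region][u]
            n_bg = rng.poisson(rate * duration_s)
            bg = np.sort(rng.uniform(0.0, duration_s, size=n_bg))
            # drop background inside trial windows (trial spikes replace it)
            keep = np.ones(bg.size, dtype=bool)
            for t_on in onsets:
                lo, hi = (t_on + w0) / 1000.0, (t_on + w1) / 1000.0
                keep &= ~((bg >= lo) & (bg < hi))
            parts = [bg[keep]]
            for tr, t_on in enumerate(onsets):
                parts.append((spikes[region][tr][u] + t_on) / 1000.0)
            spike_times.append(np.sort(np.concatenate(parts)))
            regions.append(region)

    n_total = 2 * config.n_units_per_region
    unit_width = np.where(
        rng.uniform(size=n_total) < 0.75,
        rng.uniform(0.5, 0.8, size=n_total),
        rng.uniform(0.15, 0.35, size=n_total),
    )
    unit_peak_sign = np.where(rng.uniform(size=n_total) < 0.9, -1, 1)
    unit_depth = rng.uniform(0.0, 1400.0, size=n_total)

    emg = generate_emg(
        onsets, duration_s, config.emg_params, seed=int(rng.integers(2**31))
    )

    bundle = SessionBundle(
        spike_times=spike_times,
        unit_region=np.array(regions),
        unit_depth=unit_depth,
        unit_width=unit_width,
        unit_peak_sign=unit_peak_sign,
        emg=emg,
        trials=trials,
        duration_s=duration_s,
    )
    truth = GroundTruth(
        latents=latents,
        delays_ms=latents.delays_ms,
        couplings=list(config.pair_coupling),
        reach_onsets_ms=onsets.copy(),
        loadings=info["loadings"],
        baselines=info["baselines"],
        suppression=suppression,
        light_trials=light,
    )
    return bundle, truth


def generate_session(
    config: SynthConfig, seed: int | None = None
) -> tuple[SessionBundle, GroundTruth]:
    """Generate one control session (no light trials)."""
    return _assemble(config, config.seed if seed is None else seed, with_light=False)


def generate_inactivation_dataset(
    config: SynthConfig, seed: int | None = None
) -> tuple[SessionBundle, GroundTruth]:
    """Generate a session with interleaved control and light trials.

    On light trials the targeted region's intensities are multiplied by
    ``1 - direct_fraction`` from light onset (t=0, reach onset) and the other
    region's by ``1 - downstream_fraction`` from the configured latency.
    """
    return _assemble(config, config.seed if seed is None else seed, with_light=True)
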