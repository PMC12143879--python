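"""Configuration dataclasses for the synthetic session generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

MAX_DELAY_MS = 200.0


@dataclass
class PairCoupling:
    """Directed hazard coupling between two units.

    A transient hazard increment (alpha function, 2 ms rise) is added to the
    target unit ``delay_ms`` after each source spike.
    """

    source_region: str
    source_unit: int
    target_region: str
    target_unit: int
    delay_ms: float
    gain: float  # peak hazard increment, spikes/s

    def __post_init__(self) -> None:
        if self.delay_ms < 0:
            raise ValueError("coupling delay must be nonnegative")
        if self.gain < 0:
            raise ValueError("coupling gain must be nonnegative")


@dataclass
class InactivationSpec:
    """Multiplicative suppression applied on light trials.

    ``target_region`` is scaled by ``1 - direct_fraction`` from light onset;
    the other region is scaled by ``1 - downstream_fraction`` starting
    ``downstream_latency_ms`` later.
    """

    target_region: str = "A"
    direct_fraction: float = 0.9
    downstream_fraction: float = 0.3
    downstream_latency_ms: float = 10.0

    def __post_init__(self) -> None:
        for f in (self.direct_fraction, self.downstream_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("suppression fractions must lie in [0, 1]")
        if self.target_region not in ("A", "B"):
            raise ValueError("target_region must be 'A' or 'B'")


@dataclass
class EMGParams:
    baseline_mean: float = 0.02
    baseline_sd: float = 0.005
    burst_amplitude: float = 1.0
    burst_rise_ms: float = 30.0
    burst_hold_ms: float = 250.0
    burst_fall_ms: float = 100.0
    n_muscles: int = 4

    def __post_init__(self) -> None:
        if self.baseline_sd < 0 or self.burst_amplitude < 0:
            raise ValueError("EMG amplitudes must be nonnegative")


@dataclass
class SynthConfig:
    """Ground-truth parameters for one synthetic session."""

    n_units_per_region: int = 30
    n_trials: int = 60
    trial_window: tuple[float, float] = (-200.0, 800.0)  # ms around reach onset
    n_across_latents: int = 2
    n_within_latents: int = 2
    latent_delays: Sequence[float] = (-30.0, 10.0)  # ms; negative = region A leads
    latent_timescales: float | Sequence[float] = 80.0  # ms
    loading_scale: float = 8.0  # spikes/s per unit-variance latent
    baseline_rate_range: tuple[float, float] = (4.0, 16.0)  # spikes/s
    pair_coupling: Sequence[PairCoupling] = field(default_factory=list)
    inactivation: InactivationSpec | None = None
    emg_params: EMGParams = field(default_factory=EMGParams)
    inter_trial_gap_s: float = 2.0
    light_fraction: float = 0.5
    network_lead_ms: float = 30.0
    # reach-locked rate bump (movement-related activity); region A's bump
    # precedes region B's by event_lead_ms when positive
    event_amplitude: float = 0.0
    event_lead_ms: float = 0.0
    event_center_ms: float = 150.0
    event_sd_ms: float = 60.0
    # trailing recording beyond the last trial; must accommodate the
    # 5-10 s shifted-control placements
    tail_padding_s: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.emg_params, dict):
            self.emg_params = EMGParams(**self.emg_params)
        if isinstance(self.inactivation, dict):
            self.inactivation = InactivationSpec(**self.inactivation)
        self.pair_coupling = [
            PairCoupling(**c) if isinstance(c, dict) else c for c in self.pair_coupling
        ]
        delays = np.atleast_1d(np.asarray(self.latent_delays, dtype=float))
        if delays.size != self.n_across_latents:
            raise ValueError(
                f"latent_delays has {delays.size} entries for "
                f"{self.n_across_latents} across-region latents"
            )
        if np.any(np.abs(delays) > MAX_DELAY_MS):
            raise ValueError(f"latent delays must lie within +/-{MAX_DELAY_MS} ms")
        span = self.trial_window[1] - self.trial_window[0]
        if span <= 0:
            raise ValueError("trial window must have positive duration")
        if np.any(np.abs(delays) >= span):
            raise ValueError("latent delay exceeds the trial window")
        if not np.all(np.isfinite(delays)):
            raise ValueError("latent delays must be finite")
        ts = np.atleast_1d(np.asarray(self.latent_timescales, dtype=float))
        if np.any(ts <= 0):
            raise ValueError("latent timescales must be positive")
        lo, hi = self.baseline_rate_range
        if lo < 0 or hi < lo:
            raise ValueError("baseline rates must be nonnegative with lo <= hi")
        if self.inter_trial_gap_s < 2.0:
            raise ValueError(
                "inter-trial gap below 2 s invalidates circular-shift nulls"
            )

    @property
    def delays(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.latent_delays, dtype=float))

    def timescale_for(self, kind: str, index: int) -> float:
        """Timescale (ms) for latent ``index`` of kind 'across' or 'within'."""
        ts = np.atleast_1d(np.asarray(self.latent_timescales, dtype=float))
        if ts.size == 1:
            return float(ts[0])
        if kind == "across":
            return float(ts[index % ts.size])
        return float(ts[(self.n_across_latents + index) % ts.size])

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_window[1] - self.trial_window[0]))

    def to_dict(self) -> dict:
        return asdict(self)
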