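"""Structural and training configuration for the dual network."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class DualNetworkSpec:
    n_per_region: int = 500
    excitatory_fraction: float = 0.8
    p_within: float = 0.05
    p_across: float = 0.001  # excitatory sources only
    n_muscle_readout: int = 100  # per region; barred from across projections
    n_neural_readout: int = 100  # per region; disjoint from muscle subset
    dt_ms: float = 1.0
    tau_ms: float = 10.0
    noise_sd: float = 0.0
    init_weight_scale: float = 1.0

    def __post_init__(self) -> None:
        n_exc = int(round(self.n_per_region * self.excitatory_fraction))
        if self.n_muscle_readout + self.n_neural_readout > n_exc:
            raise ValueError("readout subsets exceed the excitatory pool")


@dataclass
class TrainingConfig:
    max_trials: int = 100_000  # total condition presentations
    learning_rate: float = 2e-3
    symmetry_lambda: float = 0.0  # penalty on |sum W_AB - sum W_BA|
    target_error: float = 0.05  # normalized MSE for early stopping
    plateau_iters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.symmetry_lambda < 0:
            raise ValueError("symmetry penalty weight must be >= 0")
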