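"""Construction of constrained dual-population network instances."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spec import DualNetworkSpec


@dataclass
class NetworkInstance:
    """Weights, masks and routing for one network instance.

    ``W[i, j]`` is the weight from unit j to unit i. Dale consistency is
    per source column: excitatory units have nonnegative outgoing weights,
    inhibitory units nonpositive. ``zero_mask`` entries fixed at 0 stay 0.
    """

    spec: DualNetworkSpec
    W: np.ndarray
    zero_mask: np.ndarray  # bool, True where a connection exists
    excitatory: np.ndarray  # bool per unit
    region: np.ndarray  # 'A' / 'B' per unit
    muscle_subset: np.ndarray  # unit indices (200 total)
    neural_subset_a: np.ndarray
    neural_subset_b: np.ndarray
    muscle_w: np.ndarray  # trainable readout over muscle_subset
    w_go: np.ndarray  # fixed input weights, all units
    w_light: np.ndarray  # fixed, nonzero only on inhibitory units
    bias: np.ndarray  # fixed

    history: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    def sign_vector(self) -> np.ndarray:
        return np.where(self.excitatory, 1.0, -1.0)

    def project_constraints(self) -> None:
        """Re-impose the zero mask and Dale sign pattern on W."""
        self.W *= self.zero_mask
        exc_cols = self.excitatory
        self.W[:, exc_cols] = np.maximum(self.W[:, exc_cols], 0.0)
        self.W[:, ~exc_cols] = np.minimum(self.W[:, ~exc_cols], 0.0)

    def across_mask(self, source_region: str) -> np.ndarray:
        """Bool mask of existing connections from one region to the other."""
        src = self.region == source_region
        tgt = self.region != source_region
        return self.zero_mask & np.outer(tgt, src)

    def audit_constraints(self) -> bool:
        """True when zero mask and Dale signs are intact."""
        if np.any(self.W[~self.zero_mask] != 0.0):
            return False
        if np.any(self.W[:, self.excitatory] < 0.0):
            return False
        if np.any(self.W[:, ~self.excitatory] > 0.0):
            return False
        return True


def build(spec: DualNetworkSpec, seed: int = 0) -> NetworkInstance:
    """Draw masks, readout subsets and signed initial weights.

    Within-region connections exist with probability ``p_within``;
    across-region connections with probability ``p_across``, from
    excitatory sources only, and never from muscle-readout units.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_per_region
    N = 2 * n
    n_exc = int(round(n * spec.excitatory_fraction))

    region = np.array(["A"] * n + ["B"] * n)
    excitatory = np.zeros(N, dtype=bool)
    excitatory[:n_exc] = True
    excitatory[n : n + n_exc] = True

    subsets = {}
    for r, offset in (("A", 0), ("B", n)):
        exc_ids = offset + rng.permutation(n_exc)
        subsets[("muscle", r)] = exc_ids[: spec.n_muscle_readout]
        subsets[("neural", r)] = exc_ids[
            spec.n_muscle_readout : spec.n_muscle_readout + spec.n_neural_readout
        ]
    muscle_subset = np.concatenate([subsets[("muscle", "A")], subsets[("muscle", "B")]])

    zero_mask = np.zeros((N, N), dtype=bool)
    same = region[:, None] == region[None, :]
    zero_mask[same] = rng.uniform(size=same.sum()) < spec.p_within
    np.fill_diagonal(zero_mask, False)

    allowed_src = excitatory.copy()
    allowed_src[muscle_subset] = False  # muscle units never project across
    across = (~same) & allowed_src[None, :]
    zero_mask[across] = rng.uniform(size=across.sum()) < spec.p_across

    # inhibitory magnitudes scaled by the E/I count ratio so mean drive is
    # balanced at initialization (an unbalanced 80/20 ReLU network explodes)
    scale = 0.5 * spec.init_weight_scale / np.sqrt(max(spec.p_within * n, 1.0))
    balance = n_exc / max(n - n_exc, 1)
    W = np.abs(rng.normal(0.0, scale, size=(N, N)))
    W *= np.where(excitatory[None, :], 1.0, -balance)
    W *= zero_mask

    muscle_w = rng.normal(0.0, 0.05, size=muscle_subset.size)
    w_go = rng.uniform(0.0, 0.3, size=N)
    w_light = np.where(~excitatory, rng.uniform(1.0, 2.0, size=N), 0.0)
    bias = np.full(N, 0.1)

    return NetworkInstance(
        spec=spec,
        W=W,
        zero_mask=zero_mask,
        excitatory=excitatory,
        region=region,
        muscle_subset=muscle_subset,
        neural_subset_a=subsets[("neural", "A")],
        neural_subset_b=subsets[("neural", "B")],
        muscle_w=muscle_w,
        w_go=w_go,
        w_light=w_light,
        bias=bias,
    )
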