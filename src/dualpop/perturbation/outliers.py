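"""Pre-onset outlier-trial exclusion for perturbation analyses.

Control and light trials are pooled: the perturbation may change trial
outcome, so post-onset data cannot be used for exclusion.
"""

from __future__ import annotations

import numpy as np


def _mean_pairwise_distance(segs: np.ndarray, reduce: str) -> np.ndarray:
    """Per-trial mean distance to all other trials.

    ``segs`` is (n_trials, n_channels, n_samples); distances are Euclidean
    per channel, then summed ('sum', EMG muscles) or averaged ('mean',
    neurons) across channels before averaging over the other trials.
    """
    n = segs.shape[0]
    diff = segs[:, None, :, :] - segs[None, :, :, :]
    d = np.sqrt((diff**2).sum(axis=3))  # (n, n, n_channels)
    d = d.sum(axis=2) if reduce == "sum" else d.mean(axis=2)
    return d.sum(axis=1) / (n - 1)


def emg_outlier_mask(pre_onset_segments: np.ndarray) -> np.ndarray:
    """Keep-mask over pooled trials from pre-onset EMG distance.

    ``pre_onset_segments``: (n_trials, n_muscles, n_samples) envelope
    segments over the 50 ms before light/trial onset. Trials whose mean
    pairwise distance (summed across muscles) exceeds mean + 1 SD are
    excluded.
    """
    segs = np.asarray(pre_onset_segments, dtype=float)
    if segs.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    d = _mean_pairwise_distance(segs, reduce="sum")
    return d <= d.mean() + d.std(ddof=0)


def neural_outlier_mask(pre_onset_rates: np.ndarray) -> np.ndarray:
    """Keep-mask from pre-onset firing-rate distance.

    ``pre_onset_rates``: (n_trials, n_neurons, n_samples) over the 20 ms
    before light/trial onset. The threshold is mean + SD/4 of the per-trial
    across-neuron mean distances.
    """
    segs = np.asarray(pre_onset_rates, dtype=float)
    if segs.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    d = _mean_pairwise_distance(segs, reduce="mean")
    return d <= d.mean() + d.std(ddof=0) / 4.0
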