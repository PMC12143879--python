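"""Binned count matrices and eligibility rules for the delayed-latent fit."""

from __future__ import annotations

import numpy as np

BIN_MS = 20.0
WINDOW_MS = (-200.0, 800.0)
N_BINS = int((WINDOW_MS[1] - WINDOW_MS[0]) / BIN_MS)  # 50
MIN_NEURONS = 12


class SessionIneligibleError(ValueError):
    """Raised when a session cannot support the delayed-latent fit."""


def _bin_trial(spikes_ms: np.ndarray, onset_ms: float) -> np.ndarray:
    rel = spikes_ms - onset_ms
    edges = WINDOW_MS[0] + BIN_MS * np.arange(N_BINS + 1)
    return np.histogram(rel, bins=edges)[0].astype(float)


def prepare_counts(
    spike_times_s: list[np.ndarray],
    regions: np.ndarray,
    onsets_ms: np.ndarray,
) -> dict:
    """Per-region binned count matrices for qualifying trials.

    Firing in 20 ms bins from 200 ms before to 800 ms after reach onset
    (50 bins). Any neuron whose total spike count within the analysis
    windows is strictly fewer than half the number of trials is excluded;
    after exclusion each region needs at least 12 neurons or the session is
    reported ineligible.

    Returns dict with keys 'A' and 'B': (n_trials, n_units, 50) arrays,
    plus 'units_A' / 'units_B' index arrays.
    """
    regions = np.asarray(regions)
    onsets = np.asarray(onsets_ms, dtype=float)
    n_trials = onsets.size
    out = {}
    for region in ("A", "B"):
        idx = np.flatnonzero(regions == region)
        if idx.size == 0:
            raise SessionIneligibleError(f"region {region} has no units")
        counts = np.zeros((n_trials, idx.size, N_BINS))
        for j, u in enumerate(idx):
            sp = np.asarray(spike_times_s[u]) * 1000.0
            for t, onset in enumerate(onsets):
                counts[t, j] = _bin_trial(sp, onset)
        totals = counts.sum(axis=(0, 2))
        keep = totals >= n_trials / 2.0  # strict "fewer than" excludes
        if keep.sum() < MIN_NEURONS:
            raise SessionIneligibleError(
                f"region {region}: {int(keep.sum())} neurons after exclusion "
                f"(need {MIN_NEURONS})"
            )
        out[region] = counts[:, keep]
        out[f"units_{region}"] = idx[keep]
    return out
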