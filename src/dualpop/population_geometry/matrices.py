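"""Concatenated trial-averaged activity matrices.

Eight alignment segments — reach onset and grasp, for each of the four
spouts — each spanning 99 ms before to 100 ms after the event at 1 ms
resolution, giving 8 x 200 = 1600 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SEGMENT_WINDOW_MS = (-99, 100)  # inclusive of -99, exclusive of +101
SEGMENT_LEN = SEGMENT_WINDOW_MS[1] - SEGMENT_WINDOW_MS[0] + 1  # 200
SPOUTS = (1, 2, 3, 4)
ALIGN_EVENTS = ("onset_ms", "grasp_ms")
N_ROWS = len(ALIGN_EVENTS) * len(SPOUTS) * SEGMENT_LEN  # 1600


@dataclass
class ActivityMatrix:
    """(1600, n_units) concatenated trial-average matrix for one region."""

    values: np.ndarray
    region: str
    segment_bounds: list[tuple[int, int]]
    segment_labels: list[str]

    @property
    def centered(self) -> np.ndarray:
        return self.values - self.values.mean(axis=0, keepdims=True)

    @property
    def column_variance(self) -> np.ndarray:
        """Per-neuron summed squared deviation (the v summands)."""
        return (self.centered**2).sum(axis=0)

    @property
    def total_variance(self) -> float:
        return float(self.column_variance.sum())


def _event_times(trials: pd.DataFrame, align: str) -> np.ndarray:
    if align == "onset_ms" and "onset_ms" not in trials.columns:
        return trials["reach_onset_ms"].to_numpy(dtype=float)
    return trials[align].to_numpy(dtype=float)


def trial_average_matrix(
    rates: np.ndarray,
    trials: pd.DataFrame,
    region: str = "",
    lag_ms: float = 0.0,
) -> ActivityMatrix:
    """Build the 1600-row concatenated trial-average matrix.

    Parameters
    ----------
    rates
        (n_units, T) 1 kHz rate series for the session.
    trials
        Qualifying trials only; needs onset/grasp times and a ``spout``
        column. A spout without any qualifying trial raises ``ValueError``.
    lag_ms
        Shift applied to every alignment event before extraction (used by
        lag scans). Trials whose shifted segment leaves the recording are
        dropped with a warning by the caller's mask.
    """
    n_units, T = rates.shape
    blocks, bounds, labels = [], [], []
    row = 0
    for align in ALIGN_EVENTS:
        events = _event_times(trials, align) + lag_ms
        spouts = trials["spout"].to_numpy()
        for spout in SPOUTS:
            sel = np.flatnonzero(spouts == spout)
            if sel.size == 0:
                raise ValueError(f"no qualifying trials for spout {spout} ({align})")
            seg = np.zeros((SEGMENT_LEN, n_units))
            n_used = 0
            for i in sel:
                lo = int(round(events[i])) + SEGMENT_WINDOW_MS[0]
                hi = lo + SEGMENT_LEN
                if lo < 0 or hi > T:
                    continue  # shifted out of range: drop trial
                seg += rates[:, lo:hi].T
                n_used += 1
            if n_used == 0:
                raise ValueError(
                    f"all trials for spout {spout} ({align}) fell out of range"
                )
            blocks.append(seg / n_used)
            bounds.append((row, row + SEGMENT_LEN))
            labels.append(f"{align}:spout{spout}")
            row += SEGMENT_LEN
    return ActivityMatrix(
        values=np.vstack(blocks),
        region=region,
        segment_bounds=bounds,
        segment_labels=labels,
    )


def shifted_time_control(
    rates: np.ndarray,
    trials: pd.DataFrame,
    region: str = "",
    shift_range_ms: tuple[float, float] = (5000.0, 10000.0),
    seed: int = 0,
    max_attempts: int = 1000,
) -> ActivityMatrix:
    """Control matrix from events shifted 5-10 s into the future.

    Each reach and grasp event is shifted by an independent random amount;
    shifted segments may not overlap any original trial epoch or any other
    shifted segment, destroying behavior-locked correlation while keeping
    the extraction machinery identical.
    """
    rng = np.random.default_rng(seed)
    T = rates.shape[1]

    occupied: list[tuple[float, float]] = []
    for align in ALIGN_EVENTS:
        for ev in _event_times(trials, align):
            occupied.append((ev + SEGMENT_WINDOW_MS[0], ev + SEGMENT_WINDOW_MS[1]))

    def _overlaps(lo: float, hi: float) -> bool:
        return any(lo < b and hi > a for a, b in occupied)

    shifted = trials.copy()
    for align in ALIGN_EVENTS:
        events = _event_times(trials, align)
        new_events = np.empty_like(events)
        for i, ev in enumerate(events):
            for _ in range(max_attempts):
                cand = ev + rng.uniform(*shift_range_ms)
                lo, hi = cand + SEGMENT_WINDOW_MS[0], cand + SEGMENT_WINDOW_MS[1]
                if hi < T and not _overlaps(lo, hi):
                    new_events[i] = cand
                    occupied.append((lo, hi))
                    break
            else:
                raise RuntimeError(
                    "no non-overlapping placement found for shifted event"
                )
        col = "reach_onset_ms" if align == "onset_ms" else align
        shifted[col] = new_events
        if align == "onset_ms" and "onset_ms" in shifted.columns:
            shifted["onset_ms"] = new_events
    return trial_average_matrix(rates, shifted, region=region)
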