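"""Movement-epoch extraction and spike-train concatenation."""

from __future__ import annotations

import numpy as np

K_SD = 7.0
MERGE_GAP_MS = 100
MIN_EPOCH_MS = 10
DEFAULT_PAD_MS = 50  # longer than the 30 ms maximum metric delay


def movement_epochs(
    summed_env: np.ndarray,
    quiescent_mean: float,
    quiescent_sd: float,
) -> list[tuple[int, int]]:
    """Half-open [start, end) movement epochs at 1 kHz.

    Threshold = quiescent mean + 7 SD; below-threshold gaps of 100 ms or
    less are reclassified as movement; movement runs shorter than 10 ms are
    dropped.
    """
    env = np.asarray(summed_env, dtype=float)
    above = env > quiescent_mean + K_SD * quiescent_sd
    if not above.any():
        raise ValueError("no movement epochs above threshold")

    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]

    # merge short gaps
    merged = [(int(starts[0]), int(ends[0]))]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] <= MERGE_GAP_MS:
            merged[-1] = (merged[-1][0], int(e))
        else:
            merged.append((int(s), int(e)))
    # drop too-short epochs
    out = [(s, e) for s, e in merged if e - s >= MIN_EPOCH_MS]
    if not out:
        raise ValueError("no movement epochs after duration filtering")
    return out


def concatenate_epochs(
    spike_times_s: np.ndarray,
    epochs_ms: list[tuple[int, int]],
    pad_ms: int = DEFAULT_PAD_MS,
) -> np.ndarray:
    """Binary 1 ms train over concatenated epochs with zero pads between.

    The pads prevent spikes at the end of one epoch from being read as
    preceding spikes at the start of the next.
    """
    sp_ms = np.asarray(spike_times_s, dtype=float) * 1000.0
    pieces = []
    pad = np.zeros(pad_ms, dtype=np.int8)
    for k, (s, e) in enumerate(epochs_ms):
        seg = np.zeros(e - s, dtype=np.int8)
        idx = np.floor(sp_ms[(sp_ms >= s) & (sp_ms < e)]).astype(int) - s
        seg[idx] = 1
        if k:
            pieces.append(pad)
        pieces.append(seg)
    return np.concatenate(pieces)
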