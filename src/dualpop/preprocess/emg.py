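"""EMG conditioning: downsample, high-pass, rectify, smooth."""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

TARGET_FS_HZ = 1000
HIGHPASS_HZ = 250.0
SMOOTH_SD_MS = 10.0


def emg_envelope(
    raw: np.ndarray,
    fs_hz: float,
    highpass_hz: float = HIGHPASS_HZ,
    smooth_sd_ms: float = SMOOTH_SD_MS,
) -> np.ndarray:
    """Condition raw multi-muscle EMG into 1 kHz envelopes.

    Downsamples to 1 kHz, high-pass filters (zero-phase 4th-order
    Butterworth), rectifies, and convolves with a Gaussian (10 ms SD).

    Parameters
    ----------
    raw
        (n_muscles, n_samples) or (n_samples,) raw EMG.
    fs_hz
        Input sampling rate; must be at least 1 kHz so a 1 kHz envelope with
        a 250 Hz high-pass edge is representable.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if fs_hz < TARGET_FS_HZ:
        raise ValueError(
            f"input rate {fs_hz} Hz is below {TARGET_FS_HZ} Hz; the "
            f"{highpass_hz} Hz high-pass edge cannot be represented"
        )
    if fs_hz > TARGET_FS_HZ:
        # polyphase resampling handles non-integer ratios
        up, down = TARGET_FS_HZ, int(round(fs_hz))
        g = np.gcd(up, down)
        x = signal.resample_poly(raw, up // g, down // g, axis=1)
    else:
        x = raw
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=TARGET_FS_HZ, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)
    x = np.abs(x)
    x = gaussian_filter1d(x, smooth_sd_ms, axis=1, mode="constant")
    return x
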