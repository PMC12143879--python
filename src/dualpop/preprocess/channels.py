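"""Pathological-channel exclusion from high-frequency spectral weight."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter

BAND_HZ = (300.0, 1000.0)
MEDIAN_WINDOW = 10
K_SD = 3.0


def exclude_channels(
    raw: np.ndarray, fs_hz: float, band_hz: tuple[float, float] = BAND_HZ
) -> np.ndarray:
    """Keep-mask over channels (False = pathological).

    Per channel, spectral amplitudes in the 300-1000 Hz band are summed; a
    running median over 10 channels is subtracted; channels whose residual
    lies beyond 3 SD are flagged. DC offsets do not enter the band and so
    cannot affect the mask.
    """
    x = np.asarray(raw, dtype=float)
    if x.shape[0] < 20:
        raise ValueError("need at least 20 channels")
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / fs_hz)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    w = np.abs(np.fft.rfft(x, axis=1))[:, in_band].sum(axis=1)
    med = median_filter(w, size=MEDIAN_WINDOW, mode="nearest")
    resid = w - med
    sd = resid.std(ddof=0)
    if sd == 0:
        return np.ones(x.shape[0], dtype=bool)
    return np.abs(resid) <= K_SD * sd
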