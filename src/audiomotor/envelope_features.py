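"""Spectral covariates of an envelope: sub-10 Hz peak height and FWHM width.

The amplitude spectrum is |FFT| of the mean-subtracted envelope.  The
strongest local maximum strictly between 0 and ``f_max`` is the peak; its
width is the full width at half maximum, with the half-height crossings
located by linear interpolation between spectral bins.  A narrow peak
indicates a strongly rhythmic envelope; width and height enter downstream
models as per-trial covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .envelopes import EnvelopeSignal
from .errors import InvalidInputError, NoPeakError

__all__ = ["SpectralPeakFeatures", "spectral_peak"]


@dataclass(frozen=True)
class SpectralPeakFeatures:
    peak_freq: float
    peak_amp: float
    peak_width: float
    n_fft: int
    freq_resolution: float
    width_truncated: bool = False


def _half_crossing(freqs, amp, i_from, i_to, half):
    """Interpolated frequency where amp crosses `half` between two bins."""
    f0, f1 = freqs[i_from], freqs[i_to]
    a0, a1 = amp[i_from], amp[i_to]
    if a1 == a0:
        return f1
    return f0 + (half - a0) * (f1 - f0) / (a1 - a0)


def spectral_peak(env: EnvelopeSignal, f_max: float = 10.0) -> SpectralPeakFeatures:
    """Strongest sub-``f_max`` spectral peak of a mean-subtracted envelope.

    Raises
    ------
    NoPeakError
        If no local maximum exists below ``f_max`` (e.g. an all-zero
        envelope).
    InvalidInputError
        If the envelope is shorter than 2 s.
    """
    if env.duration < 2.0:
        raise InvalidInputError("envelope must be at least 2 s long for spectral features")
    x = env.samples - env.samples.mean()
    n = len(x)
    amp = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(n, 1.0 / env.fs)
    df = freqs[1] - freqs[0]

    # search region: bins with 0 < f < f_max (DC excluded by construction)
    i_hi = int(np.searchsorted(freqs, f_max, side="left"))
    region = amp[:i_hi]
    peaks, _ = _signal.find_peaks(region)
    peaks = peaks[peaks > 0]
    if len(peaks) == 0:
        raise NoPeakError(f"no local spectral maximum below {f_max} Hz")
    # strongest peak; np.argmax ties break toward the lower-frequency bin
    best = peaks[int(np.argmax(region[peaks]))]
    half = region[best] / 2.0

    truncated = False
    # walk left
    i = best
    while i > 0 and region[i] > half:
        i -= 1
    if region[i] > half:
        f_left = freqs[i]
        truncated = True
    else:
        f_left = _half_crossing(freqs, region, i, i + 1, half)
    # walk right
    j = best
    while j < i_hi - 1 and region[j] > half:
        j += 1
    if region[j] > half:
        f_right = freqs[j]
        truncated = True
    else:
        f_right = _half_crossing(freqs, region, j, j - 1, half)

    width = max(float(f_right - f_left), float(df))
    return SpectralPeakFeatures(
        peak_freq=float(freqs[best]),
        peak_amp=float(region[best]),
        peak_width=width,
        n_fft=n,
        freq_resolution=float(df),
        width_truncated=truncated,
    )
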