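"""Zero-phase windowed-sinc FIR filtering shared by preprocessing,
source reconstruction and the simulator.

Filters are linear-phase Hamming-window FIRs applied once with the group
delay compensated (not filtfilt), so the designed magnitude response is
the effective response. Order follows the Hamming transition-width rule
numtaps ~= 3.3 / (transition_width / fs).
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def _numtaps(transition_hz: float, srate: float, max_frac: float = 0.45) -> int:
    n = int(np.ceil(3.3 * srate / transition_hz))
    n |= 1  # odd -> integer group delay, type-I FIR
    return n


def fir_apply(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a linear-phase FIR along the last axis, zero phase via delay
    compensation, reflect-padded at the edges."""
    delay = (len(taps) - 1) // 2
    pad = min(delay, data.shape[-1] - 1)
    padded = np.pad(data, [(0, 0)] * (data.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.oaconvolve(padded, taps[(None,) * (data.ndim - 1)], mode="same",
                            axes=-1)
    return out[..., pad:padded.shape[-1] - pad]


def highpass_taps(srate: float, f_lo: float = 0.25, f_hi: float = 0.75) -> np.ndarray:
    """High pass with transition band [f_lo, f_hi]; -6 dB at the midpoint."""
    cutoff = 0.5 * (f_lo + f_hi)
    n = _numtaps(f_hi - f_lo, srate)
    taps = signal.firwin(n, cutoff, fs=srate, pass_zero=False, window="hamming")
    taps[n // 2] -= taps.sum()      # exact null at DC
    return taps


def bandpass_taps(srate: float, band: tuple[float, float],
                  transition_hz: float | None = None) -> np.ndarray:
    lo, hi = band
    nyq = srate / 2.0
    hi = min(hi, 0.95 * nyq)
    if transition_hz is None:
        transition_hz = max(0.5, 0.25 * lo)
    n = _numtaps(transition_hz, srate)
    return signal.firwin(n, [max(lo, 0.1), hi], fs=srate, pass_zero=False,
                         window="hamming")


def highpass(data: np.ndarray, srate: float, f_lo: float = 0.25,
             f_hi: float = 0.75) -> np.ndarray:
    return fir_apply(data, highpass_taps(srate, f_lo, f_hi))


def bandpass(data: np.ndarray, srate: float, band: tuple[float, float]) -> np.ndarray:
    return fir_apply(data, bandpass_taps(srate, band))


def lowpass(data: np.ndarray, srate: float, cutoff: float,
            transition_hz: float | None = None) -> np.ndarray:
    if transition_hz is None:
        transition_hz = max(1.0, 0.1 * cutoff)
    taps = signal.firwin(_numtaps(transition_hz, srate), cutoff, fs=srate,
                         window="hamming")
    return fir_apply(data, taps)


def analytic_epoch(x: np.ndarray, taper_frac: float = 0.1) -> np.ndarray:
    """Analytic signal of an epoch (last axis) with a cosine edge taper
    (``taper_frac`` of the samples at each edge) to limit Hilbert edge
    artifacts on short segments."""
    n = x.shape[-1]
    w = signal.windows.tukey(n, alpha=2 * taper_frac)
    return signal.hilbert(x * w, axis=-1)
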