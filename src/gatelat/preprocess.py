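"""Motion-channel denoising: mains notch filter + moving median.

Only the position-sensor channel is filtered; the trigger and beam channels
are near-square logic signals and are analyzed raw.  The notch is applied
forward and backward (zero net phase) because a causal IIR notch would delay
the motion waveform and bias every downstream latency estimate by
milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigurationError

__all__ = ["FilterSpec", "notch_filter", "moving_median", "preprocess_motion"]


@dataclass
class FilterSpec:
    """Motion-channel filter settings.

    notch_freq : mains interference frequency to reject, Hz (default 50).
    notch_q : notch quality factor (bandwidth = notch_freq / Q).
    median_window : odd sample count of the moving median (default 11,
        i.e. 1.1 ms at 10 kHz — wide enough to swallow single-sample spikes,
        far too narrow to distort a multi-second breathing waveform).
    zero_phase : apply the notch forward-backward (default) or causally.
    """

    notch_freq: float = 50.0
    notch_q: float = 30.0
    median_window: int = 11
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.notch_freq < sampling_rate / 2:
            raise ConfigurationError(
                f"notch_freq: must lie in (0, Nyquist={sampling_rate / 2:g}) Hz"
            )
        if self.notch_q <= 0:
            raise ConfigurationError("notch_q: must be > 0")
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ConfigurationError("median_window: must be odd and >= 3")


def notch_filter(x: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Second-order IIR notch; zero-phase (filtfilt) by default.

    Edge transients are handled by even (reflect) extension; output length
    equals input length. DC gain is unity, so the motion baseline is
    untouched.
    """
    spec = spec or FilterSpec()
    spec.validate(sampling_rate)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=sampling_rate)
    if spec.zero_phase:
        return signal.filtfilt(b, a, x, padtype="even")
    return signal.lfilter(b, a, x)


def moving_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with reflect padding at the edges."""
    if window % 2 == 0:
        raise ConfigurationError("median_window: must be odd")
    if window > len(x):
        raise ConfigurationError("median_window: longer than the signal")
    return ndimage.median_filter(np.asarray(x, dtype=float), size=window, mode="reflect")


def preprocess_motion(x: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Full motion-channel chain: notch, then moving median."""
    spec = spec or FilterSpec()
    return moving_median(notch_filter(x, sampling_rate, spec), spec.median_window)
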