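"""In-memory container for a synchronized multi-channel recording.

A :class:`Recording` mirrors what a three-channel data-acquisition device
captures during a gating QA session: a common time base plus one analog
channel each for the motion surrogate (mm), the gating trigger line (V) and
the beam detector (V), nominally sampled at 10 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Maximum tolerated deviation of one sample interval from 1/sampling_rate (s).
TIME_UNIFORMITY_TOL = 1e-9


@dataclass
class Recording:
    """Synchronized three-channel time series.

    Parameters
    ----------
    sampling_rate : float
        Samples per second, common to all channels.
    time : ndarray
        Monotone sample times in seconds. May start at a negative value
        (simulated sessions pad half a period before the first peak).
    motion : ndarray
        Surrogate vertical position in mm.
    trigger : ndarray
        Gating trigger line in volts (two-state, nominally 0 / 12 V).
    beam : ndarray
        Beam detector output in volts (~100 mV step while the beam is on).
    metadata : dict
        Free-form provenance (scenario parameters, seed, software version).
    """

    sampling_rate: float
    time: np.ndarray
    motion: np.ndarray
    trigger: np.ndarray
    beam: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        self.trigger = np.asarray(self.trigger, dtype=float)
        self.beam = np.asarray(self.beam, dtype=float)
        n = self.time.size
        for name in ("motion", "trigger", "beam"):
            if getattr(self, name).size != n:
                raise ConfigurationError(
                    f"channel '{name}' has {getattr(self, name).size} samples, "
                    f"time axis has {n}"
                )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ConfigurationError("time: sample times must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sampling_rate)) > TIME_UNIFORMITY_TOL:
                raise ConfigurationError(
                    "time: sampling is not uniform at the declared sampling_rate"
                )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return float(self.time[-1] - self.time[0]) if self.time.size else 0.0
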