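"""Three-channel trace figure for visual QA of a recording."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .recording import Recording

__all__ = ["plot_recording"]


def plot_recording(
    recording: Recording,
    path: str | Path,
    t_start: Optional[float] = None,
    t_stop: Optional[float] = None,
) -> None:
    """Save a stacked motion / trigger / beam trace plot to ``path``."""
    t = recording.time
    sel = slice(None)
    if t_start is not None or t_stop is not None:
        lo = t_start if t_start is not None else t[0]
        hi = t_stop if t_stop is not None else t[-1]
        sel = (t >= lo) & (t <= hi)
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(10, 6))
    axes[0].plot(t[sel], recording.motion[sel], color="black", lw=0.8)
    axes[0].set_ylabel("motion (mm)")
    axes[1].plot(t[sel], recording.trigger[sel], color="tab:blue", lw=0.8)
    axes[1].set_ylabel("trigger (V)")
    axes[2].plot(t[sel], recording.beam[sel], color="tab:red", lw=0.8)
    axes[2].set_ylabel("beam (V)")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
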