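"""File formats: recordings (CSV), ground truth (JSON), per-cycle latencies (CSV).

All artifacts are plain text so QA records stay inspectable and diffable.
Recording CSVs carry ``#key=value`` metadata comment lines before the
header ``time_s,motion_mm,trigger_V,beam_V``; times are serialized with six
decimals (exact on the 0.1 ms grid of a 10 kHz recording).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import RecordingParseError
from .latency import CycleLatency
from .recording import Recording
from .simulate import CycleTruth, GroundTruth, ScenarioConfig

__all__ = [
    "RECORDING_COLUMNS",
    "read_recording",
    "write_recording",
    "read_ground_truth",
    "write_ground_truth",
    "read_latencies",
    "write_latencies",
]

RECORDING_COLUMNS = ("time_s", "motion_mm", "trigger_V", "beam_V")
LATENCY_COLUMNS = (
    "cycle", "tau_rpm_on_ms", "tau_rpm_off_ms", "tau_cyc_on_ms",
    "tau_cyc_off_ms", "tau_total_on_ms", "tau_total_off_ms", "complete",
)

#: tolerated deviation of a sample interval when validating files (s)
FILE_TIME_TOL = 1e-6


def write_recording(recording: Recording, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in recording.metadata.items():
            fh.write(f"#{k}={v}\n")
        fh.write(",".join(RECORDING_COLUMNS) + "\n")
        df = pd.DataFrame(
            {
                "time_s": recording.time,
                "motion_mm": recording.motion,
                "trigger_V": recording.trigger,
                "beam_V": recording.beam,
            }
        )
        df.to_csv(fh, index=False, header=False, float_format="%.6f")


def read_recording(path: str | Path) -> Recording:
    """Parse a recording CSV, validating header, NaNs and time uniformity."""
    path = Path(path)
    metadata: dict[str, str] = {}
    header_line = 0
    with open(path) as fh:
        for line in fh:
            header_line += 1
            line = line.strip()
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    metadata[k.strip()] = v.strip()
                continue
            if line:
                header = line
                break
        else:
            raise RecordingParseError(f"{path}: empty file")
    cols = tuple(c.strip() for c in header.split(","))
    missing = [c for c in RECORDING_COLUMNS if c not in cols]
    if missing:
        raise RecordingParseError(
            f"{path}, line {header_line}: missing column(s) {', '.join(missing)}"
        )
    df = pd.read_csv(path, comment="#")
    bad = df[list(RECORDING_COLUMNS)].isna()
    if bad.to_numpy().any():
        row = int(bad.any(axis=1).idxmax())
        raise RecordingParseError(
            f"{path}: NaN sample at data row {row} (file line ~{header_line + 1 + row})"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise RecordingParseError(f"{path}: fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise RecordingParseError(
            f"{path}: non-monotone time at data row {row} "
            f"(file line ~{header_line + 1 + row})"
        )
    dt_nominal = float(np.median(dt))
    dev = np.abs(dt - dt_nominal)
    if np.max(dev) > FILE_TIME_TOL:
        row = int(np.argmax(dev)) + 1
        raise RecordingParseError(
            f"{path}: non-uniform sampling at data row {row} "
            f"(deviation {np.max(dev):.2e} s)"
        )
    fs = 1.0 / dt_nominal
    # snap to an integer rate when within the file precision (e.g. 10 kHz)
    if abs(fs - round(fs)) < 0.5:
        fs = float(round(fs))
    # rebuild a numerically uniform axis anchored at the first sample so the
    # in-memory invariant (1e-9 s) holds despite 6-decimal file rounding
    time = t[0] + np.arange(t.size) / fs
    return Recording(
        sampling_rate=fs,
        time=time,
        motion=df["motion_mm"].to_numpy(dtype=float),
        trigger=df["trigger_V"].to_numpy(dtype=float),
        beam=df["beam_V"].to_numpy(dtype=float),
        metadata=metadata,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "config": dataclasses.asdict(truth.config) if truth.config else None,
        "cycles": [dataclasses.asdict(c) for c in truth.cycles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    config = ScenarioConfig(**payload["config"]) if payload.get("config") else None
    cycles = [CycleTruth(**c) for c in payload["cycles"]]
    return GroundTruth(cycles=cycles, config=config)


def write_latencies(
    latencies: Sequence[CycleLatency],
    path: str | Path,
    metadata: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        fh.write(",".join(LATENCY_COLUMNS) + "\n")
        for lat in latencies:
            vals = [
                str(lat.cycle_index),
                *(
                    f"{getattr(lat, f):.4f}" if not math.isnan(getattr(lat, f)) else ""
                    for f in (
                        "tau_rpm_on", "tau_rpm_off", "tau_cyc_on",
                        "tau_cyc_off", "tau_total_on", "tau_total_off",
                    )
                ),
                "1" if lat.complete else "0",
            ]
            fh.write(",".join(vals) + "\n")


def read_latencies(path: str | Path) -> tuple[list[CycleLatency], dict]:
    """Read a per-cycle latency CSV; returns (latencies, metadata)."""
    metadata: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                k, v = line[1:].rstrip("\n").split("=", 1)
                metadata[k.strip()] = v.strip()
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    missing = [c for c in LATENCY_COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing column(s) {', '.join(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CycleLatency(
                cycle_index=int(row["cycle"]),
                tau_rpm_on=float(row["tau_rpm_on_ms"]) if pd.notna(row["tau_rpm_on_ms"]) else math.nan,
                tau_rpm_off=float(row["tau_rpm_off_ms"]) if pd.notna(row["tau_rpm_off_ms"]) else math.nan,
                tau_cyc_on=float(row["tau_cyc_on_ms"]) if pd.notna(row["tau_cyc_on_ms"]) else math.nan,
                tau_cyc_off=float(row["tau_cyc_off_ms"]) if pd.notna(row["tau_cyc_off_ms"]) else math.nan,
                tau_total_on=float(row["tau_total_on_ms"]) if pd.notna(row["tau_total_on_ms"]) else math.nan,
                tau_total_off=float(row["tau_total_off_ms"]) if pd.notna(row["tau_total_off_ms"]) else math.nan,
                complete=bool(int(row["complete"])),
            )
        )
    return out, metadata
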