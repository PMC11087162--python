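"""Scenario-level statistics and the QA summary table.

One :class:`ScenarioSummary` holds mean +- sample standard deviation of the
six latencies over the repeated cycles of one motion pattern; the grand
summary adds a Mean row across scenarios (unweighted mean of scenario
means; pooled per-cycle standard deviation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .latency import CycleLatency

__all__ = [
    "LATENCY_FIELDS",
    "ScenarioSummary",
    "summarize_scenario",
    "grand_summary",
    "render_report",
    "fmt_value",
]

#: order of the six latency columns in every table
LATENCY_FIELDS = ("rpm_on", "rpm_off", "cyc_on", "cyc_off", "total_on", "total_off")

_COLUMN_TITLES = {
    "rpm_on": "tau_RPM-on (ms)",
    "rpm_off": "tau_RPM-off (ms)",
    "cyc_on": "tau_CYC-on (ms)",
    "cyc_off": "tau_CYC-off (ms)",
    "total_on": "tau_total-on (ms)",
    "total_off": "tau_total-off (ms)",
}


@dataclass
class ScenarioSummary:
    """Latency statistics for one motion pattern (all values in ms)."""

    amplitude: Optional[float]      # mm; None for the grand row
    period: Optional[float]         # s; None for the grand row
    n_cycles_used: int
    rpm_on_mean: float = math.nan
    rpm_on_sd: float = math.nan
    rpm_off_mean: float = math.nan
    rpm_off_sd: float = math.nan
    cyc_on_mean: float = math.nan
    cyc_on_sd: float = math.nan
    cyc_off_mean: float = math.nan
    cyc_off_sd: float = math.nan
    total_on_mean: float = math.nan
    total_on_sd: float = math.nan
    total_off_mean: float = math.nan
    total_off_sd: float = math.nan

    def mean(self, field: str) -> float:
        return getattr(self, f"{field}_mean")

    def sd(self, field: str) -> float:
        return getattr(self, f"{field}_sd")


def summarize_scenario(
    latencies: Sequence[CycleLatency], amplitude: float, period: float
) -> ScenarioSummary:
    """Mean and sample (n-1) standard deviation over complete cycles.

    Totals are derived from the component means so the additivity of the
    total latencies is preserved exactly at the summary level too.
    """
    complete = [lat for lat in latencies if lat.complete]
    if len(complete) < 2:
        raise InsufficientDataError(
            f"{len(complete)} complete cycle(s); need >= 2 for a summary"
        )
    values = {
        f: np.array([getattr(lat, f"tau_{f}") for lat in complete])
        for f in LATENCY_FIELDS
    }
    kw = {}
    for f in LATENCY_FIELDS:
        kw[f"{f}_sd"] = float(np.std(values[f], ddof=1))
    for f in ("rpm_on", "rpm_off", "cyc_on", "cyc_off"):
        kw[f"{f}_mean"] = float(np.mean(values[f]))
    kw["total_on_mean"] = kw["rpm_on_mean"] + kw["cyc_on_mean"]
    kw["total_off_mean"] = kw["rpm_off_mean"] + kw["cyc_off_mean"]
    return ScenarioSummary(
        amplitude=amplitude, period=period, n_cycles_used=len(complete), **kw
    )


def grand_summary(
    summaries: Sequence[ScenarioSummary],
    mean_method: str = "scenario",
    std_method: str = "pooled",
) -> ScenarioSummary:
    """Mean row across scenarios.

    mean_method
        ``"scenario"`` (default): unweighted arithmetic mean of scenario
        means — each motion pattern counts equally regardless of how many
        cycles survived.  ``"pooled"``: cycle-count-weighted mean.
    std_method
        ``"pooled"`` (default): standard deviation of the pooled per-cycle
        population, reconstructed from each scenario's (n, mean, sd);
        ``"mean"``: unweighted mean of the scenario standard deviations.
    """
    if not summaries:
        raise InsufficientDataError("no scenario summaries to aggregate")
    if mean_method not in ("scenario", "pooled"):
        raise ConfigurationError(f"mean_method: unknown value {mean_method!r}")
    if std_method not in ("pooled", "mean"):
        raise ConfigurationError(f"std_method: unknown value {std_method!r}")

    ns = np.array([s.n_cycles_used for s in summaries], dtype=float)
    total_n = int(ns.sum())
    kw = {}
    for f in LATENCY_FIELDS:
        means = np.array([s.mean(f) for s in summaries])
        sds = np.array([s.sd(f) for s in summaries])
        if mean_method == "scenario":
            kw[f"{f}_mean"] = float(np.mean(means))
        else:
            kw[f"{f}_mean"] = float(np.sum(ns * means) / ns.sum())
        if std_method == "mean":
            kw[f"{f}_sd"] = float(np.mean(sds))
        else:
            # pooled variance about the cycle-weighted grand mean
            mw = float(np.sum(ns * means) / ns.sum())
            ss = float(np.sum((ns - 1) * sds**2 + ns * (means - mw) ** 2))
            kw[f"{f}_sd"] = math.sqrt(ss / (total_n - 1)) if total_n > 1 else math.nan
    return ScenarioSummary(amplitude=None, period=None, n_cycles_used=total_n, **kw)


def fmt_value(x: float, decimals: int = 2) -> str:
    """Round half-away-from-zero to the given decimals, fixed-point string."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    q = Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP
    )
    return f"{q:.{decimals}f}"


def _cell(summary: ScenarioSummary, f: str) -> str:
    return f"{fmt_value(summary.mean(f))} ± {fmt_value(summary.sd(f))}"


def render_report(
    summaries: Sequence[ScenarioSummary],
    grand: Optional[ScenarioSummary] = None,
    format: str = "text",
    provenance: Optional[dict] = None,
) -> str:
    """Render the summary table.

    ``format="text"`` gives a fixed-width human-readable table with
    ``mean +- sd`` cells rounded half-away-from-zero to 2 decimals;
    ``format="csv"`` gives machine-readable columns at 4-decimal precision.
    A provenance mapping, if given, is appended as footer comment lines.
    """
    if not summaries:
        raise InsufficientDataError("no scenario summaries to render")
    rows = list(summaries) + ([grand] if grand is not None else [])

    if format == "csv":
        header = ["amplitude_mm", "period_s", "n"]
        for f in LATENCY_FIELDS:
            header += [f"tau_{f}_mean", f"tau_{f}_sd"]
        lines = [",".join(header)]
        for s in rows:
            cells = [
                "" if s.amplitude is None else f"{s.amplitude:g}",
                "" if s.period is None else f"{s.period:g}",
                str(s.n_cycles_used),
            ]
            for f in LATENCY_FIELDS:
                cells += [fmt_value(s.mean(f), 4), fmt_value(s.sd(f), 4)]
            lines.append(",".join(cells))
        if provenance:
            for k in sorted(provenance):
                lines.append(f"#{k}={provenance[k]}")
        return "\n".join(lines) + "\n"

    if format == "text":
        widths = [16, 12, 6] + [20] * 6
        titles = ["Amplitude (mm)", "Period (s)", "n"] + [
            _COLUMN_TITLES[f] for f in LATENCY_FIELDS
        ]
        lines = ["".join(t.ljust(w) for t, w in zip(titles, widths))]
        for s in rows:
            label = "Mean" if s.amplitude is None else f"{s.amplitude:g}"
            per = "" if s.period is None else f"{s.period:g}"
            cells = [label, per, str(s.n_cycles_used)] + [_cell(s, f) for f in LATENCY_FIELDS]
            lines.append("".join(c.ljust(w) for c, w in zip(cells, widths)))
        if provenance:
            lines.append("")
            for k in sorted(provenance):
                lines.append(f"# {k}: {provenance[k]}")
        return "\n".join(lines) + "\n"

    raise ConfigurationError(f"format: unknown report format {format!r}")
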