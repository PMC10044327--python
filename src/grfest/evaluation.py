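"""Performance statistics: percent RMSE, group mean +- SE, accuracy, deltas.

The estimation error on each wrench axis is a normalized RMSE expressed in
percent. The normalization denominator is configurable ('range' by default:
max - min of the measured channel over the evaluation segment; 'peak':
max |measured|; 'std': standard deviation). Force axes (Fx, Fy, Fz) and
moment axes (Mx, My, Mz) are summarized as mean +- standard error, where the
SE is the sample (n-1) standard deviation over the three axes divided by
sqrt(3). Estimation accuracy is 100 minus the force-group mean %RMSE.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .dataset import WRENCH_CHANNELS

FORCE_AXES = ("Fx", "Fy", "Fz")
MOMENT_AXES = ("Mx", "My", "Mz")
NORMALIZATIONS = ("range", "peak", "std")


def percent_rmse(estimated: np.ndarray, measured: np.ndarray,
                 normalization: str = "range") -> float:
    """Normalized RMSE in percent between one estimated and measured channel."""
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.shape != measured.shape or estimated.size < 2:
        raise DataError("estimated and measured must be equal-length, n >= 2")
    if normalization not in NORMALIZATIONS:
        raise ConfigurationError(
            f"normalization must be one of {NORMALIZATIONS}, got {normalization!r}")
    rmse = math.sqrt(float(np.mean((estimated - measured) ** 2)))
    if normalization == "range":
        denom = float(measured.max() - measured.min())
    elif normalization == "peak":
        denom = float(np.abs(measured).max())
    else:
        denom = float(measured.std(ddof=0))
    if denom == 0:
        raise DataError("measured channel is constant; %RMSE normalization undefined")
    return 100.0 * rmse / denom


def aggregate_group(values) -> tuple[float, float]:
    """(mean, SE) over the three per-axis percentages of a force/moment group.

    SE is the n-1 sample standard deviation over the 3 axes divided by
    sqrt(3) — the convention that reproduces published mean +- SE summaries
    of per-axis errors.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (3,):
        raise DataError("aggregate_group expects exactly the three axis values")
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(3))


def accuracy_from_rmse(grf_mean_pct: float) -> float:
    """Estimation accuracy in percent: 100 - mean force %RMSE."""
    if not 0 <= grf_mean_pct <= 100:
        raise DataError("mean %RMSE must lie in [0, 100] for the accuracy reading")
    return 100.0 - grf_mean_pct


@dataclass
class EvalReport:
    """Per-axis %RMSE plus the force/moment group summaries for one pattern."""

    pattern_id: int
    motion_type: str
    per_axis_pct_rmse: dict
    grf_mean: float = field(init=False)
    grf_se: float = field(init=False)
    grm_mean: float = field(init=False)
    grm_se: float = field(init=False)
    accuracy_pct: float = field(init=False)
    normalization: str = "range"

    def __post_init__(self):
        self.grf_mean, self.grf_se = aggregate_group(
            [self.per_axis_pct_rmse[a] for a in FORCE_AXES])
        self.grm_mean, self.grm_se = aggregate_group(
            [self.per_axis_pct_rmse[a] for a in MOMENT_AXES])
        self.accuracy_pct = accuracy_from_rmse(self.grf_mean)

    def to_dict(self) -> dict:
        return {
            "pattern_id": self.pattern_id,
            "motion_type": self.motion_type,
            "per_axis_pct_rmse": dict(self.per_axis_pct_rmse),
            "grf_mean": self.grf_mean, "grf_se": self.grf_se,
            "grm_mean": self.grm_mean, "grm_se": self.grm_se,
            "accuracy_pct": self.accuracy_pct,
            "normalization": self.normalization,
        }


def evaluate_wrench(estimated: np.ndarray, measured: np.ndarray,
                    pattern_id: int, motion_type: str,
                    normalization: str = "range") -> EvalReport:
    """EvalReport from (n, 6) estimated and measured wrench arrays."""
    estimated = np.asarray(estimated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if estimated.shape != measured.shape or estimated.shape[1] != 6:
        raise DataError("expected matching (n, 6) wrench arrays")
    per_axis = {ax: percent_rmse(estimated[:, j], measured[:, j], normalization)
                for j, ax in enumerate(WRENCH_CHANNELS)}
    return EvalReport(pattern_id=pattern_id, motion_type=motion_type,
                      per_axis_pct_rmse=per_axis, normalization=normalization)


def compare_patterns(report_a: EvalReport, report_b: EvalReport) -> dict:
    """Signed error reductions a - b (positive: b is better), per group and axis."""
    if report_a.motion_type != report_b.motion_type:
        raise DataError("cannot compare reports from different motion types")
    return {
        "grf_mean_delta": report_a.grf_mean - report_b.grf_mean,
        "grm_mean_delta": report_a.grm_mean - report_b.grm_mean,
        "per_axis_delta": {
            ax: report_a.per_axis_pct_rmse[ax] - report_b.per_axis_pct_rmse[ax]
            for ax in WRENCH_CHANNELS},
    }


def _sig3(x: float) -> str:
    """Format to 3 significant figures, table style."""
    if x == 0:
        return "0.00"
    return f"{x:.{max(0, 2 - int(math.floor(math.log10(abs(x)))))}f}"


def render_table(reports) -> tuple[pd.DataFrame, str]:
    """Six pattern rows -> (DataFrame, aligned text) in the standard layout.

    Columns: per-axis %RMSE for Fx..Fz with 'Average +- SE', then Mx..Mz with
    theirs; values rounded to 3 significant figures for display.
    """
    reports = list(reports)
    if len(reports) != 6:
        raise DataError("render_table expects reports for the six patterns")
    rows = []
    for r in sorted(reports, key=lambda r: r.pattern_id):
        row = {"Input": r.pattern_id}
        for ax in FORCE_AXES:
            row[f"{ax} [N]"] = float(_sig3(r.per_axis_pct_rmse[ax]))
        row["Avg F"] = float(_sig3(r.grf_mean))
        row["SE F"] = float(_sig3(r.grf_se))
        for ax in MOMENT_AXES:
            row[f"{ax} [Nm]"] = float(_sig3(r.per_axis_pct_rmse[ax]))
        row["Avg M"] = float(_sig3(r.grm_mean))
        row["SE M"] = float(_sig3(r.grm_se))
        rows.append(row)
    df = pd.DataFrame(rows)
    buf = io.StringIO()
    buf.write(df.to_string(index=False))
    return df, buf.getvalue()
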