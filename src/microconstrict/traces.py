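"""Deformation-trace analysis: phases, critical pressures, spindle, groups.

A trace is the time series recorded while one cell is pushed through the
constriction with the stepwise pressure protocol: applied pressure (mbar),
front and rear tip positions relative to the constriction entry (um), the
aspect ratio, and optionally the spindle long-axis length and angle.  The
pipeline detects the approach/entry/transit phases, reads off the pressures
at the three canonical events (front tip at the entry, front tip at half
the constriction width, rear tip at the entry), normalizes them per
experiment against the control group, and compares groups with a rank-sum
test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DeformationTrace",
    "PhaseSegmentation",
    "CriticalPressureMeasurement",
    "GroupComparison",
    "SpindleMetrics",
    "SchemaError",
    "load_trace",
    "save_trace",
    "detect_phases",
    "extract_critical_pressures",
    "normalize_pressures",
    "spindle_metrics",
    "compare_groups",
    "analyze_traces",
    "fold_angle",
]

REQUIRED_COLUMNS = ("time_s", "pressure_mbar", "x_front_um", "x_rear_um", "aspect_ratio")
SPINDLE_COLUMNS = ("spindle_len_um", "spindle_angle_deg")
PRESSURE_FIELDS = ("P_Xf0", "P_Xf_d2", "P_Xr0")


class SchemaError(ValueError):
    """A trace file violates the expected schema; the message names the field."""


class FeatureUnavailableError(ValueError):
    """The trace lacks the optional columns a computation needs."""


class DegenerateNormalizationError(ValueError):
    """A control distribution has zero IQR; robust normalization undefined."""


@dataclass
class DeformationTrace:
    """One cell's recorded passage: frame table plus acquisition metadata.

    ``data`` columns: time_s, pressure_mbar, x_front_um, x_rear_um,
    aspect_ratio and optionally spindle_len_um / spindle_angle_deg.
    ``metadata`` must carry at least ``d_um`` (effective constriction width);
    oocyte_id, group and experiment_id identify the cell in cohort tables.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing required column {col!r}")
        t = self.data["time_s"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            raise SchemaError(f"time_s not strictly increasing at row {int(bad[0]) + 1}")
        if np.any(self.data["x_front_um"].to_numpy() < self.data["x_rear_um"].to_numpy()):
            raise SchemaError("x_front_um < x_rear_um at some frame")
        if "d_um" not in self.metadata:
            raise SchemaError("metadata missing field 'd_um'")

    @property
    def has_spindle(self) -> bool:
        return all(c in self.data.columns for c in SPINDLE_COLUMNS)

    @property
    def d(self) -> float:
        return float(self.metadata["d_um"])

    def __len__(self) -> int:
        return len(self.data)


def load_trace(path: str | Path) -> DeformationTrace:
    """Read a trace CSV plus its JSON sidecar (same stem, .json extension)."""
    path = Path(path)
    data = pd.read_csv(path, comment="#")
    sidecar = path.with_suffix(".json")
    metadata: dict = {}
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return DeformationTrace(data=data, metadata=metadata)


def save_trace(trace: DeformationTrace, path: str | Path) -> Path:
    """Write a trace CSV and its JSON sidecar next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.data.to_csv(path, index=False, float_format="%.6g")
    path.with_suffix(".json").write_text(json.dumps(trace.metadata, indent=1))
    return path


# ---------------------------------------------------------------------------
# phases and critical pressures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseSegmentation:
    """Contiguous approach/entry/transit labels per frame."""

    labels: np.ndarray
    entry_start: int | None
    transit_start: int | None
    no_entry: bool


def detect_phases(trace: DeformationTrace, rear_motion_threshold: float = 1.0) -> PhaseSegmentation:
    """Label frames as approach, entry or transit.

    Approach: front tip upstream of the entry.  Entry: front inside while
    the rear stays quasi-static (within ``rear_motion_threshold`` um of its
    position at the first entry frame).  Transit: from the first clear rear
    displacement (or from full deformation, whichever comes first) to the
    end.  If the front never reaches the entry all frames are approach and
    ``no_entry`` is set.
    """
    xf = trace.data["x_front_um"].to_numpy()
    xr = trace.data["x_rear_um"].to_numpy()
    n = len(xf)
    labels = np.full(n, "approach", dtype=object)
    entered = np.nonzero(xf >= 0.0)[0]
    if entered.size == 0:
        return PhaseSegmentation(labels, None, None, True)
    i0 = int(entered[0])
    base = xr[i0]
    moved = np.nonzero(
        (np.abs(xr - base) >= rear_motion_threshold) | (xr >= 0.0)
    )[0]
    moved = moved[moved > i0]
    i1 = int(moved[0]) if moved.size else n
    labels[i0:i1] = "entry"
    labels[i1:] = "transit"
    return PhaseSegmentation(labels, i0, i1 if i1 < n else None, False)


def _first_upcrossing(t: np.ndarray, s: np.ndarray, target: float) -> float | None:
    """Time of the first crossing of ``s`` above ``target``, linearly interpolated."""
    above = np.nonzero(s >= target)[0]
    if above.size == 0:
        return None
    i = int(above[0])
    if i == 0:
        return float(t[0])
    frac = (target - s[i - 1]) / (s[i] - s[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


@dataclass
class CriticalPressureMeasurement:
    """Per-cell event pressures (mbar) and maximum aspect ratio.

    ``valid`` flags events the trace actually reached; ``ordering_warning``
    is set when the expected ordering P_Xr0 >= P_Xf_d2 >= P_Xf0 is violated
    among valid fields (a data-quality signal, not an error).
    """

    P_Xf0: float
    P_Xf_d2: float
    P_Xr0: float
    AR_max: float
    t_Xf0: float | None = None
    t_Xf_d2: float | None = None
    t_Xr0: float | None = None
    valid: dict = field(default_factory=dict)
    ordering_warning: bool = False

    def to_dict(self) -> dict:
        return {
            "P_Xf0": self.P_Xf0, "P_Xf_d2": self.P_Xf_d2, "P_Xr0": self.P_Xr0,
            "AR_max": self.AR_max,
            "valid_P_Xf0": self.valid.get("P_Xf0", False),
            "valid_P_Xf_d2": self.valid.get("P_Xf_d2", False),
            "valid_P_Xr0": self.valid.get("P_Xr0", False),
            "ordering_warning": self.ordering_warning,
        }


def extract_critical_pressures(
    trace: DeformationTrace, d: float | None = None
) -> CriticalPressureMeasurement:
    """Pressures at the three canonical position crossings.

    Each crossing time is found by linear interpolation of the position
    series between the bracketing frames; the pressure is read from the
    recorded series at that time (same interpolation).  Events never reached
    are flagged invalid (value NaN).  ``d`` defaults to the trace metadata.
    """
    if d is None:
        d = trace.d
    t = trace.data["time_s"].to_numpy()
    p = trace.data["pressure_mbar"].to_numpy()
    xf = trace.data["x_front_um"].to_numpy()
    xr = trace.data["x_rear_um"].to_numpy()
    ar = trace.data["aspect_ratio"].to_numpy()

    times = {
        "P_Xf0": _first_upcrossing(t, xf, 0.0),
        "P_Xf_d2": _first_upcrossing(t, xf, d / 2.0),
        "P_Xr0": _first_upcrossing(t, xr, 0.0),
    }
    values = {k: (float(np.interp(tc, t, p)) if tc is not None else math.nan)
              for k, tc in times.items()}
    valid = {k: tc is not None for k, tc in times.items()}
    pre_full = xr <= 0.0
    AR_max = float(np.max(ar[pre_full])) if pre_full.any() else float(np.max(ar))
    ordering_warning = False
    if valid["P_Xf0"] and valid["P_Xf_d2"] and values["P_Xf_d2"] < values["P_Xf0"]:
        ordering_warning = True
    if valid["P_Xf_d2"] and valid["P_Xr0"] and values["P_Xr0"] < values["P_Xf_d2"]:
        ordering_warning = True
    return CriticalPressureMeasurement(
        P_Xf0=values["P_Xf0"], P_Xf_d2=values["P_Xf_d2"], P_Xr0=values["P_Xr0"],
        AR_max=AR_max, t_Xf0=times["P_Xf0"], t_Xf_d2=times["P_Xf_d2"],
        t_Xr0=times["P_Xr0"], valid=valid, ordering_warning=ordering_warning,
    )


# ---------------------------------------------------------------------------
# robust per-experiment normalization
# ---------------------------------------------------------------------------


def _iqr(values: np.ndarray) -> float:
    q1, q3 = np.percentile(values, [25.0, 75.0])  # linear ("type 7") quartiles
    return float(q3 - q1)


def normalize_pressures(
    measurements: pd.DataFrame,
    control_label: str,
    experiment_key: str = "experiment_id",
    group_key: str = "group",
) -> pd.DataFrame:
    """Robust z-like scores: (P - median_ctrl) / IQR_ctrl per experiment.

    The reference distribution is the control group's P_Xf0 within each
    experiment; the same location and scale are applied to all three
    pressures of every cell in that experiment, so the control P_Xf0 has
    median 0 and IQR 1 by construction.  Requires >= 3 valid control P_Xf0
    per experiment; a zero control IQR raises
    :class:`DegenerateNormalizationError`.
    """
    df = measurements.copy()
    for col in (experiment_key, group_key, "P_Xf0"):
        if col not in df.columns:
            raise SchemaError(f"measurements table missing column {col!r}")
    for name in PRESSURE_FIELDS:
        df[f"{name}_norm"] = np.nan
    for exp, sub in df.groupby(experiment_key):
        ctrl = sub[(sub[group_key] == control_label) & sub["P_Xf0"].notna()]
        if "valid_P_Xf0" in ctrl.columns:
            ctrl = ctrl[ctrl["valid_P_Xf0"].astype(bool)]
        if len(ctrl) < 3:
            raise ValueError(
                f"experiment {exp!r}: need >= 3 valid control P_Xf0 values, got {len(ctrl)}"
            )
        ref = ctrl["P_Xf0"].to_numpy(dtype=float)
        med, iqr = float(np.median(ref)), _iqr(ref)
        if iqr == 0.0:
            raise DegenerateNormalizationError(
                f"experiment {exp!r}: control P_Xf0 IQR is zero"
            )
        idx = sub.index
        for name in PRESSURE_FIELDS:
            df.loc[idx, f"{name}_norm"] = (df.loc[idx, name] - med) / iqr
    return df


# ---------------------------------------------------------------------------
# spindle metrics
# ---------------------------------------------------------------------------


def fold_angle(theta_deg: float) -> float:
    """Fold an orientation (degrees) to the unsigned [0, 90] range.

    An axis has period 180 deg; the distance of the axis to the channel
    direction is ``|((theta + 90) mod 180) - 90|``.
    """
    return float(abs(((theta_deg + 90.0) % 180.0) - 90.0))


@dataclass(frozen=True)
class SpindleMetrics:
    """Spindle elongation (percent of approach-phase baseline) and alignment."""

    elongation_at_full_deformation: float
    elongation_max: float
    angle_at_full_deformation: float
    baseline_len: float


def spindle_metrics(trace: DeformationTrace, rear_motion_threshold: float = 1.0) -> SpindleMetrics:
    """Elongation and channel-alignment of the spindle during passage.

    The baseline length is the approach-phase mean; elongation at full
    deformation is evaluated at the rear-entry crossing time (NaN if never
    reached), the maximum over entry plus transit frames; the angle at full
    deformation is folded to [0, 90] degrees.
    """
    if not trace.has_spindle:
        raise FeatureUnavailableError("trace has no spindle_len_um / spindle_angle_deg columns")
    seg = detect_phases(trace, rear_motion_threshold)
    approach = seg.labels == "approach"
    if not approach.any():
        raise ValueError("approach phase empty; no pre-deformation spindle baseline")
    t = trace.data["time_s"].to_numpy()
    length = trace.data["spindle_len_um"].to_numpy(dtype=float)
    angle = trace.data["spindle_angle_deg"].to_numpy(dtype=float)
    L0 = float(np.mean(length[approach]))
    in_constriction = ~approach
    elong_max = (
        100.0 * (float(np.max(length[in_constriction])) - L0) / L0
        if in_constriction.any()
        else math.nan
    )
    t_full = _first_upcrossing(t, trace.data["x_rear_um"].to_numpy(), 0.0)
    if t_full is None:
        elong_full = math.nan
        angle_full = math.nan
    else:
        elong_full = 100.0 * (float(np.interp(t_full, t, length)) - L0) / L0
        angle_full = fold_angle(float(np.interp(t_full, t, angle)))
    return SpindleMetrics(
        elongation_at_full_deformation=elong_full,
        elongation_max=elong_max,
        angle_at_full_deformation=angle_full,
        baseline_len=L0,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided rank-sum comparison of one metric between two groups."""

    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    iqr_a: float
    iqr_b: float
    statistic: float
    p_value: float
    direction: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def compare_groups(
    measurements: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    group_key: str = "group",
) -> GroupComparison:
    """Mann-Whitney U (two-sided) on ``metric`` between two labelled groups.

    Exact enumeration of the rank permutations when both groups have n <= 8
    (valid with ties via midranks); otherwise the tie-corrected normal
    approximation.  Requires >= 3 valid values per group.
    """
    a = measurements.loc[measurements[group_key] == group_a, metric].dropna().to_numpy(dtype=float)
    b = measurements.loc[measurements[group_key] == group_b, metric].dropna().to_numpy(dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need >= 3 valid values per group, got {len(a)} and {len(b)}")
    if len(a) <= 8 and len(b) <= 8:
        method = stats.PermutationMethod(n_resamples=20_000, rng=np.random.default_rng(0))
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "a<b" if med_a < med_b else ("a>b" if med_a > med_b else "a=b")
    return GroupComparison(
        metric=metric, group_a=group_a, group_b=group_b,
        n_a=len(a), n_b=len(b), median_a=med_a, median_b=med_b,
        iqr_a=_iqr(a), iqr_b=_iqr(b),
        statistic=float(res.statistic), p_value=float(res.pvalue), direction=direction,
    )


# ---------------------------------------------------------------------------
# cohort pipeline
# ---------------------------------------------------------------------------


def analyze_traces(
    traces: Iterable[DeformationTrace],
    rear_motion_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-cell measurement table for a set of traces.

    One row per trace: identifiers, raw event pressures (mbar), AR_max,
    validity flags and, when spindle columns are present, spindle metrics.
    """
    rows = []
    for trace in traces:
        meas = extract_critical_pressures(trace)
        row = {
            "oocyte_id": trace.metadata.get("oocyte_id"),
            "group": trace.metadata.get("group"),
            "experiment_id": trace.metadata.get("experiment_id"),
            "d_um": trace.d,
            "n_frames": len(trace),
        }
        row.update(meas.to_dict())
        if trace.has_spindle:
            try:
                sm = spindle_metrics(trace, rear_motion_threshold)
                row.update(
                    spindle_elongation_full_pct=sm.elongation_at_full_deformation,
                    spindle_elongation_max_pct=sm.elongation_max,
                    spindle_angle_full_deg=sm.angle_at_full_deformation,
                )
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)
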