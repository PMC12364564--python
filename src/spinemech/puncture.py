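"""Puncture-event extraction and performance summaries.

Raw material from a serial-angle compression protocol: one
force–displacement trace per spine × test angle × replicate, recorded while
the spine is pressed point-down into a skin-mimicking silicone block at a
fixed rate.  A successful puncture shows as a sharp drop in the force
curve.  This module turns traces into per-trial records and per-spine
summaries:

``puncture range``
    span (degrees) between the extreme test angles at which the spine
    punctured; 0 when at most one angle succeeded.
``lowest force``
    minimum puncture force over all successful trials.
``average force``
    mean over successful angles of the per-angle replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import ParameterError, TraceFormatError

__all__ = [
    "TraceMeta",
    "ForceTrace",
    "PunctureEvent",
    "TrialRecord",
    "AngleResult",
    "SpinePerformance",
    "read_force_trace",
    "detect_puncture",
    "score_trial",
    "score_trials",
    "aggregate_angle",
    "summarize_performance",
    "performance_table",
]


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceMeta:
    """Trial metadata attached to a trace."""

    spine_id: str | None = None
    angle_deg: int | None = None
    replicate: int | None = None
    rate: float = 10.0           # mm/min
    travel_limit: float | None = None
    broken: bool = False

    def __post_init__(self) -> None:
        if self.angle_deg is not None and self.angle_deg % 10 != 0:
            raise ParameterError("angle_deg must be a (signed) multiple of 10")
        if self.replicate is not None and self.replicate < 1:
            raise ParameterError("replicate must be >= 1")
        if self.travel_limit is not None and not 5.0 <= self.travel_limit <= 15.0:
            raise ParameterError("travel_limit must be in [5, 15] mm")


@dataclass(frozen=True)
class ForceTrace:
    """Paired displacement (mm) / force (N) series from one compression trial."""

    displacement: np.ndarray
    force: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise TraceFormatError("displacement and force must be equal-length 1D")
        if len(d) < 2:
            raise TraceFormatError("trace needs at least 2 samples")
        if np.any(np.diff(d) < 0):
            raise TraceFormatError("displacement must be monotone nondecreasing")
        if d[0] < 0:
            raise TraceFormatError("displacement must start at >= 0")
        if self.meta.travel_limit is not None and d[-1] > self.meta.travel_limit + 1e-9:
            raise TraceFormatError("displacement exceeds the travel limit")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass(frozen=True)
class PunctureEvent:
    """One detected sharp force drop."""

    peak_force: float
    peak_displacement: float
    drop_magnitude: float
    drop_fraction: float
    drop_width: float

    def __post_init__(self) -> None:
        if not self.drop_magnitude > 0:
            raise ParameterError("drop_magnitude must be > 0")
        if not 0 < self.drop_fraction <= 1:
            raise ParameterError("drop_fraction must be in (0, 1]")
        if self.peak_force < self.drop_magnitude:
            raise ParameterError("peak_force must be >= drop_magnitude")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one trial: puncture or not, and at what force."""

    spine_id: str | None
    angle_deg: int | None
    replicate: int | None
    success: bool
    puncture_force: float | None

    def __post_init__(self) -> None:
        if self.success != (self.puncture_force is not None):
            raise ParameterError("puncture_force must be present iff success")


@dataclass(frozen=True)
class AngleResult:
    """Replicate-aggregated outcome at one spine × angle."""

    success: bool
    mean_force: float | None
    n_success: int
    n_trials: int
    disagreement: bool  # replicates did not all agree


@dataclass(frozen=True)
class SpinePerformance:
    """Per-spine puncture-performance summary."""

    spine_id: str | None
    puncture_range_deg: float
    lowest_force_N: float | None
    average_force_N: float | None
    n_success_angles: int

    def __post_init__(self) -> None:
        if self.puncture_range_deg < 0:
            raise ParameterError("puncture_range must be >= 0")
        has = self.n_success_angles > 0
        if has != (self.lowest_force_N is not None) or has != (
            self.average_force_N is not None
        ):
            raise ParameterError("force fields must be present iff any success")
        if has and self.lowest_force_N > self.average_force_N + 1e-12:
            raise ParameterError("lowest force cannot exceed average force")


# ---------------------------------------------------------------------------
# reading traces
# ---------------------------------------------------------------------------

_DISPLACEMENT_NAMES = ("displacement_mm", "displacement", "extension", "position_mm")
_FORCE_NAMES = ("force_n", "force", "load", "load_n")


def read_force_trace(
    path: str | Path,
    meta: TraceMeta | None = None,
    displacement_names: Sequence[str] = _DISPLACEMENT_NAMES,
    force_names: Sequence[str] = _FORCE_NAMES,
    repair_order: bool = False,
) -> ForceTrace:
    """Read a trace CSV with recognisable displacement/force columns.

    A non-numeric first data row (a units row such as ``mm,N``) is skipped.
    Non-monotone displacement is an error unless ``repair_order=True``, in
    which case rows are stably sorted by displacement.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceFormatError(f"{path}: empty file") from exc
    if df.empty:
        raise TraceFormatError(f"{path}: no data rows")
    lower = {c.lower().strip(): c for c in df.columns}
    dcol = next((lower[n] for n in displacement_names if n in lower), None)
    fcol = next((lower[n] for n in force_names if n in lower), None)
    if dcol is None or fcol is None:
        raise TraceFormatError(
            f"{path}: could not identify displacement/force columns in "
            f"{list(df.columns)}"
        )
    sub = df[[dcol, fcol]]
    first = sub.iloc[0]
    coerced = pd.to_numeric(first, errors="coerce")
    if coerced.isna().any():  # units row under the headers
        sub = sub.iloc[1:]
    num = sub.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = int(num.isna().any(axis=1).sum())
        raise TraceFormatError(f"{path}: {bad} non-numeric data rows")
    if num.empty:
        raise TraceFormatError(f"{path}: no numeric data rows")
    d = num[dcol].to_numpy(float)
    f = num[fcol].to_numpy(float)
    if np.any(np.diff(d) < 0):
        if not repair_order:
            raise TraceFormatError(
                f"{path}: displacement not monotone (pass repair_order=True "
                "to sort)"
            )
        order = np.argsort(d, kind="stable")
        d, f = d[order], f[order]
    return ForceTrace(displacement=d, force=f, meta=meta or TraceMeta())


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def detect_puncture(
    trace: ForceTrace,
    min_drop_fraction: float = 0.10,
    min_drop_abs: float = 0.5,
    max_drop_width: float = 0.2,
    smooth_window: int = 5,
    require_persistence: bool = True,
) -> list[PunctureEvent]:
    """Find sharp force drops in a trace.

    The force series is moving-median smoothed; each local maximum is
    checked for a decrease of at least ``max(min_drop_abs,
    min_drop_fraction × peak)`` completed within ``max_drop_width`` mm.
    With ``require_persistence`` (default) the smoothed force must also
    stay below ``peak − drop/2`` for one further drop-width beyond the
    trough, which separates genuine punctures (force re-rises from the
    dropped level) from transient noise excursions.

    ``peak_force`` of an event is the unsmoothed maximum within the
    smoothing window around the smoothed peak.  Events are ordered by
    displacement.  An empty list means no puncture.
    """
    if len(trace) < 10:
        raise ParameterError("need at least 10 samples to detect punctures")
    d = trace.displacement
    f = np.asarray(trace.force, dtype=float)
    if smooth_window > 1:
        fs = median_filter(f, size=smooth_window, mode="nearest")
    else:
        fs = f
    n = len(f)
    half = max(smooth_window // 2, 1)

    # candidate peaks: first index of each strictly-greater-than-neighbours
    # plateau in the smoothed series
    peaks = []
    i = 1
    while i < n - 1:
        if fs[i] > fs[i - 1]:
            j = i
            while j + 1 < n and fs[j + 1] == fs[j]:
                j += 1
            if j + 1 < n and fs[j + 1] < fs[j]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1

    events: list[PunctureEvent] = []
    scan_from = 0
    for a in peaks:
        if a < scan_from:
            continue
        hi = np.searchsorted(d, d[a] + max_drop_width, side="right")
        if hi <= a + 1:
            continue
        window = fs[a + 1 : hi]
        b = a + 1 + int(np.argmin(window))
        drop = fs[a] - fs[b]
        threshold = max(min_drop_abs, min_drop_fraction * fs[a])
        if drop < threshold:
            continue
        if require_persistence:
            hold_hi = np.searchsorted(d, d[b] + max_drop_width, side="right")
            hold = fs[b:hold_hi]
            if len(hold) and np.max(hold) > fs[a] - 0.5 * drop:
                continue
        # the true peak is the unsmoothed sample just before the steepest
        # force step of the drop (median smoothing erodes sharp peaks, so
        # the smoothed maximum sits a few samples early)
        lo = max(a - half, 0)
        steps = np.diff(f[lo : b + 1])
        k = lo + int(np.argmin(steps)) if len(steps) else a
        seg = f[max(k - 3, lo) : k + 1]
        p_rel = int(np.argmax(seg))
        peak_force = float(seg[p_rel])
        peak_disp = float(d[max(k - 3, lo) + p_rel])
        magnitude = float(min(peak_force - fs[b], peak_force))
        if magnitude <= 0:
            continue
        events.append(
            PunctureEvent(
                peak_force=peak_force,
                peak_displacement=peak_disp,
                drop_magnitude=magnitude,
                drop_fraction=float(min(magnitude / peak_force, 1.0)),
                drop_width=float(d[b] - d[a]),
            )
        )
        scan_from = b + 1
    return events


# ---------------------------------------------------------------------------
# trial scoring and aggregation
# ---------------------------------------------------------------------------


def score_trial(trace: ForceTrace, **detect_kwargs) -> TrialRecord:
    """One trial: success iff at least one event; force from the first event."""
    events = detect_puncture(trace, **detect_kwargs)
    success = len(events) > 0
    return TrialRecord(
        spine_id=trace.meta.spine_id,
        angle_deg=trace.meta.angle_deg,
        replicate=trace.meta.replicate,
        success=success,
        puncture_force=events[0].peak_force if success else None,
    )


def score_trials(traces: Iterable[ForceTrace], **detect_kwargs) -> pd.DataFrame:
    """Score many traces into a tidy trial-record table."""
    rows = []
    for t in traces:
        rec = score_trial(t, **detect_kwargs)
        rows.append(
            {
                "spine_id": rec.spine_id,
                "angle_deg": rec.angle_deg,
                "replicate": rec.replicate,
                "success": rec.success,
                "puncture_force_N": rec.puncture_force
                if rec.puncture_force is not None
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def aggregate_angle(
    trials: Sequence[TrialRecord], rule: str = "any"
) -> AngleResult:
    """Aggregate the replicates at one spine × angle.

    ``rule="any"`` (default): the angle succeeds when at least one replicate
    punctured.  ``rule="majority"``: more than half must puncture.  The mean
    force averages the successful replicates only.
    """
    if len(trials) == 0:
        raise ParameterError("aggregate_angle needs at least one trial")
    if rule not in ("any", "majority"):
        raise ParameterError(f"unknown replicate rule {rule!r}")
    succ = [t for t in trials if t.success]
    n_success = len(succ)
    if rule == "any":
        success = n_success >= 1
    else:
        success = n_success > len(trials) / 2
    mean_force = (
        float(np.mean([t.puncture_force for t in succ])) if success and succ else None
    )
    return AngleResult(
        success=success,
        mean_force=mean_force,
        n_success=n_success,
        n_trials=len(trials),
        disagreement=0 < n_success < len(trials),
    )


def summarize_performance(
    angle_results: Mapping[int, AngleResult],
    all_success_forces: Sequence[float] | None = None,
    spine_id: str | None = None,
    grid_step: int = 10,
) -> SpinePerformance:
    """Per-spine summary over the per-angle results.

    ``puncture_range`` = max − min successful angle (0 for ≤ 1 success);
    ``lowest_force`` = minimum over all successful replicate forces (pass
    them as ``all_success_forces``; defaults to the per-angle means);
    ``average_force`` = mean of the per-angle means over successful angles.
    """
    ok_angles = sorted(a for a, r in angle_results.items() if r.success)
    n_ok = len(ok_angles)
    rng = float(ok_angles[-1] - ok_angles[0]) if n_ok > 1 else 0.0
    if rng % grid_step not in (0,):
        raise ParameterError("successful angles are not on the stated grid")
    if n_ok == 0:
        return SpinePerformance(spine_id, 0.0, None, None, 0)
    means = [angle_results[a].mean_force for a in ok_angles]
    forces = (
        list(all_success_forces)
        if all_success_forces is not None and len(all_success_forces)
        else means
    )
    return SpinePerformance(
        spine_id=spine_id,
        puncture_range_deg=rng,
        lowest_force_N=float(np.min(forces)),
        average_force_N=float(np.mean(means)),
        n_success_angles=n_ok,
    )


def performance_table(
    records: pd.DataFrame,
    broken: Sequence[str] = (),
    rule: str = "any",
    grid_step: int = 10,
) -> pd.DataFrame:
    """Per-spine performance summary table from a trial-record table.

    ``records`` needs columns ``spine_id, angle_deg, replicate, success,
    puncture_force_N``.  Spines named in ``broken`` are retained in the
    output with ``broken=True`` and ``excluded=True`` so downstream
    statistics can drop them.
    """
    required = {"spine_id", "angle_deg", "replicate", "success", "puncture_force_N"}
    missing = required - set(records.columns)
    if missing:
        raise ParameterError(f"trial table missing columns: {sorted(missing)}")
    dup = records.duplicated(subset=["spine_id", "angle_deg", "replicate"])
    if dup.any():
        raise ParameterError("inconsistent metadata: duplicated trial keys")

    rows = []
    for spine_id, group in records.groupby("spine_id", sort=True):
        angle_results: dict[int, AngleResult] = {}
        disagreement = False
        for angle, g in group.groupby("angle_deg"):
            trials = [
                TrialRecord(
                    spine_id=str(spine_id),
                    angle_deg=int(angle),
                    replicate=int(r.replicate),
                    success=bool(r.success),
                    puncture_force=float(r.puncture_force_N)
                    if r.success
                    else None,
                )
                for r in g.itertuples()
            ]
            res = aggregate_angle(trials, rule=rule)
            angle_results[int(angle)] = res
            disagreement |= res.disagreement
        succ_forces = group.loc[group.success, "puncture_force_N"].to_numpy(float)
        perf = summarize_performance(
            angle_results,
            all_success_forces=succ_forces,
            spine_id=str(spine_id),
            grid_step=grid_step,
        )
        rows.append(
            {
                "spine_id": perf.spine_id,
                "puncture_range_deg": perf.puncture_range_deg,
                "lowest_force_N": perf.lowest_force_N
                if perf.lowest_force_N is not None
                else np.nan,
                "average_force_N": perf.average_force_N
                if perf.average_force_N is not None
                else np.nan,
                "n_success_angles": perf.n_success_angles,
                "replicate_disagreement": disagreement,
                "broken": spine_id in set(broken),
                "excluded": spine_id in set(broken),
            }
        )
    return pd.DataFrame(rows)
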