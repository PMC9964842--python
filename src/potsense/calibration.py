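"""Inverse pipeline: traces -> calibration points -> slope, range and LOD.

The workflow mirrors how ISE calibrations are analysed at the bench:

1. :func:`extract_plateaus` averages the settled tail of each dilution
   step into one (log10 activity, emf) point per level per electrode.
2. :func:`fit_calibration` runs ordinary least squares per electrode and
   reports the across-electrode mean +/- SD slope (the "n = 5 ... +/-"
   convention).
3. :func:`select_linear_range` finds the widest run of levels with
   mutually consistent decade slopes — the Nernstian window.
4. :func:`compute_lod` implements the IUPAC detection-limit definition:
   the abscissa of the intersection between a line fitted to the
   Nernstian limb and a line fitted to the low-concentration plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .model import DilutionProtocol, TimeTrace

__all__ = [
    "CalibrationError",
    "InsufficientDataError",
    "NoLinearRangeError",
    "NoIntersectionError",
    "CalibrationPoint",
    "ElectrodeFit",
    "CalibrationCurve",
    "LodResult",
    "extract_plateaus",
    "fit_calibration",
    "select_linear_range",
    "compute_lod",
]


class CalibrationError(ValueError):
    """Base class for calibration failures."""


class InsufficientDataError(CalibrationError):
    pass


class NoLinearRangeError(CalibrationError):
    pass


class NoIntersectionError(CalibrationError):
    pass


@dataclass(frozen=True)
class CalibrationPoint:
    log10_activity: float
    emf_mV: float
    electrode_id: str = "E1"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.log10_activity) and math.isfinite(self.emf_mV)):
            raise ValueError("calibration point values must be finite")


@dataclass(frozen=True)
class ElectrodeFit:
    electrode_id: str
    slope: float  # mV/decade
    intercept: float  # mV
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class CalibrationCurve:
    """Per-electrode OLS fits plus across-electrode summary statistics."""

    points: tuple[CalibrationPoint, ...]
    electrode_fits: tuple[ElectrodeFit, ...]
    slope: float  # across-electrode mean, mV/decade
    intercept: float  # across-electrode mean, mV
    slope_sd: float  # across-electrode SD, mV/decade
    linear_range: tuple[float, float]  # (log10 low, log10 high)
    r_squared: float  # across-electrode mean


@dataclass(frozen=True)
class LodResult:
    """IUPAC two-regression detection limit."""

    lod: float  # mol/L (10**intersection_log10)
    nernstian_segment: tuple[float, float]  # (slope mV/dec, intercept mV)
    plateau_segment: tuple[float, float]
    intersection_log10: float
    plateau_levels: tuple[float, ...] = ()  # log10 levels used for each fit
    nernstian_levels: tuple[float, ...] = ()


def extract_plateaus(
    trace: TimeTrace,
    schedule: DilutionProtocol,
    settle_fraction: float = 0.5,
    activity_model: str = "none",
    primary_charge: int = 1,
) -> list[CalibrationPoint]:
    """Average the settled tail of each dilution step into one point.

    For each dwell window the last ``settle_fraction`` of its samples are
    averaged, discarding the transition at the window start.  The abscissa
    is log10 of the level concentration (or Debye-Hueckel activity when
    ``activity_model="debye_huckel"``, in which case ``primary_charge``
    sets the ion's charge for the coefficient).
    """
    if not (0.0 < settle_fraction < 1.0):
        raise ValueError("settle_fraction must lie strictly between 0 and 1")
    from .chem import activity_coefficient, ionic_strength

    points = []
    for i, level in enumerate(schedule.levels):
        t0, t1 = i * schedule.dwell_s, (i + 1) * schedule.dwell_s
        in_window = (trace.time_s >= t0) & (trace.time_s < t1)
        n = int(in_window.sum())
        if n == 0:
            raise InsufficientDataError(
                f"trace {trace.electrode_id!r} has no samples for level "
                f"{level:g} mol/L (window {t0:g}-{t1:g} s)"
            )
        n_keep = max(1, int(math.ceil(settle_fraction * n)))
        emf = float(trace.emf_mV[in_window][-n_keep:].mean())
        if activity_model == "none":
            a = level
        elif activity_model == "debye_huckel":
            z = abs(primary_charge)
            I = ionic_strength(schedule.background) + level * z * (z + 1) / 2.0
            a = level * activity_coefficient(primary_charge, I)
        else:
            raise ValueError(f"unknown activity model {activity_model!r}")
        points.append(CalibrationPoint(math.log10(a), emf, trace.electrode_id))
    return points


def _group_by_electrode(points: Sequence[CalibrationPoint]) -> dict[str, list[CalibrationPoint]]:
    groups: dict[str, list[CalibrationPoint]] = {}
    for p in points:
        groups.setdefault(p.electrode_id, []).append(p)
    return groups


def fit_calibration(
    points: Sequence[CalibrationPoint],
    fit_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Per-electrode ordinary least squares of emf on log10 activity.

    ``fit_range`` restricts the fit to points with log10 activity inside
    the closed interval.  The reported slope and intercept are
    across-electrode means; ``slope_sd`` is the across-electrode standard
    deviation (sample SD, zero for a single electrode).
    """
    if fit_range is not None:
        lo, hi = fit_range
        points = [p for p in points if lo <= p.log10_activity <= hi]
    groups = _group_by_electrode(points)
    if not groups:
        raise InsufficientDataError("no calibration points in range")
    fits = []
    for eid in sorted(groups):
        pts = groups[eid]
        x = np.array([p.log10_activity for p in pts])
        y = np.array([p.emf_mV for p in pts])
        if len(np.unique(x)) < 2:
            raise InsufficientDataError(
                f"electrode {eid!r}: need >= 2 distinct activity levels in range"
            )
        res = stats.linregress(x, y)
        fits.append(
            ElectrodeFit(eid, float(res.slope), float(res.intercept),
                         float(res.rvalue**2), len(pts))
        )
    slopes = np.array([f.slope for f in fits])
    intercepts = np.array([f.intercept for f in fits])
    xs = [p.log10_activity for p in points]
    return CalibrationCurve(
        points=tuple(points),
        electrode_fits=tuple(fits),
        slope=float(slopes.mean()),
        intercept=float(intercepts.mean()),
        slope_sd=float(slopes.std(ddof=1)) if len(fits) > 1 else 0.0,
        linear_range=(min(xs), max(xs)),
        r_squared=float(np.mean([f.r_squared for f in fits])),
    )


def _level_means(points: Sequence[CalibrationPoint]) -> tuple[np.ndarray, np.ndarray]:
    """Pool replicate points into one mean emf per log10 level, ascending."""
    levels: dict[float, list[float]] = {}
    for p in points:
        levels.setdefault(round(p.log10_activity, 12), []).append(p.emf_mV)
    xs = np.array(sorted(levels))
    ys = np.array([float(np.mean(levels[x])) for x in xs])
    return xs, ys


def select_linear_range(
    points: Sequence[CalibrationPoint], tolerance: float = 10.0
) -> tuple[float, float]:
    """Widest contiguous run of levels with consistent decade slopes.

    A run qualifies when every slope between its consecutive levels lies
    within ``tolerance`` mV/decade of the run's median segment slope, and
    the run's overall slope is itself larger than ``tolerance`` (a dead,
    flat electrode has no linear range).  Ties go to the run ending at the
    higher concentration.
    """
    xs, ys = _level_means(points)
    if len(xs) < 3:
        raise InsufficientDataError("need >= 3 levels to select a linear range")
    seg = np.diff(ys) / np.diff(xs)
    best: tuple[int, float, tuple[float, float]] | None = None  # (width, hi, range)
    n = len(xs)
    for i in range(n - 2):
        for j in range(i + 2, n):
            s = seg[i:j]
            med = float(np.median(s))
            if np.all(np.abs(s - med) <= tolerance) and abs(med) > tolerance:
                cand = (j - i, xs[j], (float(xs[i]), float(xs[j])))
                if best is None or cand[:2] > best[:2]:
                    best = cand
    if best is None:
        raise NoLinearRangeError(
            f"no run of >= 3 levels with slopes within {tolerance} mV/decade"
        )
    return best[2]


def _grow_run(seg: np.ndarray, order: Sequence[int], tolerance: float) -> int:
    """Number of consecutive segments (in ``order``) forming a consistent run.

    A candidate segment joins while its slope lies within ``tolerance`` of
    the median of the slopes already accepted.
    """
    accepted = [seg[order[0]]]
    for k in order[1:]:
        if abs(seg[k] - float(np.median(accepted))) <= tolerance:
            accepted.append(seg[k])
        else:
            break
    return len(accepted)


def compute_lod(
    points: Sequence[CalibrationPoint],
    split: int | None = None,
    tolerance: float = 10.0,
) -> LodResult:
    """IUPAC detection limit from the two-regression intersection.

    One line is fitted to the low-concentration plateau (where the emf no
    longer tracks dilution because interference or membrane leaching sets
    the potential) and one to the Nernstian limb; the abscissa of their
    intersection is log10 LOD.

    When ``split`` is given, levels ``[0:split]`` (ascending activity)
    form the plateau and ``[split:]`` the Nernstian limb.  Otherwise each
    limb is grown from its end of the curve as a slope-consistent run —
    each additional inter-level slope must lie within ``tolerance``
    mV/decade of the median slope of the run so far — and curved
    transition levels between the two runs are excluded from both fits.
    """
    xs, ys = _level_means(points)
    n = len(xs)
    if n < 4:
        raise InsufficientDataError("need >= 4 levels (>= 2 per segment) for a LOD")
    if split is not None:
        if not (2 <= split <= n - 2):
            raise InsufficientDataError(
                f"split={split} leaves fewer than 2 levels on one side (n={n})"
            )
        plat_idx = list(range(split))
        nern_idx = list(range(split, n))
    else:
        seg = np.diff(ys) / np.diff(xs)
        n_plat = _grow_run(seg, list(range(n - 1)), tolerance)
        n_nern = _grow_run(seg, list(range(n - 2, -1, -1)), tolerance)
        plat_idx = list(range(n_plat + 1))
        nern_idx = list(range(n - 1 - n_nern, n))
        if n_plat + n_nern >= n - 1 and len(set(plat_idx) & set(nern_idx)) > 1:
            # Runs swallowed the whole curve: a single straight line, no knee.
            raise NoIntersectionError("calibration has no plateau/Nernstian knee")
        if len(plat_idx) < 2 or len(nern_idx) < 2:
            raise InsufficientDataError("could not isolate two levels per segment")
    m1, b1 = np.polyfit(xs[plat_idx], ys[plat_idx], 1)
    m2, b2 = np.polyfit(xs[nern_idx], ys[nern_idx], 1)
    if abs(m1 - m2) < 1e-9:
        raise NoIntersectionError("plateau and Nernstian segments are parallel")
    x_star = float((b2 - b1) / (m1 - m2))
    if not (xs[0] - 1.0 <= x_star <= xs[-1] + 1.0):
        raise NoIntersectionError(
            f"regression intersection at log10 a = {x_star:.2f} lies outside "
            f"the calibrated span [{xs[0]:.2f}, {xs[-1]:.2f}]"
        )
    return LodResult(
        lod=10.0**x_star,
        nernstian_segment=(float(m2), float(b2)),
        plateau_segment=(float(m1), float(b1)),
        intersection_log10=x_star,
        plateau_levels=tuple(float(x) for x in xs[plat_idx]),
        nernstian_levels=tuple(float(x) for x in xs[nern_idx]),
    )
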