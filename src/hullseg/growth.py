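"""Per-unit area series and relative growth rate (RGR) estimation.

Under exponential growth A(t) = A0 * exp(r t), ln A is linear in t and the
relative growth rate r (per day) is the slope of an ordinary least squares
straight-line fit of ln(area) on time.  Zero areas are excluded from the
fit (and flagged) rather than pseudo-counted.  Units whose series fit the
log-linear model poorly are flagged ``ModelFitOutlier`` — advisory only,
the fit is retained — prompting inspection of the underlying images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .layout import PlateLayout

__all__ = [
    "AreaRecord",
    "RgrFit",
    "FitCriteria",
    "area_per_unit",
    "fit_rgr",
    "flag_outliers",
    "group_summary",
    "fits_table",
    "areas_table",
]

FLAG_OUTLIER = "ModelFitOutlier"
FLAG_ZERO = "ZeroArea"
FLAG_FEW = "TooFewPoints"


@dataclass(frozen=True)
class AreaRecord:
    """One unit's area at one timepoint.

    time is in days since the start of the series; area_cal is the
    calibrated area (area_px * scale**2) when a scale is known.
    """

    unit_index: int
    group_index: int
    time: float
    area_px: int
    area_cal: float | None = None


@dataclass
class RgrFit:
    """Log-linear growth fit for one unit.

    rgr : slope of ln(area) vs time, per day.
    intercept : ln(area) at t = 0.
    residual_std : standard deviation of ln-area residuals (ddof=2).
    flags : subset of {ModelFitOutlier, ZeroArea, TooFewPoints}.
    """

    unit_index: int
    group_index: int = 0
    rgr: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    residual_std: float = float("nan")
    n_points: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def fitted(self) -> bool:
        return np.isfinite(self.rgr)

    def predict_area(self, t: np.ndarray) -> np.ndarray:
        """Fitted curve transformed back to units of area."""
        return np.exp(self.intercept + self.rgr * np.asarray(t, dtype=float))


@dataclass
class FitCriteria:
    """Thresholds for the ModelFitOutlier flag (either trips it).

    ``None`` disables a criterion; both None disables flagging entirely.
    """

    max_residual_std: float | None = 0.3
    min_r_squared: float | None = 0.7


def area_per_unit(
    mask: np.ndarray,
    labels: np.ndarray,
    time: float = 0.0,
    scale: float | None = None,
    groups: dict[int, int] | None = None,
) -> list[AreaRecord]:
    """Count foreground pixels inside each labeled region of interest.

    Returns one record per unit present in ``labels`` (including units with
    zero foreground).  ``scale`` is physical length per pixel; calibrated
    area is count * scale**2.
    """
    mask = np.asarray(mask).astype(bool)
    labels = np.asarray(labels)
    if mask.shape != labels.shape:
        raise ValueError("mask and labels must share dimensions")
    units = np.unique(labels)
    units = units[units > 0]
    out = []
    counts = np.bincount(
        labels.ravel(), weights=mask.ravel(), minlength=int(labels.max()) + 1
    )
    for u in units:
        n = int(counts[int(u)])
        out.append(
            AreaRecord(
                unit_index=int(u),
                group_index=(groups or {}).get(int(u), 1),
                time=float(time),
                area_px=n,
                area_cal=n * scale**2 if scale is not None else None,
            )
        )
    return out


def fit_rgr(series: list[AreaRecord], use_calibrated: bool = False) -> RgrFit:
    """OLS fit of ln(area) on time (days) for one unit's series.

    Zero-area records are excluded from the fit and raise the ZeroArea
    flag; fewer than 2 positive-area records yields no fit and the
    TooFewPoints flag.  Fitting calibrated areas instead of pixel counts
    leaves the slope unchanged and shifts the intercept by 2 ln(scale).
    """
    if not series:
        return RgrFit(unit_index=0, flags={FLAG_FEW})
    unit = series[0].unit_index
    group = series[0].group_index
    fit = RgrFit(unit_index=unit, group_index=group)
    t = np.array([r.time for r in series], dtype=float)
    if use_calibrated:
        a = np.array([r.area_cal for r in series], dtype=float)
    else:
        a = np.array([r.area_px for r in series], dtype=float)
    positive = a > 0
    if not positive.all():
        fit.flags.add(FLAG_ZERO)
    t, a = t[positive], a[positive]
    fit.n_points = int(positive.sum())
    if fit.n_points < 2:
        fit.flags.add(FLAG_FEW)
        return fit
    y = np.log(a)
    if np.allclose(t, t[0]):
        fit.flags.add(FLAG_FEW)  # no time spread: slope unidentifiable
        return fit
    res = stats.linregress(t, y)
    fit.rgr = float(res.slope)
    fit.intercept = float(res.intercept)
    fit.r_squared = float(res.rvalue**2)
    resid = y - (res.intercept + res.slope * t)
    ddof = min(2, fit.n_points - 1)
    fit.residual_std = float(np.sqrt((resid**2).sum() / max(fit.n_points - ddof, 1)))
    return fit


def flag_outliers(
    fits: list[RgrFit], criteria: FitCriteria | None = None
) -> list[RgrFit]:
    """Apply the ModelFitOutlier flag in place and return the list.

    A fit is flagged when residual_std exceeds ``max_residual_std`` or
    r_squared falls below ``min_r_squared``.  Fits are retained either way.
    """
    criteria = criteria or FitCriteria()
    for f in fits:
        if not f.fitted:
            continue
        bad = False
        if criteria.max_residual_std is not None:
            bad |= f.residual_std > criteria.max_residual_std
        if criteria.min_r_squared is not None:
            bad |= f.r_squared < criteria.min_r_squared
        if bad:
            f.flags.add(FLAG_OUTLIER)
        else:
            f.flags.discard(FLAG_OUTLIER)
    return fits


def group_summary(
    fits: list[RgrFit], layout: PlateLayout | None = None
) -> pd.DataFrame:
    """Per-group mean/SD of RGR over unflagged fits.

    Flagged or unfitted units are excluded from the statistics but remain
    in the per-unit table; a group with no usable fit reports NaN with
    count 0.
    """
    groups: dict[int, list[float]] = {}
    all_groups = set()
    for f in fits:
        all_groups.add(f.group_index)
        if f.fitted and FLAG_OUTLIER not in f.flags:
            groups.setdefault(f.group_index, []).append(f.rgr)
    rows = []
    for g in sorted(all_groups):
        vals = np.array(groups.get(g, []), dtype=float)
        rows.append(
            {
                "group": g,
                "n_units": len(vals),
                "rgr_mean": float(vals.mean()) if len(vals) else np.nan,
                "rgr_sd": float(vals.std(ddof=1)) if len(vals) > 1 else
                (0.0 if len(vals) == 1 else np.nan),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_units", "rgr_mean", "rgr_sd"])


def areas_table(records: list[AreaRecord]) -> pd.DataFrame:
    """Tidy table of area records (unit, group, time, area_px, area_cal)."""
    return pd.DataFrame(
        [
            {
                "unit": r.unit_index,
                "group": r.group_index,
                "time": r.time,
                "area_px": r.area_px,
                "area_cal": r.area_cal,
            }
            for r in records
        ],
        columns=["unit", "group", "time", "area_px", "area_cal"],
    )


def fits_table(fits: list[RgrFit]) -> pd.DataFrame:
    """Tidy table of RGR fits, one row per unit, flags semicolon-joined."""
    return pd.DataFrame(
        [
            {
                "unit": f.unit_index,
                "group": f.group_index,
                "rgr": f.rgr,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "residual_std": f.residual_std,
                "n_points": f.n_points,
                "flags": ";".join(sorted(f.flags)),
            }
            for f in fits
        ],
        columns=[
            "unit",
            "group",
            "rgr",
            "intercept",
            "r_squared",
            "residual_std",
            "n_points",
            "flags",
        ],
    )
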