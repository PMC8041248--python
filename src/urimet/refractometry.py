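"""RID-to-specific-gravity calibration, conversion, validation and agreement.

A differential refractive-index detector (RID) reports urine as a peak
area in nano refractive-index units (nRIU).  Area is linear in the excess
specific gravity x = SG - 1, so a weighted least-squares line

    area = slope * (SG - 1) + intercept,   weights 1/x^2

is fitted against refractometer reference values (1/x^2 weighting gives
the low, physiologically common SG range equal relative influence).  All
accuracy/precision statistics are computed on the SG - 1 scale: with SG
values clustered just above 1.000, statistics on SG itself would be
dominated by the constant offset and grossly understate relative error.

Converted SG values are rounded half-away-from-zero at the instrument's
displayed digit count (3 for UG-D-style refractometers, 4 for
UG-alpha-style); the unrounded value is retained for dilution planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

SG_RANGE = (1.000, 1.100)  # plausible urine/NaCl span


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration standard: refractometer SG reference and RID peak area."""

    sg_ref: float
    area: float

    def __post_init__(self) -> None:
        if not (SG_RANGE[0] < self.sg_ref <= SG_RANGE[1]):
            raise ValueError(f"sg_ref {self.sg_ref} outside plausible range {SG_RANGE}")
        if self.area < 0:
            raise ValueError(f"negative RID area {self.area}")


@dataclass(frozen=True)
class CalibrationModel:
    """Linear nRIU-vs-(SG-1) calibration with weighting and readout digits."""

    slope: float  # nRIU per (SG-1) unit
    intercept: float  # nRIU
    weighting_exponent: float = 2.0
    digits: int = 4
    residual_sd: float = float("nan")  # weighted residual SD, n-2 dof
    n: int = 0
    sg_span: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.digits not in (3, 4):
            raise ValueError(f"digits must be 3 or 4, got {self.digits}")

    def sg_to_area(self, sg: float) -> float:
        return self.slope * (sg - 1.0) + self.intercept

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "weighting_exponent": self.weighting_exponent,
            "digits": self.digits,
            "residual_sd": self.residual_sd,
            "n": self.n,
            "sg_span": list(self.sg_span),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CalibrationModel":
        return cls(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            weighting_exponent=float(d.get("weighting_exponent", 2.0)),
            digits=int(d.get("digits", 4)),
            residual_sd=float(d.get("residual_sd", "nan")),
            n=int(d.get("n", 0)),
            sg_span=tuple(d.get("sg_span", (float("nan"), float("nan")))),  # type: ignore[arg-type]
        )


def fit_calibration(
    points: Sequence[CalibrationPoint],
    weighting_exponent: float = 2.0,
    digits: int = 4,
) -> CalibrationModel:
    """Weighted least-squares line area = slope*(SG-1) + intercept.

    Weights are 1/x^weighting_exponent with x = sg_ref - 1, so an exponent
    of 2 gives the standard 1/x^2 calibration weighting; 0 reproduces
    ordinary least squares.  Requires at least two distinct x values.
    """
    if len(points) < 2:
        raise ValueError(f"need at least 2 calibration points, got {len(points)}")
    x = np.array([p.sg_ref - 1.0 for p in points])
    y = np.array([p.area for p in points])
    if (x <= 0).any():
        raise ValueError("calibration requires sg_ref > 1.000 for every point")
    if len(np.unique(x)) < 2:
        raise ValueError("calibration requires at least 2 distinct SG values")
    w = x ** (-weighting_exponent)
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    resid = y - (slope * x + intercept)
    dof = len(points) - 2
    rsd = math.sqrt(float(np.sum(w * resid**2) / dof)) if dof > 0 else float("nan")
    return CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        weighting_exponent=weighting_exponent,
        digits=digits,
        residual_sd=rsd,
        n=len(points),
        sg_span=(float(x.min() + 1.0), float(x.max() + 1.0)),
    )


def _round_half_away(value: float, digits: int) -> float:
    # decimal semantics of the shortest repr, so 1.0015 -> 1.002 like on a display
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SGReading:
    """A converted SG value with instrument-style rounding and range flags."""

    sg: float  # rounded at the instrument's digit count
    sg_raw: float  # unrounded, for dilution planning
    out_of_range: bool  # outside (1.000, 1.100]
    extrapolated: bool  # outside the calibration's fitted SG span


def area_to_sg(area: float, model: CalibrationModel) -> SGReading:
    """Convert an nRIU peak area to SG: 1 + (area - intercept)/slope, rounded.

    Rounding is half-away-from-zero at ``model.digits``.  Values outside
    (1.000, 1.100] carry an out-of-range flag; values beyond the fitted
    calibration span carry an extrapolation flag.  Neither flag raises.
    """
    raw = 1.0 + (area - model.intercept) / model.slope
    rounded = _round_half_away(raw, model.digits)
    lo, hi = model.sg_span
    extrapolated = bool(np.isfinite(lo) and (raw < lo or raw > hi))
    out = not (SG_RANGE[0] < rounded <= SG_RANGE[1])
    return SGReading(sg=rounded, sg_raw=raw, out_of_range=out, extrapolated=extrapolated)


def areas_to_sg(areas: Sequence[float], model: CalibrationModel) -> list[SGReading]:
    return [area_to_sg(a, model) for a in areas]


# ---------------------------------------------------------------------------
# FDA-style accuracy / precision validation on the SG-1 scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelValidation:
    level: str
    nominal_sg: float
    n: int
    accuracy_pct: float  # mean(SG-1)/nominal(SG-1) * 100
    precision_cv_pct: float  # CV of SG-1
    passed: bool


@dataclass(frozen=True)
class ValidationReport:
    levels: tuple[LevelValidation, ...]
    threshold_pct: float

    @property
    def passed(self) -> bool:
        return all(lv.passed for lv in self.levels)


def validate_levels(
    measurements: Mapping[str, Sequence[float]],
    nominals: Mapping[str, float],
    threshold_pct: float = 15.0,
) -> ValidationReport:
    """Accuracy and precision per QC level, computed on SG - 1.

    A level passes when accuracy lies within 100 +/- threshold_pct and the
    CV of SG - 1 does not exceed threshold_pct.
    """
    out = []
    for level, values in measurements.items():
        nominal = nominals[level]
        if nominal <= 1.0:
            raise ValueError(f"level {level!r}: nominal SG must be > 1.000, got {nominal}")
        vals = np.asarray(values, dtype=float) - 1.0
        if len(vals) < 2:
            raise ValueError(f"level {level!r}: need >= 2 replicates, got {len(vals)}")
        acc = float(vals.mean() / (nominal - 1.0) * 100.0)
        cv = float(vals.std(ddof=1) / vals.mean() * 100.0) if vals.mean() != 0 else float("inf")
        passed = (100.0 - threshold_pct <= acc <= 100.0 + threshold_pct) and cv <= threshold_pct
        out.append(
            LevelValidation(
                level=level, nominal_sg=nominal, n=len(vals),
                accuracy_pct=acc, precision_cv_pct=cv, passed=passed,
            )
        )
    return ValidationReport(levels=tuple(out), threshold_pct=threshold_pct)


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference (bias) and 95% limits of agreement, in SG units."""

    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValueError("limits of agreement must bracket the bias")


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman statistics for paired measurements (differences y - x).

    bias = mean(d); limits of agreement = bias +/- 1.96 * SD(d) with the
    n-1 denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError(f"need >= 2 pairs, got {x.size}")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=x.size)


def plot_bland_altman(x: Sequence[float], y: Sequence[float], ax=None):
    """Bland-Altman plot: per-pair mean vs difference, bias and LOA lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, y - x, marker="D", s=12, color="tab:blue")
    ax.axhline(res.bias, color="red")
    for loa in (res.loa_low, res.loa_high):
        ax.axhline(loa, color="red", linestyle=":")
    ax.set_xlabel("mean SG of the two methods")
    ax.set_ylabel("SG difference")
    return ax, res
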