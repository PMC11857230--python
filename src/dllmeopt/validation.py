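"""Method-validation mathematics: calibration, LOD/LOQ, recovery, precision.

Quantification follows internal-standard calibration: the analyte/IS peak
area ratio is regressed on spiked concentration; detection and quantitation
limits come from the residual standard deviation σ and slope S of that line,

    LOD = 3.3 σ / S,        LOQ = 10 σ / S,

so LOQ/LOD = 10/3.3 exactly.  Accuracy is expressed as the matrix recovery
R = (Co − Cb)/Cs × 100 from paired spiked/unspiked measurements, and
precision as the relative standard deviation (sample sd / mean × 100),
intra-day within an analytical day and inter-day pooled over all days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "RecoveryRecord",
    "PrecisionRecord",
    "fit_calibration",
    "lod_loq",
    "quantify",
    "recovery",
    "precision",
    "rsd",
]


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float  # S, area-ratio per µg/L
    intercept: float
    r_squared: float
    residual_sd: float  # σ, n−2 denominator
    lod: float
    loq: float
    linear_range: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class RecoveryRecord:
    analyte: str
    matrix_id: str
    level: str
    co: float  # measured concentration in the spiked matrix
    cb: float  # measured concentration in the unspiked matrix
    cs: float  # spiked concentration
    recovery_pct: float


@dataclass(frozen=True)
class PrecisionRecord:
    analyte: str
    level: str
    intra_day_rsd: float
    inter_day_rsd: float
    n_extractions: int


def lod_loq(sigma: float, slope: float) -> tuple[float, float]:
    """Detection and quantitation limits from residual sd and slope."""
    if slope <= 0:
        raise ValueError("calibration slope must be > 0")
    if sigma < 0:
        raise ValueError("residual sd must be >= 0")
    return 3.3 * sigma / slope, 10.0 * sigma / slope


def fit_calibration(points: pd.DataFrame, analyte: str | None = None) -> CalibrationCurve:
    """Least-squares calibration line of area_ratio on concentration.

    Requires ≥ 3 distinct concentration levels; σ is the residual standard
    deviation on n−2 degrees of freedom and r² the squared Pearson
    correlation of fitted vs observed (identical to the coefficient of
    determination for a simple linear fit).
    """
    if analyte is not None:
        points = points[points["analyte"] == analyte]
    elif "analyte" in points.columns:
        uniq = points["analyte"].unique()
        if len(uniq) > 1:
            raise ValueError("calibration table holds several analytes; pass `analyte`")
        analyte = str(uniq[0]) if len(uniq) else "analyte"
    else:
        analyte = "analyte"
    c = points["concentration"].to_numpy(dtype=float)
    y = points["area_ratio"].to_numpy(dtype=float)
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct calibration levels")
    if np.ptp(c) == 0:
        raise ValueError("zero concentration spread")
    fit = stats.linregress(c, y)
    resid = y - (fit.intercept + fit.slope * c)
    sigma = float(np.sqrt((resid @ resid) / (len(c) - 2)))
    lod, loq = lod_loq(sigma, float(fit.slope))
    return CalibrationCurve(
        analyte=analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        residual_sd=sigma,
        lod=lod,
        loq=loq,
        linear_range=(float(c.min()), float(c.max())),
        n_points=len(c),
    )


def quantify(area_ratio: float, curve: CalibrationCurve) -> tuple[float, str]:
    """Invert the calibration line; qualify the result against LOD/LOQ/range.

    Returns (concentration, qualifier) with qualifier one of
    ``ok | below_LOQ | below_LOD | above_range``.
    """
    conc = (area_ratio - curve.intercept) / curve.slope
    if conc < curve.lod:
        return conc, "below_LOD"
    if conc < curve.loq:
        return conc, "below_LOQ"
    if conc > curve.linear_range[1]:
        return conc, "above_range"
    return conc, "ok"


def recovery(co: float, cb: float, cs: float) -> float:
    """Matrix recovery R = (Co − Cb)/Cs × 100 (%)."""
    if cs <= 0:
        raise ValueError("spiked concentration Cs must be > 0")
    return (co - cb) / cs * 100.0


def rsd(values) -> float:
    """Relative standard deviation, % (sample sd over mean)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("RSD needs at least 2 measurements")
    m = v.mean()
    if m == 0:
        raise ValueError("RSD undefined at zero mean")
    return float(v.std(ddof=1) / m * 100.0)


def precision(
    measurements_by_day: dict[str, np.ndarray | list[float]],
    analyte: str = "analyte",
    level: str = "level",
) -> PrecisionRecord:
    """Intra- and inter-day precision of repeated extractions.

    Intra-day RSD is the mean of per-day RSDs; inter-day RSD pools all
    measurements across days.
    """
    if not measurements_by_day:
        raise ValueError("no measurements supplied")
    per_day = []
    pooled: list[float] = []
    for day, vals in measurements_by_day.items():
        v = np.asarray(vals, dtype=float)
        if len(v) < 2:
            raise ValueError(f"day {day!r} has fewer than 2 measurements")
        per_day.append(rsd(v))
        pooled.extend(v.tolist())
    return PrecisionRecord(
        analyte=analyte,
        level=level,
        intra_day_rsd=float(np.mean(per_day)),
        inter_day_rsd=rsd(pooled),
        n_extractions=len(pooled),
    )
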