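"""Error metrics, dataset description and cumulative-frequency curves.

The five regression metrics follow the conventions of the DES sound-speed
QSPR literature:

    ARD%  = (100/N) sum |(u_exp - u_calc) / u_exp|
    RMSE  = sqrt( sum (u_exp - u_calc)^2 / N )                      [m/s]
    SD    = sqrt( sum ((u_exp - u_calc)^2 / u_exp) / (N - 1) )
    MAE   = (1/N) sum |u_exp - u_calc|                              [m/s]
    R^2   = 1 - sum (u_exp - u_calc)^2 / sum (u_exp - mean(u_exp))^2

SD is kept in the verbatim (residual-squared over experimental value) form
reported alongside ARD% in this literature, odd units and all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataFormatError, ValidityRangeError


@dataclass(frozen=True)
class MetricsReport:
    ard_percent: float
    rmse: float
    sd: float
    mae: float
    r2: float
    n: int
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "ard_percent": self.ard_percent,
            "rmse": self.rmse,
            "sd": self.sd,
            "mae": self.mae,
            "r2": self.r2,
        }


def metrics(exp, calc, label: str = "") -> MetricsReport:
    """Compute all five metrics over paired experimental/calculated values."""
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if exp.shape != calc.shape:
        raise ValidityRangeError(
            f"length mismatch: exp has {exp.size} points, calc has {calc.size}"
        )
    n = exp.size
    if n < 2:
        raise ValidityRangeError(f"need at least 2 paired points, got {n}")
    if np.any(exp <= 0):
        raise ValidityRangeError("experimental values must be strictly positive")
    resid = exp - calc
    ard = 100.0 / n * np.sum(np.abs(resid / exp))
    rmse = float(np.sqrt(np.sum(resid**2) / n))
    sd = float(np.sqrt(np.sum(resid**2 / exp) / (n - 1)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((exp - exp.mean()) ** 2))
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else float("nan")
    return MetricsReport(
        ard_percent=float(ard), rmse=rmse, sd=sd, mae=mae, r2=r2, n=int(n), label=label
    )


def ard_per_point(exp, calc) -> np.ndarray:
    """Pointwise absolute relative deviation in percent."""
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if np.any(exp <= 0):
        raise ValidityRangeError("experimental values must be strictly positive")
    return 100.0 * np.abs((exp - calc) / exp)


#: Row order of the statistical summary.
SUMMARY_STATISTICS = (
    "minimum",
    "maximum",
    "range",
    "mean",
    "median",
    "standard_deviation",
    "variance",
    "mid_range",
    "interquartile_range",
    "sum_of_squares",
    "mean_absolute_deviation",
    "root_mean_square",
    "skewness",
    "kurtosis",
    "coefficient_of_variation",
)


def summarize(data, ddof: int = 1) -> pd.DataFrame:
    """Column-wise statistical description of a modelling dataset.

    ``data`` is a DataFrame (or mapping of name -> vector).  Sample
    (``ddof=1``) and population (``ddof=0``) variance conventions are both
    exposed; skewness and kurtosis use population moments with non-excess
    kurtosis (a normal column scores about 3).  Sum of squares is central,
    sum (x - mean)^2.  Constant columns get NaN skewness/kurtosis and a
    warning rather than a crash.
    """
    df = pd.DataFrame(data)
    if len(df) < 4:
        raise ValidityRangeError(f"need n >= 4 rows for kurtosis, got {len(df)}")
    out = {}
    for col in df.columns:
        x = df[col].to_numpy()
        try:
            x = np.asarray(x, dtype=float)
        except (TypeError, ValueError):
            bad = next(
                i for i, v in enumerate(df[col]) if not isinstance(v, (int, float))
            )
            raise DataFormatError(
                f"column {col!r}: non-numeric cell at row {bad}"
            ) from None
        if np.any(~np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x))[0])
            raise DataFormatError(f"column {col!r}: non-finite cell at row {bad}")
        mean = float(x.mean())
        sd = float(x.std(ddof=ddof))
        if sd == 0:
            warnings.warn(
                f"column {col!r} is constant; skewness/kurtosis undefined",
                RuntimeWarning,
                stacklevel=2,
            )
            skew = kurt = float("nan")
            cv = 0.0
        else:
            skew = float(stats.skew(x, bias=True))
            kurt = float(stats.kurtosis(x, fisher=False, bias=True))
            cv = sd / mean if mean != 0 else float("inf")
        out[col] = {
            "minimum": float(x.min()),
            "maximum": float(x.max()),
            "range": float(x.max() - x.min()),
            "mean": mean,
            "median": float(np.median(x)),
            "standard_deviation": sd,
            "variance": float(x.var(ddof=ddof)),
            "mid_range": float((x.max() + x.min()) / 2),
            "interquartile_range": float(
                np.percentile(x, 75) - np.percentile(x, 25)
            ),
            "sum_of_squares": float(np.sum((x - mean) ** 2)),
            "mean_absolute_deviation": float(np.mean(np.abs(x - mean))),
            "root_mean_square": float(np.sqrt(np.mean(x**2))),
            "skewness": skew,
            "kurtosis": kurt,
            "coefficient_of_variation": cv,
        }
    return pd.DataFrame(out).reindex(list(SUMMARY_STATISTICS))


def cumulative_frequency(ard_per_point) -> pd.DataFrame:
    """Empirical CDF of pointwise ARD%: fraction of points at or below each
    observed threshold.  Right-continuous; the last fraction is 1."""
    ard = np.asarray(ard_per_point, dtype=float)
    if ard.size == 0:
        raise ValidityRangeError("empty ARD vector")
    if np.any(ard < 0):
        raise ValidityRangeError("ARD values must be non-negative")
    thresholds = np.unique(ard)
    fraction = np.searchsorted(np.sort(ard), thresholds, side="right") / ard.size
    return pd.DataFrame({"threshold": thresholds, "fraction": fraction})


def fraction_below(ard_per_point, threshold: float) -> float:
    """Fraction of points with ARD% <= threshold."""
    ard = np.asarray(ard_per_point, dtype=float)
    if ard.size == 0:
        raise ValidityRangeError("empty ARD vector")
    return float(np.mean(ard <= threshold))
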