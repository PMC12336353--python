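"""Applicability-domain and sensitivity diagnostics.

Leverage analysis: with design matrix X (here an intercept column plus the
four scaled inputs), the hat matrix H = X (X^T X)^-1 X^T projects onto the
column space of X; its diagonal h_i measures each observation's influence.
Points are screened on the Williams plot: standardized residuals SR against
leverage, with the applicability domain 0 <= h <= h* = 3(n+1)/m and
|SR| <= 3 (n inputs, m points).

Garson sensitivity: the relative importance of input j is obtained by
partitioning absolute input->hidden connection weights along each
hidden->output path,

    IF_j = sum_m ( |w_jm^ih| / sum_k |w_km^ih| * |w_m^ho| ) / (total over j)

normalized to sum to one.  A signed variant (raw w^ho multiplier) is
available behind a flag but can produce negative "importances".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidityRangeError
from .network import FEATURE_COLUMNS, SoundSpeedModel

FLAG_IN_DOMAIN = "in_domain"
FLAG_HIGH_LEVERAGE = "high_leverage"
FLAG_OUTLIER = "outlier"
FLAG_BOTH = "both"


@dataclass
class DiagnosticsReport:
    leverage: np.ndarray
    standardized_residuals: np.ndarray
    h_star: float
    flags: np.ndarray  # array of flag strings, one per point
    garson_importance: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "leverage": self.leverage,
                "standardized_residual": self.standardized_residuals,
                "flag": self.flags,
            }
        )

    @property
    def n_outliers(self) -> int:
        return int(np.sum((self.flags == FLAG_OUTLIER) | (self.flags == FLAG_BOTH)))


def hat_diagonal(X) -> np.ndarray:
    """Diagonal of H = X (X^T X)^-1 X^T via a thin QR (no explicit inverse)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidityRangeError("design matrix must be 2-D")
    m, p = X.shape
    if m <= p:
        raise ValidityRangeError(f"need more rows than columns, got {m}x{p}")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if diag.min() <= np.finfo(float).eps * max(m, p) * diag.max():
        raise ValidityRangeError("collinear design (rank-deficient X)")
    return np.einsum("ij,ij->i", q, q)


def critical_leverage(n_inputs: int, m_points: int) -> float:
    """h* = 3(n+1)/m with n model inputs and m data points."""
    if m_points <= 0:
        raise ValidityRangeError("m_points must be positive")
    return 3.0 * (n_inputs + 1) / m_points


def standardized_residuals(exp, calc, ddof: int = 1) -> np.ndarray:
    """Residuals divided by their standard deviation over the evaluated set."""
    resid = np.asarray(exp, dtype=float) - np.asarray(calc, dtype=float)
    sd = float(np.std(resid, ddof=ddof)) if resid.size > ddof else 0.0
    if sd == 0:
        warnings.warn(
            "zero residual variance; standardized residuals set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(resid)
    return resid / sd


def williams(
    exp,
    calc,
    X,
    n_inputs: int | None = None,
    sr_limit: float = 3.0,
) -> DiagnosticsReport:
    """Classify points on the Williams plane (leverage vs standardized residual).

    ``X`` is the design matrix used for leverage (conventionally intercept +
    scaled inputs, see :func:`leverage_design`); ``n_inputs`` defaults to
    X's column count minus the intercept.
    """
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    X = np.asarray(X, dtype=float)
    if not (exp.size == calc.size == X.shape[0]):
        raise ValidityRangeError("exp, calc and X must have consistent lengths")
    lev = hat_diagonal(X)
    sr = standardized_residuals(exp, calc)
    if n_inputs is None:
        n_inputs = X.shape[1] - 1
    h_star = critical_leverage(n_inputs, X.shape[0])
    high = lev > h_star
    out = np.abs(sr) > sr_limit
    flags = np.full(exp.size, FLAG_IN_DOMAIN, dtype=object)
    flags[high] = FLAG_HIGH_LEVERAGE
    flags[out] = FLAG_OUTLIER
    flags[high & out] = FLAG_BOTH
    return DiagnosticsReport(
        leverage=lev,
        standardized_residuals=sr,
        h_star=h_star,
        flags=np.asarray(flags),
    )


def leverage_design(model: SoundSpeedModel, X_raw) -> np.ndarray:
    """Intercept column plus the model-scaled inputs (p = 5 columns)."""
    X_raw = np.atleast_2d(np.asarray(X_raw, dtype=float))
    s = model.scaler.scale_x(X_raw)
    return np.hstack([np.ones((s.shape[0], 1)), s])


def williams_for_model(model: SoundSpeedModel, data: pd.DataFrame) -> DiagnosticsReport:
    """Convenience wrapper: run the Williams screen of a model on a dataset."""
    X = data.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    exp = data["u_ms"].to_numpy(dtype=float)
    calc = model.forward(X)
    return williams(exp, calc, leverage_design(model, X), n_inputs=len(FEATURE_COLUMNS))


def garson_importance(w_ih, w_ho, signed: bool = False) -> np.ndarray:
    """Relative importance of each input by Garson weight partitioning.

    ``w_ih`` has shape (n_hidden, n_inputs) and ``w_ho`` (n_hidden,).
    Absolute values are used throughout (``signed=True`` keeps the raw
    hidden->output multiplier).  The result sums to 1 and is invariant to a
    common positive rescaling of all weights.
    """
    w_ih = np.asarray(w_ih, dtype=float)
    w_ho = np.asarray(w_ho, dtype=float)
    if w_ih.ndim != 2 or w_ho.shape != (w_ih.shape[0],):
        raise ValidityRangeError(
            f"inconsistent shapes: w_ih {w_ih.shape}, w_ho {w_ho.shape}"
        )
    absin = np.abs(w_ih)
    row_sums = absin.sum(axis=1)
    if np.all(row_sums == 0) or np.all(w_ho == 0):
        raise ValidityRangeError("all-zero weights: importance undefined")
    keep = row_sums > 0
    mult = w_ho if signed else np.abs(w_ho)
    contrib = (absin[keep] / row_sums[keep, None]) * mult[keep, None]
    imp = contrib.sum(axis=0)
    total = imp.sum()
    if total == 0:
        raise ValidityRangeError("importances sum to zero (signed cancellation)")
    return imp / total


def garson_for_model(model: SoundSpeedModel, signed: bool = False) -> np.ndarray:
    return garson_importance(model.w_ih, model.w_ho, signed=signed)
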