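"""The 4-16-1 sound-speed regression network.

Inputs are (T [K], V_c [cm^3/mol], omega [-], MW [g/mol]); the output is the
speed of sound u [m/s].  Inputs and target are min-max scaled to [-1, 1]
(scaler fitted on the training split only), the single hidden layer uses the
hyperbolic-tangent sigmoid

    tansig(z) = 2 / (1 + exp(-2 z)) - 1 = tanh(z)

and the output neuron is linear.  Training minimises the mean squared error
on scaled targets with a Levenberg-Marquardt loop: damped Gauss-Newton on
the full Jacobian, multiplicative damping (x10 on reject, /10 on accept),
best-so-far parameters returned on non-convergence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidityRangeError
from .metrics import MetricsReport, metrics

#: Column order of the model inputs in a dataset frame.
FEATURE_COLUMNS = ("T_K", "Vc_cm3mol", "omega", "MW_gmol")
TARGET_COLUMN = "u_ms"


def tansig(z):
    """Hyperbolic-tangent sigmoid, 2/(1+exp(-2z)) - 1; identical to tanh."""
    return np.tanh(z)


@dataclass(frozen=True)
class ScalerParams:
    """Per-column min-max affine map onto [lo, hi] for inputs and target."""

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    lo: float = -1.0
    hi: float = 1.0

    @classmethod
    def fit(cls, X, y, lo: float = -1.0, hi: float = 1.0) -> "ScalerParams":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        x_min, x_max = X.min(axis=0), X.max(axis=0)
        if np.any(x_max <= x_min):
            cols = [
                FEATURE_COLUMNS[i] if i < len(FEATURE_COLUMNS) else str(i)
                for i in np.flatnonzero(x_max <= x_min)
            ]
            raise ValidityRangeError(f"constant feature column(s): {cols}")
        if y.max() <= y.min():
            raise ValidityRangeError("constant target column")
        return cls(x_min=x_min, x_max=x_max, y_min=float(y.min()),
                   y_max=float(y.max()), lo=lo, hi=hi)

    def _fwd(self, v, vmin, vmax):
        return self.lo + (self.hi - self.lo) * (v - vmin) / (vmax - vmin)

    def _inv(self, s, vmin, vmax):
        return vmin + (s - self.lo) * (vmax - vmin) / (self.hi - self.lo)

    def scale_x(self, X):
        return self._fwd(np.asarray(X, dtype=float), self.x_min, self.x_max)

    def unscale_x(self, S):
        return self._inv(np.asarray(S, dtype=float), self.x_min, self.x_max)

    def scale_y(self, y):
        return self._fwd(np.asarray(y, dtype=float), self.y_min, self.y_max)

    def unscale_y(self, s):
        return self._inv(np.asarray(s, dtype=float), self.y_min, self.y_max)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
            "y_min": self.y_min,
            "y_max": self.y_max,
            "lo": self.lo,
            "hi": self.hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=float(d["y_min"]),
            y_max=float(d["y_max"]),
            lo=float(d["lo"]),
            hi=float(d["hi"]),
        )


@dataclass
class SoundSpeedModel:
    """Weights, biases and scaler of a trained 4-n_hidden-1 network."""

    w_ih: np.ndarray  # (n_hidden, 4)
    b_h: np.ndarray  # (n_hidden,)
    w_ho: np.ndarray  # (n_hidden,)
    b_o: float
    scaler: ScalerParams
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w_ih = np.asarray(self.w_ih, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        self.w_ho = np.asarray(self.w_ho, dtype=float)
        h = self.w_ih.shape[0]
        if self.w_ih.ndim != 2 or self.w_ih.shape[1] != len(FEATURE_COLUMNS):
            raise DataFormatError(
                f"w_ih must be (n_hidden, 4), got {self.w_ih.shape}"
            )
        if self.b_h.shape != (h,) or self.w_ho.shape != (h,):
            raise DataFormatError("b_h/w_ho shapes inconsistent with w_ih")
        for name, arr in (("w_ih", self.w_ih), ("b_h", self.b_h),
                          ("w_ho", self.w_ho), ("b_o", np.asarray(self.b_o))):
            if not np.all(np.isfinite(arr)):
                raise DataFormatError(f"non-finite entries in {name}")

    @property
    def n_hidden(self) -> int:
        return self.w_ih.shape[0]

    def forward(self, X) -> np.ndarray:
        """Predict u [m/s] for raw inputs X of shape (n, 4) or (4,)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(FEATURE_COLUMNS):
            raise DataFormatError(
                f"expected {len(FEATURE_COLUMNS)} input columns, got {X.shape[1]}"
            )
        s = self.scaler.scale_x(X)
        hidden = tansig(s @ self.w_ih.T + self.b_h)
        y_scaled = hidden @ self.w_ho + self.b_o
        return self.scaler.unscale_y(y_scaled)

    predict = forward

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        return self.forward(df.loc[:, list(FEATURE_COLUMNS)].to_numpy())

    def to_dict(self) -> dict:
        return {
            "schema": 1,
            "n_hidden": self.n_hidden,
            "feature_columns": list(FEATURE_COLUMNS),
            "w_ih": self.w_ih.tolist(),
            "b_h": self.b_h.tolist(),
            "w_ho": self.w_ho.tolist(),
            "b_o": float(self.b_o),
            "scaler": self.scaler.to_dict(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SoundSpeedModel":
        try:
            return cls(
                w_ih=np.asarray(d["w_ih"], dtype=float),
                b_h=np.asarray(d["b_h"], dtype=float),
                w_ho=np.asarray(d["w_ho"], dtype=float),
                b_o=float(d["b_o"]),
                scaler=ScalerParams.from_dict(d["scaler"]),
                metadata=dict(d.get("metadata", {})),
            )
        except KeyError as exc:
            raise DataFormatError(f"model file missing field {exc}") from None


def save_model(model: SoundSpeedModel, path: str | Path) -> None:
    """JSON round-trip preserves every weight bit-for-bit (shortest repr)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> SoundSpeedModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"corrupted model file {path}: {exc}") from None
    return SoundSpeedModel.from_dict(payload)


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the LM training loop; all tolerances strictly positive."""

    n_hidden: int = 16
    max_iterations: int = 400
    lambda_init: float = 1e-2
    lambda_up: float = 10.0
    lambda_down: float = 10.0
    lambda_max: float = 1e12
    grad_tol: float = 1e-8
    step_tol: float = 1e-12
    seed: int = 42
    train_fraction: float = 300 / 415
    init_scale: float = 0.5
    n_restarts: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidityRangeError("train_fraction must lie in (0, 1)")
        if min(self.grad_tol, self.step_tol) <= 0:
            raise ValidityRangeError("tolerances must be positive")
        if self.n_hidden < 1:
            raise ValidityRangeError("n_hidden must be a positive integer")


@dataclass
class TrainingReport:
    train_metrics: MetricsReport
    test_metrics: MetricsReport
    loss_history: list
    n_iterations: int
    converged: bool
    seed: int
    n_hidden: int

    def to_dict(self) -> dict:
        return {
            "train": self.train_metrics.to_dict(),
            "test": self.test_metrics.to_dict(),
            "final_loss": self.loss_history[-1],
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "n_hidden": self.n_hidden,
        }


def _pack(w_ih, b_h, w_ho, b_o):
    return np.concatenate([w_ih.ravel(), b_h, w_ho, [b_o]])


def _unpack(p, h, d):
    w_ih = p[: h * d].reshape(h, d)
    b_h = p[h * d : h * d + h]
    w_ho = p[h * d + h : h * d + 2 * h]
    b_o = p[-1]
    return w_ih, b_h, w_ho, b_o


def _residuals_and_jacobian(p, Xs, ys, h, with_jac=True):
    d = Xs.shape[1]
    w_ih, b_h, w_ho, b_o = _unpack(p, h, d)
    z = Xs @ w_ih.T + b_h
    a = np.tanh(z)
    r = a @ w_ho + b_o - ys
    if not with_jac:
        return r, None
    sech2 = 1.0 - a * a  # (n, h)
    g = sech2 * w_ho  # d r / d z_j
    # columns ordered as _pack: w_ih (h*d), b_h (h), w_ho (h), b_o (1)
    J = np.empty((Xs.shape[0], p.size))
    J[:, : h * d] = (g[:, :, None] * Xs[:, None, :]).reshape(Xs.shape[0], h * d)
    J[:, h * d : h * d + h] = g
    J[:, h * d + h : h * d + 2 * h] = a
    J[:, -1] = 1.0
    return r, J


def _lm_fit(Xs, ys, p0, config: TrainingConfig):
    """Damped Gauss-Newton on 0.5*sum(r^2); returns (p_best, history, converged)."""
    p = p0.copy()
    r, _ = _residuals_and_jacobian(p, Xs, ys, config.n_hidden, with_jac=False)
    loss = 0.5 * float(r @ r)
    lam = config.lambda_init
    history = [loss]
    converged = False
    eye = np.eye(p.size)
    for _ in range(config.max_iterations):
        r, J = _residuals_and_jacobian(p, Xs, ys, config.n_hidden)
        grad = J.T @ r
        if np.max(np.abs(grad)) < config.grad_tol:
            converged = True
            break
        JtJ = J.T @ J
        accepted = False
        while lam <= config.lambda_max:
            try:
                step = np.linalg.solve(JtJ + lam * eye, -grad)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            r_new, _ = _residuals_and_jacobian(
                p + step, Xs, ys, config.n_hidden, with_jac=False
            )
            loss_new = 0.5 * float(r_new @ r_new)
            if np.isfinite(loss_new) and loss_new < loss:
                p = p + step
                loss = loss_new
                lam = max(lam / config.lambda_down, 1e-14)
                history.append(loss)
                accepted = True
                break
            lam *= config.lambda_up
        if not accepted:
            break
        if np.linalg.norm(step) < config.step_tol * (1.0 + np.linalg.norm(p)):
            converged = True
            break
    return p, history, converged


def split_dataset(n: int, train_fraction: float, seed: int):
    """Seeded uniform shuffle into train/test index arrays."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def train(
    data: pd.DataFrame,
    config: TrainingConfig = TrainingConfig(),
) -> tuple[SoundSpeedModel, TrainingReport]:
    """Train a sound-speed network on a dataset frame.

    The frame needs the feature columns (T_K, Vc_cm3mol, omega, MW_gmol) and
    u_ms.  Rows are split train/test by a seeded shuffle; the scaler is
    fitted on the training split only.  Several seeded restarts are run and
    the lowest-training-loss fit is kept; the loss history reported is that
    of the winning restart (non-increasing across accepted steps).
    """
    missing = [c for c in (*FEATURE_COLUMNS, TARGET_COLUMN) if c not in data.columns]
    if missing:
        raise DataFormatError(f"dataset missing column(s) {missing}")
    X = data.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = data.loc[:, TARGET_COLUMN].to_numpy(dtype=float)
    n = len(y)
    n_params = config.n_hidden * (len(FEATURE_COLUMNS) + 2) + 1
    if n < 4:
        raise ValidityRangeError(f"insufficient data: {n} rows")
    if n < n_params / 2:
        warnings.warn(
            f"only {n} rows for {n_params} parameters; fit may be degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    idx_train, idx_test = split_dataset(n, config.train_fraction, config.seed)
    scaler = ScalerParams.fit(X[idx_train], y[idx_train])
    Xs = scaler.scale_x(X[idx_train])
    ys = scaler.scale_y(y[idx_train])

    best = None
    rng = np.random.default_rng(config.seed)
    for _ in range(max(config.n_restarts, 1)):
        p0 = rng.uniform(-config.init_scale, config.init_scale, size=n_params)
        p, history, converged = _lm_fit(Xs, ys, p0, config)
        if best is None or history[-1] < best[1][-1]:
            best = (p, history, converged)
    p, history, converged = best
    if not converged:
        warnings.warn(
            "LM did not reach its convergence tolerances; returning the "
            "best-so-far parameters",
            RuntimeWarning,
            stacklevel=2,
        )
    w_ih, b_h, w_ho, b_o = _unpack(p, config.n_hidden, len(FEATURE_COLUMNS))
    model = SoundSpeedModel(
        w_ih=w_ih,
        b_h=b_h,
        w_ho=w_ho,
        b_o=float(b_o),
        scaler=scaler,
        metadata={
            "seed": config.seed,
            "n_iterations": len(history) - 1,
            "final_loss": history[-1],
            "converged": converged,
            "n_train": int(idx_train.size),
            "n_test": int(idx_test.size),
        },
    )
    report = TrainingReport(
        train_metrics=metrics(y[idx_train], model.forward(X[idx_train]), "train"),
        test_metrics=metrics(y[idx_test], model.forward(X[idx_test]), "test"),
        loss_history=history,
        n_iterations=len(history) - 1,
        converged=converged,
        seed=config.seed,
        n_hidden=config.n_hidden,
    )
    return model, report


@dataclass
class SweepResult:
    table: pd.DataFrame
    selected: int
    models: dict


def neuron_sweep(
    data: pd.DataFrame,
    candidate_sizes,
    config: TrainingConfig = TrainingConfig(),
) -> SweepResult:
    """Train one model per hidden size; pick the test-ARD optimum.

    Ties break toward parsimony: the smallest size within 1% relative of the
    best test ARD wins.  Duplicated candidates are deduplicated with a
    warning.  The split and the restart seeds are shared across sizes.
    """
    sizes = list(dict.fromkeys(int(s) for s in candidate_sizes))
    if len(sizes) < len(list(candidate_sizes)):
        warnings.warn("duplicate hidden sizes deduplicated", UserWarning, stacklevel=2)
    if not sizes:
        raise ValidityRangeError("need at least one candidate hidden size")
    rows, models = [], {}
    for h in sizes:
        model, report = train(data, replace(config, n_hidden=h))
        models[h] = model
        rows.append(
            {
                "n_hidden": h,
                "train_ard_percent": report.train_metrics.ard_percent,
                "test_ard_percent": report.test_metrics.ard_percent,
            }
        )
    table = pd.DataFrame(rows)
    best_ard = table["test_ard_percent"].min()
    ok = table[table["test_ard_percent"] <= best_ard * 1.01]
    selected = int(ok["n_hidden"].min())
    return SweepResult(table=table, selected=selected, models=models)
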