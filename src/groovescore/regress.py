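"""PLS calibration of the scoring function and leave-one-out validation.

The five term columns are mean-centred (and by default unit-variance
scaled) and regressed on experimental binding free energies with PLS1
(NIPALS, via scikit-learn).  Model quality is reported as the
cross-validated correlation q2 = 1 - PRESS / SS_tot and the standard error
of prediction S_press = sqrt(PRESS / n), with PRESS accumulated from an
explicit n-refit leave-one-out loop (no shortcut formulas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .errors import RegressionError
from .terms import TermVector

__all__ = [
    "RegressionModel", "CVResult", "fit_pls", "predict", "loocv",
    "select_components",
]


@dataclass
class RegressionModel:
    """Fitted linear scoring model: intercept plus one coefficient per term,
    expressed on the original (unscaled) term axes, in kJ/mol per unit."""

    intercept: float
    coefficients: np.ndarray
    n_components: int
    training_ids: list = field(default_factory=list)
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    scaled: bool = True

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "n_components": self.n_components,
            "training_ids": list(self.training_ids),
            "x_mean": None if self.x_mean is None else list(map(float, self.x_mean)),
            "x_std": None if self.x_std is None else list(map(float, self.x_std)),
            "scaled": self.scaled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            n_components=int(d["n_components"]),
            training_ids=list(d.get("training_ids", [])),
            x_mean=None if d.get("x_mean") is None else np.asarray(d["x_mean"]),
            x_std=None if d.get("x_std") is None else np.asarray(d["x_std"]),
            scaled=bool(d.get("scaled", True)),
        )


@dataclass
class CVResult:
    """Leave-one-out summary: q2, S_press (kJ/mol) and per-fold predictions."""

    q2: float
    s_press: float
    per_fold_predictions: dict
    n: int


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise RegressionError("X must be a 2-D matrix")
    return X


def _active_columns(X: np.ndarray) -> np.ndarray:
    """Columns with non-negligible variation.

    Near-constant columns carry no information but, once autoscaled to unit
    variance, amplify float noise into wild extrapolations; they are held
    out of the latent-variable fit and given zero coefficient.
    """
    std = X.std(axis=0, ddof=1)
    span = np.maximum(1.0, np.abs(X).max(axis=0))
    return std > 1e-9 * span


def _effective_rank(X: np.ndarray, scale: bool) -> int:
    X = X[:, _active_columns(X)]
    if X.shape[1] == 0:
        return 0
    Xc = X - X.mean(axis=0)
    if scale:
        std = Xc.std(axis=0, ddof=1)
        std[std == 0] = 1.0
        Xc = Xc / std
    return int(np.linalg.matrix_rank(Xc, tol=1e-10))


def fit_pls(
    X, y, n_components: int | None = None,
    scale: bool = True, ids: list | None = None,
) -> RegressionModel:
    """Fit PLS1 of y (kJ/mol) on the term matrix X.

    With `n_components=None` the component count defaults to
    min(n_columns, n - 2), clamped to the column rank; an explicit request
    beyond the rank raises.  With the maximum number of components the
    training predictions coincide with ordinary least squares.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n != y.size:
        raise RegressionError(f"X has {n} rows but y has {y.size}")
    if n < 3:
        raise RegressionError("at least 3 training rows required")
    ids = list(ids) if ids is not None else list(range(n))

    if np.ptp(y) == 0:
        # degenerate target: flat model at the mean
        return RegressionModel(
            intercept=float(y.mean()),
            coefficients=np.zeros(p),
            n_components=0,
            training_ids=ids,
            x_mean=X.mean(axis=0),
            x_std=np.ones(p),
            scaled=scale,
        )

    active = _active_columns(X)
    if not active.any():
        return RegressionModel(
            intercept=float(y.mean()),
            coefficients=np.zeros(p),
            n_components=0,
            training_ids=ids,
            x_mean=X.mean(axis=0),
            x_std=np.ones(p),
            scaled=scale,
        )
    rank = _effective_rank(X, scale)
    if n_components is None:
        k = max(1, min(p, n - 2, rank))
    else:
        k = int(n_components)
        if k < 1 or k > min(p, n - 1):
            raise RegressionError(
                f"n_components={k} outside 1..min(p, n-1)={min(p, n - 1)}"
            )
        if k > rank:
            raise RegressionError(
                f"n_components={k} exceeds column rank {rank}"
            )

    pls = PLSRegression(n_components=k, scale=scale)
    pls.fit(X[:, active], y.reshape(-1, 1))
    coef = np.zeros(p)
    coef[active] = np.asarray(pls.coef_).ravel()
    x_mean = X.mean(axis=0)
    # sklearn's predict() centres X first; fold that into a plain intercept
    intercept = float(
        np.asarray(pls.intercept_).ravel()[0] - x_mean[active] @ coef[active]
    )
    return RegressionModel(
        intercept=intercept,
        coefficients=coef,
        n_components=k,
        training_ids=ids,
        x_mean=x_mean,
        x_std=_full_std(np.asarray(pls._x_std, dtype=float), active, p),
        scaled=scale,
    )


def _full_std(active_std: np.ndarray, active: np.ndarray, p: int) -> np.ndarray:
    out = np.ones(p)
    out[active] = active_std
    return out


def predict(model: RegressionModel, t) -> float:
    """Predicted binding free energy (kJ/mol) for one term vector."""
    if isinstance(t, TermVector):
        x = t.as_array()
    else:
        x = np.asarray(t, dtype=float).ravel()
    return float(model.intercept + np.dot(model.coefficients, x))


def loocv(
    X, y, n_components: int | None = None,
    scale: bool = True, ids: list | None = None,
) -> CVResult:
    """Leave-one-out cross-validation by explicit refitting.

    For each row i the model is refit on the remaining n-1 rows and row i
    is predicted; q2 = 1 - PRESS/SS_tot and S_press = sqrt(PRESS/n).
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 4:
        raise RegressionError("LOOCV requires at least 4 rows")
    if np.ptp(y) == 0:
        raise RegressionError("q2 undefined for zero-variance y")
    ids = list(ids) if ids is not None else list(range(n))

    if n_components is None:
        k = max(1, min(p, n - 2))
    else:
        k = int(n_components)

    preds = {}
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train, y_train = X[mask], y[mask]
        k_fold = k
        if n_components is None:
            k_fold = max(1, min(k, _effective_rank(X_train, scale)))
        model = fit_pls(X_train, y_train, n_components=k_fold, scale=scale)
        y_hat = predict(model, X[i])
        preds[ids[i]] = y_hat
        press += (y[i] - y_hat) ** 2

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return CVResult(
        q2=1.0 - press / ss_tot,
        s_press=float(np.sqrt(press / n)),
        per_fold_predictions=preds,
        n=n,
    )


def select_components(
    X, y, max_components: int | None = None, scale: bool = True,
) -> tuple[int, dict[int, CVResult]]:
    """Pick the component count with minimal PRESS under LOOCV."""
    X = _as_matrix(X)
    n, p = X.shape
    upper = min(p, n - 2) if max_components is None else max_components
    results = {}
    for k in range(1, max(upper, 1) + 1):
        try:
            results[k] = loocv(X, y, n_components=k, scale=scale)
        except RegressionError:
            continue
    if not results:
        raise RegressionError("no admissible component count")
    best = min(results, key=lambda k: results[k].s_press)
    return best, results
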