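"""Regression models: OLS multiple linear regression and RBF ε-SVR.

Both models follow the model/results idiom: a model object is constructed
from data (``from_table`` binds a :class:`~qsarforge.table.DescriptorTable`
and a descriptor subset), ``fit`` returns a results object carrying the
estimates, their uncertainties and diagnostics, and ``summary()`` renders a
report. The MLR results expose the fitted equation in the conventional
QSAR layout, ``pIC50 = b0 (± se) + b1 (± se) X1 + ...``.

The SVR is an ε-insensitive support vector regression with a radial basis
kernel; descriptors and activity are autoscaled on the training set (RBF
kernels need commensurate scales) and predictions are back-transformed to
the pIC50 scale. Hyperparameters (C, ε, γ) are tuned by minimizing the
leave-one-out cross-validated RMSE over a grid.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.svm import SVR as _SkSVR

from .exceptions import ConfigurationError, SingularFitError, TableError
from .table import DescriptorTable

# default LOO-RMSE tuning grid; includes the (C, eps, gamma) = (50, 0.01, 5)
# optimum commonly reported for small descriptor subsets
DEFAULT_SVR_GRID = {
    "C": (1.0, 10.0, 50.0, 100.0),
    "epsilon": (0.001, 0.01, 0.1),
    "gamma": (0.1, 1.0, 5.0, 10.0),
}


def _as_xy(table: DescriptorTable, subset: Sequence[str] | None):
    sub = table if subset is None else table.select_descriptors(subset)
    if sub.activity is None:
        raise TableError("model fitting requires an activity vector")
    return sub.X, sub.y, sub.descriptor_names


# ---------------------------------------------------------------------------
# MLR
# ---------------------------------------------------------------------------

class MLR:
    """Ordinary least squares on a descriptor subset, with an intercept."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 descriptor_names: Sequence[str] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise TableError("X must be 2-D with rows matching y")
        self.descriptor_names = (list(descriptor_names) if descriptor_names
                                 else [f"x{j + 1}" for j in range(self.X.shape[1])])

    @classmethod
    def from_table(cls, table: DescriptorTable,
                   subset: Sequence[str] | None = None) -> "MLR":
        X, y, names = _as_xy(table, subset)
        return cls(y, X, names)

    def fit(self) -> "MLRResults":
        n, p = self.X.shape
        if n <= p + 1:
            raise SingularFitError(f"need n > p + 1 (got n={n}, p={p})")
        design = sm.add_constant(self.X, has_constant="add")
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SingularFitError("design matrix is rank deficient")
        res = sm.OLS(self.y, design).fit()
        return MLRResults(model=self, _sm_results=res)


@dataclass
class MLRResults:
    """OLS estimates with standard errors and fit diagnostics."""

    model: MLR
    _sm_results: object = field(repr=False)

    @property
    def intercept(self) -> float:
        return float(self._sm_results.params[0])

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(np.asarray(self._sm_results.params[1:]),
                         index=self.model.descriptor_names)

    @property
    def std_errors(self) -> pd.Series:
        """Standard errors, intercept first."""
        return pd.Series(np.asarray(self._sm_results.bse),
                         index=["intercept"] + self.model.descriptor_names)

    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._sm_results.params),
                         index=["intercept"] + self.model.descriptor_names)

    @property
    def nobs(self) -> int:
        return int(self._sm_results.nobs)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._sm_results.fittedvalues)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._sm_results.resid)

    @property
    def rsquared(self) -> float:
        return float(self._sm_results.rsquared)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid ** 2)))

    @property
    def resid_sd(self) -> float:
        """Regression standard error sqrt(RSS / (n - p - 1))."""
        return float(np.sqrt(self._sm_results.mse_resid))

    def predict(self, data) -> np.ndarray:
        X = self._query_matrix(data)
        return self.intercept + X @ self.coefficients.to_numpy()

    def _query_matrix(self, data) -> np.ndarray:
        if isinstance(data, DescriptorTable):
            return data.select_descriptors(self.model.descriptor_names).X
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.model.descriptor_names):
            raise TableError("query width does not match the fitted subset")
        return X

    def equation(self, activity_name: str = "pIC50", digits: int = 3) -> str:
        """Render ``pIC50 = b0 (± se0) + b1 (± se1) NAME + ...``."""
        se = self.std_errors
        parts = [f"{activity_name} = {self.intercept:.{digits}f} (± {se.iloc[0]:.{digits}f})"]
        for name, b in self.coefficients.items():
            sign = "+" if b >= 0 else "-"
            parts.append(f"{sign} {abs(b):.{digits}f} (± {se[name]:.{digits}f}) {name}")
        return " ".join(parts)

    def summary(self) -> str:
        lines = [
            "Multiple linear regression (OLS)",
            f"  n = {self.nobs}, descriptors = {len(self.model.descriptor_names)}",
            f"  R² = {self.rsquared:.4f}, RMSE = {self.rmse:.4f}",
            "  " + self.equation(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "mlr",
            "descriptor_names": self.model.descriptor_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients.to_dict(),
            "std_errors": self.std_errors.to_dict(),
            "n_train": self.nobs,
            "r2": self.rsquared,
            "rmse": self.rmse,
        }


def fit_mlr(table: DescriptorTable, subset: Sequence[str] | None = None) -> MLRResults:
    """Convenience wrapper: build and fit an :class:`MLR` in one call."""
    return MLR.from_table(table, subset).fit()


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

@dataclass
class SvrConfig:
    """RBF ε-SVR hyperparameters."""

    C: float = 50.0
    epsilon: float = 0.01
    gamma: float = 5.0

    def validate(self) -> None:
        if self.C <= 0 or self.gamma <= 0 or self.epsilon < 0:
            raise ConfigurationError("require C > 0, gamma > 0, epsilon >= 0")


class RBFSVR:
    """ε-SVR with a radial basis kernel on autoscaled descriptors."""

    def __init__(self, y: np.ndarray, X: np.ndarray,
                 descriptor_names: Sequence[str] | None = None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise TableError("X must be 2-D with rows matching y")
        self.descriptor_names = (list(descriptor_names) if descriptor_names
                                 else [f"x{j + 1}" for j in range(self.X.shape[1])])
        self._x_mean = self.X.mean(axis=0)
        sd = self.X.std(axis=0, ddof=0)
        self._x_sd = np.where(sd == 0.0, 1.0, sd)
        self._y_mean = float(self.y.mean())
        y_sd = float(self.y.std(ddof=0))
        self._y_sd = y_sd if y_sd > 0 else 1.0

    @classmethod
    def from_table(cls, table: DescriptorTable,
                   subset: Sequence[str] | None = None) -> "RBFSVR":
        X, y, names = _as_xy(table, subset)
        return cls(y, X, names)

    # scaling -------------------------------------------------------------

    def _scale_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self._x_mean) / self._x_sd

    def _scale_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self._y_mean) / self._y_sd

    def _unscale_y(self, z: np.ndarray) -> np.ndarray:
        return z * self._y_sd + self._y_mean

    # fitting -------------------------------------------------------------

    def fit(self, config: SvrConfig | None = None) -> "SVRResults":
        config = config or SvrConfig()
        config.validate()
        est = self._fit_estimator(self._scale_x(self.X), self._scale_y(self.y), config)
        return SVRResults(model=self, config=config, _estimator=est)

    @staticmethod
    def _fit_estimator(Xs, ys, config: SvrConfig) -> _SkSVR:
        est = _SkSVR(kernel="rbf", C=config.C, epsilon=config.epsilon,
                     gamma=config.gamma, tol=1e-8)
        est.fit(Xs, ys)
        return est

    def loo_rmse(self, config: SvrConfig) -> float:
        """Leave-one-out RMSE on the pIC50 scale for one hyperparameter triple."""
        Xs, ys = self._scale_x(self.X), self._scale_y(self.y)
        n = len(ys)
        errors = np.empty(n)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            est = self._fit_estimator(Xs[mask], ys[mask], config)
            pred = self._unscale_y(est.predict(Xs[i:i + 1]))[0]
            errors[i] = self.y[i] - pred
        return float(np.sqrt(np.mean(errors ** 2)))

    def tune_and_fit(self, grid: dict | None = None) -> "SVRResults":
        """Grid search by LOO-RMSE, then refit on all training rows.

        Ties are broken toward the smallest C, then smallest γ, then
        smallest ε, so the search is deterministic.
        """
        grid = dict(DEFAULT_SVR_GRID) if grid is None else dict(grid)
        triples = [SvrConfig(C=c, epsilon=e, gamma=g)
                   for c, e, g in itertools.product(
                       grid.get("C", DEFAULT_SVR_GRID["C"]),
                       grid.get("epsilon", DEFAULT_SVR_GRID["epsilon"]),
                       grid.get("gamma", DEFAULT_SVR_GRID["gamma"]))]
        if not triples:
            raise ConfigurationError("empty hyperparameter grid")
        scored = [(self.loo_rmse(cfg), cfg.C, cfg.gamma, cfg.epsilon, cfg)
                  for cfg in triples]
        scored.sort(key=lambda t: t[:4])
        best_rmse, *_, best_cfg = scored[0]
        results = self.fit(best_cfg)
        results.loo_rmse_ = best_rmse
        results.search_ = [
            {"C": c.C, "epsilon": c.epsilon, "gamma": c.gamma, "loo_rmse": r}
            for r, _, _, _, c in scored
        ]
        return results


@dataclass
class SVRResults:
    """Fitted ε-SVR with training-set scaling baked into prediction."""

    model: RBFSVR
    config: SvrConfig
    _estimator: object = field(repr=False)
    loo_rmse_: float | None = None
    search_: list | None = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def rsquared(self) -> float:
        y = self.model.y
        ss_res = float(np.sum(self.resid ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    @property
    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid ** 2)))

    @property
    def n_support(self) -> int:
        return int(len(self._estimator.support_))

    def predict(self, data) -> np.ndarray:
        if isinstance(data, DescriptorTable):
            X = data.select_descriptors(self.model.descriptor_names).X
        else:
            X = np.asarray(data, dtype=float)
            if X.ndim == 1:
                X = X[None, :]
        return self.model._unscale_y(self._estimator.predict(self.model._scale_x(X)))

    def summary(self) -> str:
        lines = [
            "ε-support vector regression (RBF kernel)",
            f"  n = {len(self.model.y)}, descriptors = {len(self.model.descriptor_names)}",
            f"  C = {self.config.C:g}, ε = {self.config.epsilon:g}, γ = {self.config.gamma:g}",
            f"  support vectors = {self.n_support}",
            f"  R² = {self.rsquared:.4f}, RMSE = {self.rmse:.4f}",
        ]
        if self.loo_rmse_ is not None:
            lines.append(f"  LOO-RMSE at optimum = {self.loo_rmse_:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": "svr",
            "descriptor_names": self.model.descriptor_names,
            "C": self.config.C,
            "epsilon": self.config.epsilon,
            "gamma": self.config.gamma,
            "n_support": self.n_support,
            "scaling": {
                "x_mean": self.model._x_mean.tolist(),
                "x_sd": self.model._x_sd.tolist(),
                "y_mean": self.model._y_mean,
                "y_sd": self.model._y_sd,
            },
            "r2": self.rsquared,
            "rmse": self.rmse,
            "loo_rmse": self.loo_rmse_,
        }


def tune_and_fit_svr(table: DescriptorTable, subset: Sequence[str] | None = None,
                     grid: dict | None = None) -> SVRResults:
    """Convenience wrapper: build, tune and fit an :class:`RBFSVR`."""
    return RBFSVR.from_table(table, subset).tune_and_fit(grid)


def save_model(results, path) -> None:
    with open(path, "w") as fh:
        json.dump(results.to_dict(), fh, indent=2, sort_keys=True)
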