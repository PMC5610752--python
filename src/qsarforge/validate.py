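"""Model-quality statistics: fit metrics, cross-validation, randomization
tests, external-prediction criteria and collinearity diagnostics.

The battery mirrors standard QSAR practice:

* fit metrics R², RMSE, Fisher F and adjusted R²;
* leave-one-out cross-validation, Q²_LOO = 1 − PRESS/SS_tot;
* bootstrap Q² from out-of-bag predictions (pooled estimator);
* Y-randomization (response scrambling) to detect chance correlation;
* Lin's concordance correlation coefficient (CCC);
* Roy's modified R² (rm²) and the Golbraikh–Tropsha acceptance conditions
  for external predictivity;
* variance inflation factors from the descriptor correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SingularFitError, UndefinedStatisticError
from .table import DescriptorTable

ModelFactory = Callable[[np.ndarray, np.ndarray], object]


def ols_factory(X: np.ndarray, y: np.ndarray):
    """Default model factory: OLS with intercept (lazy import avoids cycles)."""
    from .models import MLR

    return MLR(y, X).fit()


def svr_factory(config=None) -> ModelFactory:
    """Model factory producing an RBF ε-SVR at fixed hyperparameters."""
    from .models import RBFSVR, SvrConfig

    cfg = config or SvrConfig()

    def factory(X: np.ndarray, y: np.ndarray):
        return RBFSVR(y, X).fit(cfg)

    return factory


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def coefficient_of_determination(observed, predicted) -> float:
    """R² = 1 − SS_res/SS_tot (can be negative for bad predictions)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("observed values have zero variance")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def squared_correlation(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.std() == 0.0 or pred.std() == 0.0:
        raise UndefinedStatisticError("zero variance in observed or predicted")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def rmse(observed, predicted) -> float:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise UndefinedStatisticError("adjusted R² needs n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def f_statistic(r2: float, n: int, p: int) -> float:
    """Fisher F = (R²/p) / ((1 − R²)/(n − p − 1))."""
    if n <= p + 1:
        raise UndefinedStatisticError("F statistic needs n > p + 1")
    if r2 >= 1.0:
        return float("inf")
    return (r2 / p) / ((1.0 - r2) / (n - p - 1))


@dataclass
class FitMetrics:
    r2: float
    rmse: float
    f_stat: float
    r2_adj: float


def fit_metrics(observed, predicted, n_params: int) -> FitMetrics:
    """R², RMSE, F and adjusted R² for a model with ``n_params`` descriptors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred):
        raise UndefinedStatisticError("observed/predicted length mismatch")
    r2 = coefficient_of_determination(obs, pred)
    n = len(obs)
    return FitMetrics(
        r2=r2,
        rmse=rmse(obs, pred),
        f_stat=f_statistic(r2, n, n_params),
        r2_adj=adjusted_r2(r2, n, n_params),
    )


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def press_loo_ols(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS PRESS and Q²_LOO via the hat-matrix identity.

    For OLS the deleted residual is e_i/(1 − h_i); this avoids n explicit
    refits and is the fast path used inside the GA fitness loop.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(design)
    if np.abs(np.diag(r)).min() < 1e-10 * max(1.0, np.abs(np.diag(r)).max()):
        raise SingularFitError("design matrix is rank deficient")
    h = np.einsum("ij,ij->i", q, q)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - design @ beta
    denom = 1.0 - h
    if np.any(denom <= 1e-12):
        raise SingularFitError("leverage of 1 encountered; LOO undefined")
    press = float(np.sum((resid / denom) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("activity has zero variance")
    return press, 1.0 - press / ss_tot


def q2_loo(table: DescriptorTable, subset: Sequence[str] | None = None,
           model_factory: ModelFactory = ols_factory) -> tuple[float, float]:
    """Leave-one-out Q² and PRESS by explicit refitting.

    One compound is removed at a time, the model refitted on the remainder
    and the held-out compound predicted; PRESS sums the squared deleted
    errors and Q² = 1 − PRESS/SS_tot with SS_tot about the full-set mean.
    Returns ``(q2, press)``.
    """
    sub = table if subset is None else table.select_descriptors(subset)
    X, y = sub.X, sub.y
    n = len(y)
    if n < X.shape[1] + 3:
        raise UndefinedStatisticError("too few compounds for LOO validation")
    deleted = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            fitted = model_factory(X[mask], y[mask])
        except SingularFitError as exc:
            raise SingularFitError(f"singular refit in LOO fold {i}") from exc
        deleted[i] = np.asarray(fitted.predict(X[i:i + 1]))[0]
    press = float(np.sum((y - deleted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("activity has zero variance")
    return 1.0 - press / ss_tot, press


def q2_bootstrap(table: DescriptorTable, subset: Sequence[str] | None = None,
                 model_factory: ModelFactory = ols_factory,
                 n_boot: int = 5000, seed: int = 0) -> float:
    """Bootstrap Q² from pooled out-of-bag predictions.

    Each replicate resamples training rows with replacement, refits, and
    predicts the out-of-bag rows; Q²_BOOT pools squared errors and squared
    deviations from each replicate's resample mean across all replicates.
    Replicates with an empty out-of-bag set are redrawn.
    """
    if n_boot < 1:
        raise UndefinedStatisticError("n_boot must be >= 1")
    sub = table if subset is None else table.select_descriptors(subset)
    X, y = sub.X, sub.y
    n = len(y)
    rng = np.random.default_rng(seed)
    num = 0.0
    den = 0.0
    done = 0
    guard = 0
    while done < n_boot:
        guard += 1
        if guard > 50 * n_boot:
            raise UndefinedStatisticError("bootstrap failed to draw usable resamples")
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        try:
            fitted = model_factory(X[idx], y[idx])
        except SingularFitError:
            continue
        pred = np.asarray(fitted.predict(X[oob]))
        num += float(np.sum((y[oob] - pred) ** 2))
        den += float(np.sum((y[oob] - y[idx].mean()) ** 2))
        done += 1
    if den == 0.0:
        raise UndefinedStatisticError("bootstrap denominator is zero")
    return 1.0 - num / den


def y_randomization(table: DescriptorTable, subset: Sequence[str] | None = None,
                    model_factory: ModelFactory = ols_factory,
                    n_iter: int = 10, seed: int = 0) -> list[tuple[float, float]]:
    """Response-scrambling test: refit after permuting the activity.

    Returns ``n_iter`` pairs ``(r2, q2_loo)`` of the scrambled refits. A
    robust model shows scrambled R²/Q² far below the unscrambled values.
    """
    if n_iter < 1:
        raise UndefinedStatisticError("n_iter must be >= 1")
    sub = table if subset is None else table.select_descriptors(subset)
    X, y = sub.X, sub.y
    rng = np.random.default_rng(seed)
    out: list[tuple[float, float]] = []
    for _ in range(n_iter):
        y_perm = rng.permutation(y)
        fitted = model_factory(X, y_perm)
        r2 = coefficient_of_determination(y_perm, np.asarray(fitted.predict(X)))
        shuffled = DescriptorTable(sub.data, pd.Series(y_perm, index=sub.data.index))
        q2, _ = q2_loo(shuffled, None, model_factory)
        out.append((r2, q2))
    return out


# ---------------------------------------------------------------------------
# external-prediction criteria
# ---------------------------------------------------------------------------

def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient (biased 1/n moments).

    CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²); equals 1 only for identity
    agreement, penalizing both scale and location shifts.
    """
    x = np.asarray(observed, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if len(x) < 2:
        raise UndefinedStatisticError("CCC needs at least 2 observations")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0.0:
        raise UndefinedStatisticError("CCC undefined: both vectors constant")
    return 2.0 * sxy / denom


def origin_slope(x, y) -> float:
    """Least-squares slope of ``y = k·x`` through the origin: Σxy/Σx²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise UndefinedStatisticError("origin regression undefined: Σx² = 0")
    return float(np.sum(x * y)) / sxx


def origin_r2(x, y) -> float:
    """Determination coefficient of the origin-constrained fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = origin_slope(x, y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("origin R² undefined: y has zero variance")
    return 1.0 - float(np.sum((y - k * x) ** 2)) / ss_tot


def rm2(observed, predicted, predicted_on_y: bool = True) -> float:
    """Roy's modified R²: rm² = r²·(1 − √(r² − r0²)).

    ``r²`` is the squared Pearson correlation; ``r0²`` the origin-constrained
    determination coefficient with predicted values on the y axis by default
    (set ``predicted_on_y=False`` for the transposed convention). The
    difference r² − r0² is floored at 0 before the square root.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) < 3:
        raise UndefinedStatisticError("rm² needs at least 3 observations")
    r2 = squared_correlation(obs, pred)
    r0 = origin_r2(obs, pred) if predicted_on_y else origin_r2(pred, obs)
    return r2 * (1.0 - np.sqrt(max(r2 - r0, 0.0)))


@dataclass
class GTReport:
    """Golbraikh–Tropsha external-validation conditions I–IV."""

    q2: float
    r2: float
    k: float
    k_prime: float
    r0_2: float
    r0_prime_2: float
    condition_1: bool
    condition_2: bool
    condition_3: bool
    condition_4: bool

    @property
    def all_passed(self) -> bool:
        return (self.condition_1 and self.condition_2
                and self.condition_3 and self.condition_4)

    def to_dict(self) -> dict:
        return {
            "q2": self.q2, "r2": self.r2,
            "k": self.k, "k_prime": self.k_prime,
            "r0_2": self.r0_2, "r0_prime_2": self.r0_prime_2,
            "condition_1": self.condition_1, "condition_2": self.condition_2,
            "condition_3": self.condition_3, "condition_4": self.condition_4,
            "all_passed": self.all_passed,
        }

    def summary(self) -> str:
        fmt = lambda ok: "Passed" if ok else "FAILED"  # noqa: E731
        return "\n".join([
            "Golbraikh–Tropsha conditions",
            f"  I   Q² = {self.q2:.3f} > 0.5          {fmt(self.condition_1)}",
            f"  II  R² = {self.r2:.3f} > 0.6          {fmt(self.condition_2)}",
            f"  III k = {self.k:.3f}, k' = {self.k_prime:.3f}, "
            f"(R²−R0²)/R² = {(self.r2 - self.r0_2) / self.r2:.3f}  {fmt(self.condition_3)}",
            f"  IV  |R0² − R0'²| = {abs(self.r0_2 - self.r0_prime_2):.4f} < 0.3  "
            f"{fmt(self.condition_4)}",
        ])


def golbraikh_tropsha(observed_test, predicted_test, q2_loo_value: float,
                      r2_test: float | None = None) -> GTReport:
    """Evaluate the Golbraikh–Tropsha acceptance conditions on a test set.

    Conditions: (I) Q²_LOO > 0.5; (II) R² > 0.6; (III) one of the
    origin-constrained fits is close to identity, (R² − R0²)/R² < 0.1 with
    0.85 < k < 1.15 or the primed variant; (IV) |R0² − R0'²| < 0.3.
    Slopes: k for observed regressed on predicted through the origin,
    k' for predicted regressed on observed.
    """
    obs = np.asarray(observed_test, dtype=float)
    pred = np.asarray(predicted_test, dtype=float)
    if len(obs) < 3:
        raise UndefinedStatisticError("GT conditions need at least 3 test compounds")
    r2 = squared_correlation(obs, pred) if r2_test is None else float(r2_test)
    k = origin_slope(pred, obs)
    k_prime = origin_slope(obs, pred)
    r0_2 = origin_r2(pred, obs)
    r0_prime_2 = origin_r2(obs, pred)
    cond3_plain = (r2 - r0_2) / r2 < 0.1 and 0.85 < k < 1.15
    cond3_primed = (r2 - r0_prime_2) / r2 < 0.1 and 0.85 < k_prime < 1.15
    return GTReport(
        q2=float(q2_loo_value), r2=r2, k=k, k_prime=k_prime,
        r0_2=r0_2, r0_prime_2=r0_prime_2,
        condition_1=q2_loo_value > 0.5,
        condition_2=r2 > 0.6,
        condition_3=bool(cond3_plain or cond3_primed),
        condition_4=bool(abs(r0_2 - r0_prime_2) < 0.3),
    )


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------

def vif_from_correlation(corr_matrix, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors from a descriptor correlation matrix.

    The lower triangle is mirrored first (printed matrices usually show only
    one triangle); VIF_i = 1/(1 − R_i²) is read off the diagonal of the
    inverse correlation matrix.
    """
    A = np.asarray(corr_matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise UndefinedStatisticError("correlation matrix must be square")
    L = np.tril(A, k=-1)
    C = L + L.T + np.diag(np.diag(A))
    if not np.allclose(np.diag(C), 1.0, atol=1e-8):
        raise UndefinedStatisticError("correlation matrix diagonal must be 1")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError("correlation matrix is not positive definite") from exc
    vif = np.diag(np.linalg.inv(C))
    idx = list(names) if names is not None else list(range(len(vif)))
    return pd.Series(vif, index=idx, name="VIF")


def vif(table: DescriptorTable, subset: Sequence[str] | None = None) -> pd.Series:
    """VIFs of a descriptor subset computed from its sample correlations."""
    sub = table if subset is None else table.select_descriptors(subset)
    corr = np.corrcoef(sub.X, rowvar=False)
    return vif_from_correlation(corr, sub.descriptor_names)


# ---------------------------------------------------------------------------
# consolidated report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Full statistics battery for one fitted model."""

    train: FitMetrics
    q2_loo: float
    press: float
    q2_boot: float | None = None
    y_randomization: list[tuple[float, float]] = field(default_factory=list)
    test: FitMetrics | None = None
    test_r2_pearson: float | None = None
    ccc_train: float | None = None
    ccc_test: float | None = None
    rm2_test: float | None = None
    gt: GTReport | None = None
    vif: pd.Series | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        out = {
            "train": vars(self.train),
            "q2_loo": self.q2_loo,
            "press": self.press,
            "q2_boot": self.q2_boot,
            "y_randomization": [{"r2": r, "q2": q} for r, q in self.y_randomization],
            "ccc_train": self.ccc_train,
            "seed": self.seed,
        }
        if self.test is not None:
            out["test"] = vars(self.test)
        if self.test_r2_pearson is not None:
            out["test_r2_pearson"] = self.test_r2_pearson
        if self.ccc_test is not None:
            out["ccc_test"] = self.ccc_test
        if self.rm2_test is not None:
            out["rm2_test"] = self.rm2_test
        if self.gt is not None:
            out["golbraikh_tropsha"] = self.gt.to_dict()
        if self.vif is not None:
            out["vif"] = self.vif.to_dict()
        return out

    def summary(self) -> str:
        lines = [
            "Validation report",
            f"  training: R² = {self.train.r2:.3f}, RMSE = {self.train.rmse:.3f}, "
            f"F = {self.train.f_stat:.3f}, R²_adj = {self.train.r2_adj:.3f}",
            f"  Q²_LOO = {self.q2_loo:.3f} (PRESS = {self.press:.3f})",
        ]
        if self.q2_boot is not None:
            lines.append(f"  Q²_BOOT = {self.q2_boot:.3f}")
        if self.ccc_train is not None:
            lines.append(f"  CCC(train) = {self.ccc_train:.4f}")
        if self.y_randomization:
            max_r2 = max(r for r, _ in self.y_randomization)
            lines.append(
                f"  Y-randomization ({len(self.y_randomization)} shuffles): "
                f"max R² = {max_r2:.3f}")
        if self.test is not None:
            lines.append(
                f"  test: R² = {self.test.r2:.3f}, RMSE = {self.test.rmse:.3f}")
        if self.rm2_test is not None:
            lines.append(f"  rm²(test) = {self.rm2_test:.3f}")
        if self.ccc_test is not None:
            lines.append(f"  CCC(test) = {self.ccc_test:.4f}")
        if self.gt is not None:
            lines.append(self.gt.summary())
        if self.vif is not None:
            lines.append("  VIF: " + ", ".join(
                f"{k}={v:.3f}" for k, v in self.vif.items()))
        return "\n".join(lines)


def validate_model(results, train_table: DescriptorTable,
                   test_table: DescriptorTable | None = None,
                   model_factory: ModelFactory | None = None,
                   n_boot: int = 5000, n_yrand: int = 10,
                   seed: int = 0, compute_vif: bool = True) -> ValidationReport:
    """Run the full battery for a fitted MLR/SVR results object.

    ``results`` must expose ``model.descriptor_names`` and ``predict``;
    ``model_factory`` (used for LOO, bootstrap and Y-randomization) defaults
    to OLS for MLR results and a fixed-hyperparameter SVR for SVR results.
    """
    from .models import MLRResults, SVRResults

    subset = list(results.model.descriptor_names)
    p = len(subset)
    if model_factory is None:
        if isinstance(results, SVRResults):
            model_factory = svr_factory(results.config)
        elif isinstance(results, MLRResults):
            model_factory = ols_factory
        else:
            raise UndefinedStatisticError("cannot infer a model factory")

    train_sub = train_table.select_descriptors(subset)
    y_train = train_sub.y
    pred_train = np.asarray(results.predict(train_sub))
    train_stats = fit_metrics(y_train, pred_train, p)
    q2, press = q2_loo(train_sub, None, model_factory)
    q2b = q2_bootstrap(train_sub, None, model_factory, n_boot=n_boot, seed=seed)
    yrand = y_randomization(train_sub, None, model_factory, n_iter=n_yrand,
                            seed=seed + 1)

    report = ValidationReport(
        train=train_stats, q2_loo=q2, press=press, q2_boot=q2b,
        y_randomization=yrand, ccc_train=ccc(y_train, pred_train), seed=seed,
    )
    if compute_vif and p >= 2:
        report.vif = vif(train_sub)

    if test_table is not None:
        test_sub = test_table.select_descriptors(subset)
        y_test = test_sub.y
        pred_test = np.asarray(results.predict(test_sub))
        report.test = FitMetrics(
            r2=coefficient_of_determination(y_test, pred_test),
            rmse=rmse(y_test, pred_test),
            f_stat=float("nan"), r2_adj=float("nan"),
        )
        report.test_r2_pearson = squared_correlation(y_test, pred_test)
        report.ccc_test = ccc(y_test, pred_test)
        report.rm2_test = rm2(y_test, pred_test)
        report.gt = golbraikh_tropsha(y_test, pred_test, q2,
                                      r2_test=report.test_r2_pearson)
    return report
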