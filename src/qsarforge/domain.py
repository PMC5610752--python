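"""Applicability-domain assessment.

Two complementary views of whether a compound lies within the chemical space
a model was trained on:

* **Leverage / Williams plot.** The hat value h_i = x_iᵀ(XᵀX)⁻¹x_i (intercept
  included) measures how far a compound sits from the training-set centroid
  in descriptor space; the warning threshold is h* = 3p′/n with p′ the number
  of model parameters plus one. Standardized residuals beyond ±3 mark
  response outliers; the in-domain region is the square |std resid| ≤ 3,
  h ≤ h*.

* **Euclidean normalized mean distance.** Each compound's mean Euclidean
  distance to all training compounds (self-distance excluded for training
  rows) is min-max normalized over the training set, anchoring training
  scores to [0, 1]; query compounds scoring outside that interval are outside
  the domain.

Descriptors are autoscaled with training statistics before distances are
taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, SingularFitError

RESIDUAL_BOUND = 3.0


@dataclass
class LeverageDomain:
    """Williams-plot quantities for training and optional query compounds."""

    leverages_train: np.ndarray
    std_residuals_train: np.ndarray
    h_star: float
    leverages_query: np.ndarray | None = None
    std_residuals_query: np.ndarray | None = None

    @property
    def leverage_flags_train(self) -> np.ndarray:
        return self.leverages_train > self.h_star

    @property
    def residual_flags_train(self) -> np.ndarray:
        return np.abs(self.std_residuals_train) > RESIDUAL_BOUND

    @property
    def leverage_flags_query(self) -> np.ndarray | None:
        if self.leverages_query is None:
            return None
        return self.leverages_query > self.h_star

    @property
    def residual_flags_query(self) -> np.ndarray | None:
        if self.std_residuals_query is None:
            return None
        return np.abs(self.std_residuals_query) > RESIDUAL_BOUND

    def to_dict(self) -> dict:
        out = {
            "h_star": self.h_star,
            "leverages_train": self.leverages_train.tolist(),
            "std_residuals_train": self.std_residuals_train.tolist(),
            "leverage_flags_train": self.leverage_flags_train.tolist(),
            "residual_flags_train": self.residual_flags_train.tolist(),
        }
        if self.leverages_query is not None:
            out["leverages_query"] = self.leverages_query.tolist()
            out["leverage_flags_query"] = self.leverage_flags_query.tolist()
        if self.std_residuals_query is not None:
            out["std_residuals_query"] = self.std_residuals_query.tolist()
            out["residual_flags_query"] = self.residual_flags_query.tolist()
        return out


@dataclass
class EuclideanDomain:
    """Normalized mean-distance scores; training scores span exactly [0, 1]."""

    scores_train: np.ndarray
    scores_query: np.ndarray | None = None
    d_min: float = 0.0
    d_max: float = 1.0

    @property
    def flags_train(self) -> np.ndarray:
        return (self.scores_train < 0.0) | (self.scores_train > 1.0)

    @property
    def flags_query(self) -> np.ndarray | None:
        if self.scores_query is None:
            return None
        return (self.scores_query < 0.0) | (self.scores_query > 1.0)

    def to_dict(self) -> dict:
        out = {
            "scores_train": self.scores_train.tolist(),
            "flags_train": self.flags_train.tolist(),
            "d_min": self.d_min,
            "d_max": self.d_max,
        }
        if self.scores_query is not None:
            out["scores_query"] = self.scores_query.tolist()
            out["flags_query"] = self.flags_query.tolist()
        return out


@dataclass
class DomainReport:
    """Combined applicability-domain report."""

    leverage: LeverageDomain | None = None
    euclidean: EuclideanDomain | None = None

    def to_dict(self) -> dict:
        out = {}
        if self.leverage is not None:
            out["leverage"] = self.leverage.to_dict()
        if self.euclidean is not None:
            out["euclidean"] = self.euclidean.to_dict()
        return out


def leverage_threshold(n_params_plus_one: int, n_train: int) -> float:
    """Warning leverage h* = 3p′/n (p′ = model parameters + intercept)."""
    if n_train < 1 or n_params_plus_one < 1:
        raise DomainError("h* requires positive p' and n")
    return 3.0 * n_params_plus_one / n_train


def leverage_domain(X_train: np.ndarray,
                    residuals_train: np.ndarray,
                    X_query: np.ndarray | None = None,
                    residuals_query: np.ndarray | None = None,
                    residual_sd: float | None = None) -> LeverageDomain:
    """Hat values, h* threshold and standardized residuals.

    ``X_train``/``X_query`` hold the model's descriptor subset (no intercept
    column; it is added internally). Residuals for both sets are standardized
    by the training residual SD, sqrt(RSS/(n − p′)), unless ``residual_sd``
    is supplied.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    residuals_train = np.asarray(residuals_train, dtype=float)
    n, p = X_train.shape
    p_prime = p + 1
    design = np.column_stack([np.ones(n), X_train])
    gram = design.T @ design
    try:
        gram_inv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError("training normal matrix is singular") from exc

    h_train = np.einsum("ij,jk,ik->i", design, gram_inv, design)
    if residual_sd is None:
        dof = n - p_prime
        if dof <= 0:
            raise DomainError("cannot estimate residual SD: n <= p'")
        residual_sd = float(np.sqrt(np.sum(residuals_train ** 2) / dof))
    if residual_sd == 0.0:
        residual_sd = 1.0  # perfect fit: residuals are all exactly zero

    report = LeverageDomain(
        leverages_train=h_train,
        std_residuals_train=residuals_train / residual_sd,
        h_star=leverage_threshold(p_prime, n),
    )
    if X_query is not None:
        X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
        dq = np.column_stack([np.ones(len(X_query)), X_query])
        report.leverages_query = np.einsum("ij,jk,ik->i", dq, gram_inv, dq)
        if residuals_query is not None:
            report.std_residuals_query = (
                np.asarray(residuals_query, dtype=float) / residual_sd)
    return report


def euclidean_domain(X_train: np.ndarray,
                     X_query: np.ndarray | None = None,
                     autoscale: bool = True) -> EuclideanDomain:
    """Normalized mean Euclidean distance scores.

    Distances are computed on descriptors autoscaled by training statistics
    (pass ``autoscale=False`` for inputs already on a common scale). Training
    scores are anchored to [0, 1] by min-max normalization; query scores
    reuse the training d_min/d_max, so values outside [0, 1] flag compounds
    outside the spanned diversity range.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    n = len(X_train)
    if n < 2:
        raise DomainError("Euclidean domain needs at least 2 training compounds")
    if autoscale:
        mean = X_train.mean(axis=0)
        sd = X_train.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
    else:
        mean = np.zeros(X_train.shape[1])
        sd = np.ones(X_train.shape[1])
    Z = (X_train - mean) / sd

    from scipy.spatial.distance import cdist

    dist = cdist(Z, Z)
    mean_dist = dist.sum(axis=1) / (n - 1)  # self-distance (0) excluded
    d_min, d_max = float(mean_dist.min()), float(mean_dist.max())
    if d_max == d_min:
        raise DomainError("degenerate spread: all mean distances identical")
    scores_train = (mean_dist - d_min) / (d_max - d_min)

    scores_query = None
    if X_query is not None:
        Zq = (np.atleast_2d(np.asarray(X_query, dtype=float)) - mean) / sd
        mean_dist_q = cdist(Zq, Z).mean(axis=1)
        scores_query = (mean_dist_q - d_min) / (d_max - d_min)
    return EuclideanDomain(scores_train=scores_train, scores_query=scores_query,
                           d_min=d_min, d_max=d_max)


def assess_domain(results, train_table, query_table=None) -> DomainReport:
    """Leverage + Euclidean domain for a fitted model and its training table."""
    subset = list(results.model.descriptor_names)
    Xtr = train_table.select_descriptors(subset).X
    resid_train = train_table.select_descriptors(subset).y - np.asarray(
        results.predict(train_table))
    Xq = resid_q = None
    if query_table is not None:
        Xq = query_table.select_descriptors(subset).X
        if query_table.has_activity:
            resid_q = query_table.y - np.asarray(results.predict(query_table))
    return DomainReport(
        leverage=leverage_domain(Xtr, resid_train, Xq, resid_q),
        euclidean=euclidean_domain(Xtr, Xq),
    )


def williams_plot(report: LeverageDomain, ax=None):
    """Render a Williams plot (leverage vs standardized residual)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(report.leverages_train, report.std_residuals_train,
               label="training", color="tab:blue")
    if report.leverages_query is not None and report.std_residuals_query is not None:
        ax.scatter(report.leverages_query, report.std_residuals_query,
                   label="query", color="tab:red", marker="^")
    ax.axvline(report.h_star, linestyle="--", color="grey")
    for bound in (-RESIDUAL_BOUND, RESIDUAL_BOUND):
        ax.axhline(bound, linestyle="--", color="grey")
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    return ax
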