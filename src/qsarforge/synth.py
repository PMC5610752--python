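"""Synthetic descriptor/activity data with planted, recoverable structure.

Real QSAR descriptor matrices (a few dozen compounds against a pool of
hundreds to thousands of computed descriptors) are rarely published alongside
the models fitted to them. This module generates surrogate tables with the
statistical features that matter to the downstream pipeline — constant and
near-constant columns, collinear pairs, and a small informative subset that
generates the activity linearly (optionally with a smooth interaction term) —
so that every stage can be tested against known ground truth.

Descriptor marginals are standard normal, matching the autoscaled form in
which descriptors are consumed downstream. Activity is mapped affinely into a
target pIC50 window (default 4–8, a typical potency span for a congeneric
inhibitor series) before Gaussian noise is added.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .table import DescriptorTable

# x2 = x1 + N(0, s^2) has population correlation 1/sqrt(1+s^2);
# this value targets r ~= 0.95 for planted collinear pairs.
_COLLINEAR_NOISE_SD = math.sqrt(1.0 / 0.95**2 - 1.0)

# mode frequency for near-constant columns; > the 0.95 preprocessing default
_NEAR_CONSTANT_FRACTION = 0.97


@dataclass
class SynthConfig:
    """Parameters of the synthetic descriptor generator.

    Defaults emulate the study conditions the pipeline is designed around:
    ~35 compounds, a large descriptor pool containing constant, near-constant
    and collinear nuisance columns, five informative descriptors, and pIC50
    spanning roughly four log units.
    """

    n_compounds: int = 35
    n_descriptors: int = 200
    k_informative: int = 5
    n_constant: int = 4
    n_near_constant: int = 3
    n_collinear_pairs: int = 3
    noise_sd: float = 0.2
    coefficient_range: tuple[float, float] = (0.5, 2.0)
    activity_range: tuple[float, float] = (4.0, 8.0)
    nonlinear: bool = False
    seed: int = 0

    def validate(self) -> None:
        reserved = (self.k_informative + self.n_constant + self.n_near_constant
                    + 2 * self.n_collinear_pairs)
        if reserved > self.n_descriptors:
            raise ConfigurationError(
                f"planted columns ({reserved}) exceed n_descriptors ({self.n_descriptors})")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_compounds < self.k_informative + 2:
            raise ConfigurationError("n_compounds must be >= k_informative + 2")
        if self.k_informative < 1:
            raise ConfigurationError("k_informative must be >= 1")
        lo, hi = self.coefficient_range
        if not (0 < lo <= hi):
            raise ConfigurationError("coefficient_range must satisfy 0 < lo <= hi")
        lo, hi = self.activity_range
        if not lo < hi:
            raise ConfigurationError("activity_range must be a non-empty interval")


@dataclass
class SynthDataset:
    """A generated table plus the ground truth that produced it."""

    table: DescriptorTable
    true_subset: list[str]
    true_coefficients: dict[str, float]
    true_intercept: float
    noise_sd: float
    config: SynthConfig = field(repr=False)
    nonlinear_term: tuple[str, str, float] | None = None

    def truth_dict(self) -> dict:
        out = {
            "true_subset": self.true_subset,
            "true_coefficients": self.true_coefficients,
            "true_intercept": self.true_intercept,
            "noise_sd": self.noise_sd,
            "seed": self.config.seed,
        }
        if self.nonlinear_term is not None:
            a, b, g = self.nonlinear_term
            out["nonlinear_term"] = {"descriptors": [a, b], "coefficient": g}
        return out

    def save_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth_dict(), fh, indent=2, sort_keys=True)


def generate(config: SynthConfig) -> SynthDataset:
    """Generate a descriptor table with planted structure.

    Column roles (informative, constant, near-constant, collinear pair,
    independent noise) are assigned to a seeded permutation of positions so
    structure is never trivially localized. The same ``SynthConfig``
    reproduces the dataset bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_compounds, config.n_descriptors
    k = config.k_informative

    X = np.empty((n, p))
    order = rng.permutation(p)
    cursor = 0

    def take(count: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor:cursor + count]
        cursor += count
        return idx

    info_idx = take(k)
    const_idx = take(config.n_constant)
    nearconst_idx = take(config.n_near_constant)
    pair_base_idx = take(config.n_collinear_pairs)
    pair_partner_idx = take(config.n_collinear_pairs)
    noise_idx = order[cursor:]

    X[:, info_idx] = rng.standard_normal((n, k))

    for j in const_idx:
        X[:, j] = rng.normal()

    mode_rows = math.ceil(_NEAR_CONSTANT_FRACTION * n)
    for j in nearconst_idx:
        col = rng.standard_normal(n)
        mode_value = rng.normal()
        which = rng.permutation(n)[:mode_rows]
        col[which] = mode_value
        X[:, j] = col

    for jb, jp in zip(pair_base_idx, pair_partner_idx):
        base = rng.standard_normal(n)
        X[:, jb] = base
        X[:, jp] = base + rng.normal(0.0, _COLLINEAR_NOISE_SD, size=n)

    if len(noise_idx):
        X[:, noise_idx] = rng.standard_normal((n, len(noise_idx)))

    # linear signal from the informative block
    lo, hi = config.coefficient_range
    beta_raw = rng.uniform(lo, hi, size=k) * rng.choice([-1.0, 1.0], size=k)
    signal = X[:, info_idx] @ beta_raw

    gamma_raw = 0.0
    if config.nonlinear:
        inter = X[:, info_idx[0]] * X[:, info_idx[min(1, k - 1)]]
        # interaction variance pinned at 20% of the linear signal variance
        target_var = 0.2 * signal.var()
        gamma_raw = math.sqrt(target_var / inter.var()) if inter.var() > 0 else 0.0
        signal = signal + gamma_raw * inter

    a_lo, a_hi = config.activity_range
    span = signal.max() - signal.min()
    if span == 0:
        raise ConfigurationError("degenerate signal: informative block has no spread")
    scale = (a_hi - a_lo) / span
    offset = a_lo - scale * signal.min()
    activity = offset + scale * signal + rng.normal(0.0, config.noise_sd, size=n)

    width = max(4, len(str(p)))
    names = [f"D{j + 1:0{width}d}" for j in range(p)]
    ids = [f"C{i + 1:03d}" for i in range(n)]
    table = DescriptorTable(
        pd.DataFrame(X, index=ids, columns=names),
        pd.Series(activity, index=ids, name="pIC50"),
    )

    true_subset = [names[j] for j in sorted(info_idx)]
    coeff = {names[j]: scale * beta_raw[list(info_idx).index(j)] for j in info_idx}
    coeff = {name: coeff[name] for name in true_subset}
    nonlinear_term = None
    if config.nonlinear:
        nonlinear_term = (names[info_idx[0]], names[info_idx[min(1, k - 1)]],
                          scale * gamma_raw)
    return SynthDataset(
        table=table,
        true_subset=true_subset,
        true_coefficients=coeff,
        true_intercept=offset,
        noise_sd=config.noise_sd,
        config=config,
        nonlinear_term=nonlinear_term,
    )


def config_from_dict(payload: dict) -> SynthConfig:
    allowed = set(SynthConfig.__dataclass_fields__)
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(f"unknown SynthConfig fields: {sorted(unknown)}")
    cfg = SynthConfig(**payload)
    for name in ("coefficient_range", "activity_range"):
        value = getattr(cfg, name)
        setattr(cfg, name, tuple(float(v) for v in value))
    cfg.validate()
    return cfg


def config_to_dict(config: SynthConfig) -> dict:
    out = asdict(config)
    out["coefficient_range"] = list(config.coefficient_range)
    out["activity_range"] = list(config.activity_range)
    return out
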