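"""Descriptor reduction: constant/near-constant removal and collinearity filter.

Two passes are applied to a raw descriptor pool before modelling:

1. columns that are exactly constant, or whose most frequent value occurs in
   at least a given fraction of compounds (default 0.95), are removed;
2. of every pair of descriptors with |Pearson r| above a cutoff (default 0.9),
   the member less correlated with the activity is removed.

Both passes preserve the order of surviving columns and log every decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyTableError, TableError
from .table import DescriptorTable


@dataclass
class ReductionLog:
    """Record of what a reduction pass removed and why."""

    removed_constant: list[str] = field(default_factory=list)
    removed_near_constant: list[str] = field(default_factory=list)
    # (kept, dropped, r_pair, r_y_kept, r_y_dropped)
    collinear_pairs: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    n_before: int = 0
    n_after: int = 0

    @property
    def removed(self) -> list[str]:
        return (self.removed_constant + self.removed_near_constant
                + [dropped for _, dropped, *_ in self.collinear_pairs])

    def to_dict(self) -> dict:
        return {
            "removed_constant": self.removed_constant,
            "removed_near_constant": self.removed_near_constant,
            "collinear_pairs": [
                {"kept": k, "dropped": d, "r": r, "r_y_kept": rk, "r_y_dropped": rd}
                for k, d, r, rk, rd in self.collinear_pairs
            ],
            "n_before": self.n_before,
            "n_after": self.n_after,
        }


def filter_constant(table: DescriptorTable,
                    near_constant_fraction: float = 0.95,
                    ) -> tuple[DescriptorTable, ReductionLog]:
    """Remove constant and near-constant descriptor columns.

    A column is removed when its variance is exactly zero or when its most
    frequent value occurs in at least ``near_constant_fraction`` of rows.
    With ``near_constant_fraction=1.0`` only exactly-constant columns go.
    """
    if not 0.0 < near_constant_fraction <= 1.0:
        raise TableError("near_constant_fraction must be in (0, 1]")
    log = ReductionLog(n_before=table.n_descriptors)
    n = table.n_compounds
    for name in table.descriptor_names:
        col = table.data[name].to_numpy()
        if np.ptp(col) == 0.0:
            log.removed_constant.append(name)
            continue
        _, counts = np.unique(col, return_counts=True)
        if counts.max() / n >= near_constant_fraction:
            log.removed_near_constant.append(name)
    reduced = table.drop_descriptors(log.removed_constant + log.removed_near_constant)
    log.n_after = reduced.n_descriptors
    if log.n_after == 0:
        raise EmptyTableError("constant filter removed every descriptor")
    return reduced, log


def filter_collinear(table: DescriptorTable, r_cut: float = 0.9,
                     ) -> tuple[DescriptorTable, ReductionLog]:
    """Resolve collinear descriptor pairs in favour of activity correlation.

    All pairs with sample |Pearson r| > ``r_cut`` are collected, sorted by
    descending |r| (ties broken by name for determinism) and resolved
    greedily: the member with the larger |r| to the activity is kept, the
    other dropped; pairs touching an already-dropped column are skipped.
    """
    if table.activity is None:
        raise TableError("collinearity filter requires an activity vector")
    if not 0.0 < r_cut < 1.0:
        raise TableError("r_cut must be in (0, 1)")
    log = ReductionLog(n_before=table.n_descriptors)
    names = table.descriptor_names
    if table.n_descriptors >= 2:
        X = table.X
        y = table.y
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(X, rowvar=False)
            r_y = np.array([_safe_corr(X[:, j], y) for j in range(X.shape[1])])
        corr = np.nan_to_num(corr, nan=0.0)
        iu, ju = np.triu_indices(len(names), k=1)
        mask = np.abs(corr[iu, ju]) > r_cut
        pairs = sorted(
            zip(iu[mask], ju[mask]),
            key=lambda ij: (-abs(corr[ij[0], ij[1]]), names[ij[0]], names[ij[1]]),
        )
        dropped: set[int] = set()
        for i, j in pairs:
            if i in dropped or j in dropped:
                continue
            # keep the member better correlated with activity; break exact
            # ties toward the lexicographically smaller name
            if (abs(r_y[i]), names[j]) >= (abs(r_y[j]), names[i]):
                keep, drop = i, j
            else:
                keep, drop = j, i
            dropped.add(drop)
            log.collinear_pairs.append(
                (names[keep], names[drop], float(corr[i, j]),
                 float(r_y[keep]), float(r_y[drop]))
            )
        reduced = table.drop_descriptors([names[j] for j in dropped])
    else:
        reduced = table
    log.n_after = reduced.n_descriptors
    if log.n_after == 0:
        raise EmptyTableError("collinearity filter removed every descriptor")
    return reduced, log


def reduce_descriptors(table: DescriptorTable,
                       near_constant_fraction: float = 0.95,
                       r_cut: float = 0.9,
                       ) -> tuple[DescriptorTable, ReductionLog]:
    """Run both reduction passes and merge their logs."""
    reduced, log1 = filter_constant(table, near_constant_fraction)
    reduced, log2 = filter_collinear(reduced, r_cut)
    merged = ReductionLog(
        removed_constant=log1.removed_constant,
        removed_near_constant=log1.removed_near_constant,
        collinear_pairs=log2.collinear_pairs,
        n_before=log1.n_before,
        n_after=log2.n_after,
    )
    return reduced, merged


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
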