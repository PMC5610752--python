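"""Cluster-based train/test partitioning.

Compounds are clustered hierarchically (Euclidean distance on autoscaled
descriptors) and the test set is drawn with one compound per cluster, so that
it is structurally dispersed, while the compounds carrying the global minimum
and maximum activity are always kept in training so the test activities lie
inside the training range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .exceptions import SplitError, TableError
from .table import DescriptorTable

LINKAGE_METHODS = ("complete", "average", "single", "ward")


@dataclass
class SplitAssignment:
    """A train/test partition of compound labels."""

    train_ids: list
    test_ids: list
    linkage_method: str
    n_clusters_used: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "train_ids": list(self.train_ids),
            "test_ids": list(self.test_ids),
            "linkage_method": self.linkage_method,
            "n_clusters_used": self.n_clusters_used,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "SplitAssignment":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def cluster_dendrogram(table: DescriptorTable,
                       linkage_method: str = "complete") -> np.ndarray:
    """Agglomerative merge tree over compounds.

    Descriptors are autoscaled internally before Euclidean distances are
    taken; the return value is a SciPy linkage matrix with N-1 rows.
    """
    if table.n_compounds < 2:
        raise TableError("clustering requires at least 2 compounds")
    if linkage_method not in LINKAGE_METHODS:
        raise TableError(f"unknown linkage method {linkage_method!r}")
    X = table.autoscaled().X
    return linkage(pdist(X, metric="euclidean"), method=linkage_method)


def make_split(tree: np.ndarray, table: DescriptorTable,
               test_fraction: float = 0.2, seed: int = 0,
               linkage_method: str = "complete",
               max_retries: int = 100) -> SplitAssignment:
    """Draw a train/test split from the cluster tree.

    The tree is cut into as many clusters as there are test compounds
    (``round(test_fraction * n)``), and one test compound is sampled per
    cluster, each from a distinct cluster. The compounds with the global
    minimum and maximum activity are always assigned to training, which
    enforces the range-coverage rule (test activities within the training
    activity range). If those reserved compounds monopolize whole clusters,
    the cut is deepened until enough clusters with eligible members exist;
    ``n_clusters_used`` records the cut actually taken.
    """
    if table.activity is None:
        raise TableError("splitting requires an activity vector")
    if not 0.0 < test_fraction <= 0.5:
        raise SplitError("test_fraction must be in (0, 0.5]")
    n = table.n_compounds
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n - n_test < 2:
        raise SplitError(f"cannot draw {n_test} test compounds from {n}")

    ids = np.asarray(table.compound_ids, dtype=object)
    y = table.y
    forced_train = {int(np.argmin(y)), int(np.argmax(y))}

    # deepen the cut until >= n_test clusters hold a non-reserved compound
    cluster_of = None
    for n_clusters in range(n_test, n + 1):
        labels = fcluster(tree, t=n_clusters, criterion="maxclust")
        eligible = {lab for lab in np.unique(labels)
                    if any(i not in forced_train
                           for i in np.flatnonzero(labels == lab))}
        if len(eligible) >= n_test:
            cluster_of = labels
            break
    if cluster_of is None:
        raise SplitError("not enough selectable clusters for the test set")

    rng = np.random.default_rng(seed)
    eligible = sorted(eligible)
    for _ in range(max_retries):
        picked_clusters = rng.choice(eligible, size=n_test, replace=False)
        chosen = []
        for label in picked_clusters:
            members = [i for i in np.flatnonzero(cluster_of == label)
                       if i not in forced_train]
            chosen.append(int(rng.choice(members)))
        test_idx = sorted(chosen)
        train_idx = [i for i in range(n) if i not in set(test_idx)]
        if _covers_range(y, train_idx, test_idx):
            return SplitAssignment(
                train_ids=list(ids[train_idx]),
                test_ids=list(ids[test_idx]),
                linkage_method=linkage_method,
                n_clusters_used=int(cluster_of.max()),
                seed=seed,
            )
    raise SplitError(
        f"no split satisfying range coverage found in {max_retries} attempts "
        f"(n={n}, n_test={n_test})")


def split_table(table: DescriptorTable, assignment: SplitAssignment,
                ) -> tuple[DescriptorTable, DescriptorTable]:
    return (table.select_compounds(assignment.train_ids),
            table.select_compounds(assignment.test_ids))


def _covers_range(y: np.ndarray, train_idx, test_idx) -> bool:
    train = y[list(train_idx)]
    test = y[list(test_idx)]
    return bool(test.min() >= train.min() and test.max() <= train.max())
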