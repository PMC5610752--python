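"""The descriptor table container shared by every pipeline stage.

A :class:`DescriptorTable` is a thin, validated wrapper around a pandas
DataFrame of molecular descriptors (compounds x descriptors) plus an optional
activity vector (pIC50 = -log10 IC50 [M]). Query-only tables (new compounds
to be predicted) carry no activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import TableError

ACTIVITY_COLUMN = "pIC50"
ID_COLUMN = "compound_id"


@dataclass
class DescriptorTable:
    """Compounds x descriptors matrix with an optional pIC50 vector.

    Parameters
    ----------
    data
        DataFrame of descriptor values; index holds unique compound labels,
        columns hold unique descriptor names. All values must be finite.
    activity
        Optional pIC50 series aligned with ``data.index``.
    """

    data: pd.DataFrame
    activity: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise TableError("duplicate descriptor names")
        if self.data.index.duplicated().any():
            raise TableError("duplicate compound identifiers")
        values = self.data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise TableError("descriptor matrix contains missing or non-finite values")
        if self.activity is not None:
            self.activity = pd.Series(
                np.asarray(self.activity, dtype=float), index=self.data.index,
                name=ACTIVITY_COLUMN,
            ) if not isinstance(self.activity, pd.Series) else self.activity.astype(float)
            if len(self.activity) != len(self.data):
                raise TableError("activity length does not match compound count")
            if not np.isfinite(self.activity.to_numpy()).all():
                raise TableError("activity contains missing or non-finite values")
            if not self.activity.index.equals(self.data.index):
                self.activity = self.activity.reindex(self.data.index)
                if self.activity.isna().any():
                    raise TableError("activity index does not match compound index")

    # -- basic views -----------------------------------------------------

    @property
    def n_compounds(self) -> int:
        return len(self.data)

    @property
    def n_descriptors(self) -> int:
        return self.data.shape[1]

    @property
    def compound_ids(self) -> list:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.activity is None:
            raise TableError("table carries no activity vector")
        return self.activity.to_numpy(dtype=float)

    @property
    def has_activity(self) -> bool:
        return self.activity is not None

    # -- derived tables --------------------------------------------------

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise TableError(f"unknown descriptor names: {missing}")
        return DescriptorTable(self.data.loc[:, list(names)].copy(), self.activity)

    def select_compounds(self, ids: Sequence) -> "DescriptorTable":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise TableError(f"unknown compound ids: {missing}")
        act = self.activity.loc[list(ids)] if self.activity is not None else None
        return DescriptorTable(self.data.loc[list(ids)].copy(), act)

    def drop_descriptors(self, names: Sequence[str]) -> "DescriptorTable":
        keep = [c for c in self.data.columns if c not in set(names)]
        return DescriptorTable(self.data.loc[:, keep].copy(), self.activity)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, activity_column: str = ACTIVITY_COLUMN,
                 id_column: str = ID_COLUMN) -> "DescriptorTable":
        """Load ``compound_id, <descriptors...>[, pIC50]`` CSV."""
        frame = pd.read_csv(path)
        if id_column not in frame.columns:
            raise TableError(f"missing id column {id_column!r}")
        frame = frame.set_index(id_column)
        activity = None
        if activity_column in frame.columns:
            activity = frame.pop(activity_column)
        return cls(frame, activity)

    def to_csv(self, path) -> None:
        frame = self.data.copy()
        if self.activity is not None:
            frame[ACTIVITY_COLUMN] = self.activity
        frame.to_csv(path, index_label=ID_COLUMN)

    def autoscaled(self) -> "DescriptorTable":
        """Zero-mean / unit-variance copy; constant columns map to zero."""
        values = self.X
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        scaled = (values - mean) / sd
        return DescriptorTable(
            pd.DataFrame(scaled, index=self.data.index, columns=self.data.columns),
            self.activity,
        )
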