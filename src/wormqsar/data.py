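"""Core in-memory container: a descriptor matrix with aligned binary labels.

The pipeline's unit of data is a table of compounds (rows) by numeric
molecular descriptors (columns), together with a binary toxicity label per
compound (1 = toxic, 0 = nontoxic). Labels derive from NOEC endpoints via
the curation rules; positive class is *toxic* throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TOXIC = 1
NONTOXIC = 0


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with aligned labels.

    Parameters
    ----------
    X : pandas.DataFrame
        Numeric descriptor values, indexed by compound id.
    y : pandas.Series or None
        Binary labels (1 = toxic) aligned to ``X.index``. ``None`` for
        unlabeled prediction inputs.
    """

    X: pd.DataFrame
    y: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.y is not None:
            self.y = pd.Series(self.y)
            if not self.X.index.equals(self.y.index):
                self.y = self.y.reindex(self.X.index)
                if self.y.isna().any():
                    raise ValueError("labels are not aligned with the descriptor matrix index")
            self.y = self.y.astype(int)

    @property
    def n_compounds(self) -> int:
        return len(self.X)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.X.columns)

    def class_counts(self) -> tuple[int, int]:
        """Return ``(n_toxic, n_nontoxic)``."""
        if self.y is None:
            raise ValueError("no labels attached")
        return int((self.y == TOXIC).sum()), int((self.y == NONTOXIC).sum())

    def select_descriptors(self, names: Sequence[str] | np.ndarray) -> "DescriptorMatrix":
        """Restrict to a subset of descriptors, by names or boolean mask."""
        arr = np.asarray(names)
        if arr.dtype == bool:
            if arr.size != self.X.shape[1]:
                raise ValueError("boolean mask length does not match descriptor count")
            cols = self.X.columns[arr]
        else:
            missing = [c for c in names if c not in self.X.columns]
            if missing:
                raise KeyError(f"descriptors not present: {missing}")
            cols = list(names)
        return DescriptorMatrix(self.X[cols], self.y)

    def subset(self, index: Iterable) -> "DescriptorMatrix":
        idx = pd.Index(index)
        return DescriptorMatrix(self.X.loc[idx], None if self.y is None else self.y.loc[idx])

    def to_csv(self, path: str | Path, label_column: str = "label") -> None:
        df = self.X.copy()
        if self.y is not None:
            df.insert(0, label_column, self.y)
        df.to_csv(path, index_label="compound_id")

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = "label") -> "DescriptorMatrix":
        df = pd.read_csv(path, index_col="compound_id")
        y = None
        if label_column in df.columns:
            y = df.pop(label_column)
        return cls(df, y)


# Stage seeds are derived from a single global seed by hashing stage names,
# so adding a stage does not shift the randomness of the others.
def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit stage seed from a master seed and a stage name."""
    import hashlib

    digest = hashlib.sha256(f"{int(master_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
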