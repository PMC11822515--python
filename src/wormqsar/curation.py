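"""NOEC endpoint curation, data-set splitting, and identity primitives.

A reproductive NOEC (no-observed-effect concentration, mg compound per kg
soil) is converted to a binary class at the 100 mg/kg breakpoint — the
boundary of the least-harmful category recommended by the UN Committee of
Experts. Endpoints arrive either as real values or as interval dialects
(e.g. ``>10-100``); intervals that straddle the breakpoint cannot be
classified and are discarded.

The conversion rules, with ``bp`` = 100 mg/kg:

1. real value < bp            -> toxic
2. real value >= bp           -> nontoxic
3. interval (0, 10]           -> toxic
4. interval (10, 100]         -> discard (contains the breakpoint)
5. interval (100, inf)        -> nontoxic
6. interval [0, 100)          -> toxic
7. interval below-100 ... inf -> discard (spans the breakpoint)

All seven are instances of one containment rule: toxic if the whole
interval lies below ``bp``, nontoxic if it lies at/above ``bp``, discard
otherwise.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .data import NONTOXIC, TOXIC, DescriptorMatrix

DEFAULT_BREAKPOINT = 100.0


class ClassLabel(str, Enum):
    TOXIC = "toxic"
    NONTOXIC = "nontoxic"
    DISCARD = "discard"


class IntervalDialectError(ValueError):
    """Raised when a NOEC string is not in the supported interval grammar."""


@dataclass(frozen=True)
class NOECRecord:
    """One compound's NOEC endpoint: a real value or an interval in mg/kg."""

    compound_id: str
    kind: str  # "real" | "interval"
    value: float | None = None
    lower: float | None = None
    upper: float | None = None
    lower_closed: bool = True
    upper_closed: bool = False

    def __post_init__(self) -> None:
        if self.kind == "real":
            if self.value is None or self.value < 0 or not math.isfinite(self.value):
                raise ValueError(f"{self.compound_id}: real NOEC must be a finite value >= 0")
        elif self.kind == "interval":
            if self.lower is None or self.upper is None:
                raise ValueError(f"{self.compound_id}: interval NOEC needs both bounds")
            if not self.lower < self.upper:
                raise ValueError(
                    f"{self.compound_id}: interval lower bound must be below upper "
                    f"({self.lower!r} vs {self.upper!r})"
                )
        else:
            raise ValueError(f"{self.compound_id}: unknown NOEC kind {self.kind!r}")


_REAL_RE = re.compile(r"^\s*\d+(\.\d+)?([eE][+-]?\d+)?\s*$")
_GT_RE = re.compile(r"^\s*>\s*(\d+(\.\d+)?)\s*$")          # ">100"
_LT_RE = re.compile(r"^\s*<\s*(\d+(\.\d+)?)\s*$")          # "<100"
_RANGE_RE = re.compile(r"^\s*>\s*(\d+(\.\d+)?)\s*-\s*(\d+(\.\d+)?)\s*$")  # ">10-100"
_LTINF_RE = re.compile(r"^\s*<\s*(\d+(\.\d+)?)\s*-\s*inf\s*$", re.IGNORECASE)  # "<100-inf"


def parse_noec(compound_id: str, text: str | float) -> NOECRecord:
    """Parse a NOEC entry from the text grammar used in endpoint tables.

    Supported dialects: a plain real number; ``>A`` (A, inf); ``<A``
    [0, A); ``>A-B`` (A, B]; ``<A-inf`` — a value known only to start below
    A with no upper bound, represented as [0, inf). Intervals may also be
    supplied as explicit dicts ``{lower, upper, lower_closed, upper_closed}``
    via :class:`NOECRecord` directly.
    """
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return NOECRecord(compound_id, "real", value=float(text))
    s = str(text).strip()
    if _REAL_RE.match(s):
        return NOECRecord(compound_id, "real", value=float(s))
    m = _RANGE_RE.match(s)
    if m:
        return NOECRecord(compound_id, "interval", lower=float(m.group(1)),
                          upper=float(m.group(3)), lower_closed=False, upper_closed=True)
    m = _GT_RE.match(s)
    if m:
        return NOECRecord(compound_id, "interval", lower=float(m.group(1)),
                          upper=math.inf, lower_closed=False, upper_closed=False)
    m = _LTINF_RE.match(s)
    if m:
        # Lower end known only to lie below the stated value; unbounded above.
        return NOECRecord(compound_id, "interval", lower=0.0, upper=math.inf,
                          lower_closed=True, upper_closed=False)
    m = _LT_RE.match(s)
    if m:
        return NOECRecord(compound_id, "interval", lower=0.0, upper=float(m.group(1)),
                          lower_closed=True, upper_closed=False)
    raise IntervalDialectError(f"{compound_id}: unsupported NOEC dialect {text!r}")


def assign_class(record: NOECRecord, breakpoint: float = DEFAULT_BREAKPOINT) -> ClassLabel:
    """Map one NOEC record to toxic / nontoxic / discard at the breakpoint."""
    if record.kind == "real":
        return ClassLabel.TOXIC if record.value < breakpoint else ClassLabel.NONTOXIC
    lo, hi = record.lower, record.upper
    entirely_below = hi < breakpoint or (hi == breakpoint and not record.upper_closed)
    entirely_at_or_above = lo >= breakpoint
    if entirely_below:
        return ClassLabel.TOXIC
    if entirely_at_or_above:
        return ClassLabel.NONTOXIC
    return ClassLabel.DISCARD


def labels_from_records(records: list[NOECRecord],
                        breakpoint: float = DEFAULT_BREAKPOINT) -> pd.Series:
    """Binary labels for non-discarded records (index = compound id)."""
    out: dict[str, int] = {}
    for rec in records:
        lab = assign_class(rec, breakpoint)
        if lab is ClassLabel.TOXIC:
            out[rec.compound_id] = TOXIC
        elif lab is ClassLabel.NONTOXIC:
            out[rec.compound_id] = NONTOXIC
    return pd.Series(out, dtype=int)


def split_dataset(matrix: DescriptorMatrix, test_size: int, seed: int,
                  stratified: bool = False) -> tuple[DescriptorMatrix, DescriptorMatrix]:
    """Set aside ``test_size`` compounds as an external test set.

    Unstratified seeded random sampling by default; stratified sampling
    allocates the test set across classes proportionally (largest
    remainders) for synthetic experiments.
    """
    n = matrix.n_compounds
    if not 0 <= test_size < n:
        raise ValueError(f"test_size must be in [0, {n}), got {test_size}")
    rng = np.random.default_rng(seed)
    if stratified and matrix.y is not None and test_size > 0:
        parts = []
        classes = sorted(matrix.y.unique())
        quotas = {}
        fracs = {}
        for c in classes:
            exact = test_size * (matrix.y == c).sum() / n
            quotas[c] = int(np.floor(exact))
            fracs[c] = exact - quotas[c]
        for c in sorted(classes, key=lambda c: -fracs[c]):
            if sum(quotas.values()) < test_size:
                quotas[c] += 1
        for c in classes:
            ids = matrix.y.index[matrix.y == c].to_numpy()
            parts.append(rng.choice(ids, size=quotas[c], replace=False))
        test_ids = pd.Index(np.concatenate(parts))
    else:
        perm = rng.permutation(matrix.X.index.to_numpy())
        test_ids = pd.Index(perm[:test_size])
    modeling_ids = matrix.X.index.difference(test_ids, sort=False)
    return matrix.subset(modeling_ids), matrix.subset(test_ids)


def resample_train_val(modeling_set: DescriptorMatrix, train_fraction: float = 0.8,
                       seed: int = 0) -> tuple[DescriptorMatrix, DescriptorMatrix]:
    """Seeded random 80/20-style split of the modeling pool.

    Train size is ``floor(train_fraction * n)``. Resampled with a fresh seed
    after every GA generation.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = modeling_set.n_compounds
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(modeling_set.X.index.to_numpy())
    train_ids, val_ids = pd.Index(perm[:n_train]), pd.Index(perm[n_train:])
    return modeling_set.subset(train_ids), modeling_set.subset(val_ids)


def under_sample(train: DescriptorMatrix, seed: int) -> DescriptorMatrix:
    """Randomly drop majority-class compounds until classes balance.

    All minority compounds are retained; the majority class is reduced to a
    seeded random subset of the minority size. Equal weighting of the two
    classes is what makes the boosted-tree fits usable on the ~79:21
    imbalanced endpoint data.
    """
    if train.y is None:
        raise ValueError("under_sample requires labels")
    n_tox, n_non = train.class_counts()
    if n_tox == 0 or n_non == 0:
        raise ValueError("cannot balance: one class is absent from the training set")
    rng = np.random.default_rng(seed)
    minority = TOXIC if n_tox <= n_non else NONTOXIC
    n_min = min(n_tox, n_non)
    min_ids = train.y.index[train.y == minority].to_numpy()
    maj_ids = train.y.index[train.y != minority].to_numpy()
    kept_maj = rng.choice(maj_ids, size=n_min, replace=False) if len(maj_ids) > n_min else maj_ids
    keep = train.X.index.intersection(pd.Index(np.concatenate([min_ids, kept_maj])), sort=False)
    return train.subset(keep)


def jaccard_similarity(fp_a, fp_b) -> float:
    """Jaccard index |A & B| / |A | B| between two binary fingerprints."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprints must have equal length")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("similarity undefined: both fingerprints are all-zero")
    return float(np.logical_and(a, b).sum() / union)


def identifiers_coincide(fingerprints: list) -> bool:
    """Identity-curation predicate over per-identifier fingerprints.

    A structure with more than two distinct identifiers is considered valid
    when the circular fingerprints derived from every identifier coincide
    (all pairwise Jaccard indices equal 1).
    """
    if len(fingerprints) <= 2:
        return False
    first = np.asarray(fingerprints[0], dtype=bool)
    return all(
        np.array_equal(first, np.asarray(fp, dtype=bool)) and first.any()
        for fp in fingerprints[1:]
    )
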