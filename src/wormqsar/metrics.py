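"""Classification performance metrics and Y-scrambling validation.

Positive class = toxic throughout. Metrics follow the usual confusion-matrix
definitions; Balanced Accuracy is the mean of Sensitivity and Specificity,
MCC is the Matthews correlation coefficient, and the Brier score is the mean
squared difference between the predicted toxic-class probability and the
0/1 outcome.

Conventions for degenerate counts: Sensitivity (Specificity) is undefined —
reported as ``None`` — when its class is absent; Balanced Accuracy averages
whichever components are defined; MCC is 0 whenever a confusion-matrix
marginal is zero. These keep Y-scrambling and tight applicability-domain
cells numerically stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .curation import resample_train_val, under_sample
from .data import TOXIC, DescriptorMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=pd.Index(["toxic", "nontoxic"], name="true"),
            columns=pd.Index(["toxic", "nontoxic"], name="predicted"),
        )


@dataclass
class MetricReport:
    acc: float
    sens: float | None
    spec: float | None
    balacc: float
    mcc: float
    brier: float | None = None
    coverage: float | None = None
    counts: ConfusionCounts | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in ("acc", "sens", "spec", "balacc", "mcc",
                                           "brier", "coverage")}
        if self.counts is not None:
            d.update(tp=self.counts.tp, tn=self.counts.tn,
                     fp=self.counts.fp, fn=self.counts.fn, total=self.counts.total)
        return d


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Acc, Sens, Spec, BalAcc and MCC from a confusion matrix."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    defined = [v for v in (sens, spec) if v is not None]
    if not defined:
        raise ValueError("both classes absent: no metric is defined")
    balacc = float(np.mean(defined))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricReport(acc=acc, sens=sens, spec=spec, balacc=balacc, mcc=mcc, counts=counts)


def confusion_from_predictions(true_labels, predicted_labels) -> ConfusionCounts:
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionCounts(
        tp=int(((y == TOXIC) & (p == TOXIC)).sum()),
        tn=int(((y != TOXIC) & (p != TOXIC)).sum()),
        fp=int(((y != TOXIC) & (p == TOXIC)).sum()),
        fn=int(((y == TOXIC) & (p != TOXIC)).sum()),
    )


def brier_score(true_labels, probabilities) -> float:
    """Mean over compounds of (Pr(toxic) - y)^2."""
    y = np.asarray(true_labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if y.size == 0:
        raise ValueError("need at least one compound")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def coverage(n_inside_ad: int, n_total: int) -> float:
    """Fraction of queried compounds inside the applicability domain."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_inside_ad <= n_total:
        raise ValueError("n_inside_ad must be in [0, n_total]")
    return n_inside_ad / n_total


def evaluate_predictions(true_labels, probabilities, threshold: float = 0.5) -> MetricReport:
    """Full metric report (incl. Brier) from toxic-class probabilities."""
    p = np.asarray(probabilities, dtype=float)
    report = compute_metrics(confusion_from_predictions(true_labels, (p > threshold).astype(int)))
    report.brier = brier_score(true_labels, p)
    return report


# ---------------------------------------------------------------------------
# Y-scrambling


def y_scramble(
    modeling_set: DescriptorMatrix,
    trainer: Callable[[DescriptorMatrix, int], object],
    n_repeats: int = 100,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> list[MetricReport]:
    """Chance-correlation null: refit on label-permuted copies.

    For each repeat the labels of the modeling pool are permuted (marginals
    preserved), the pool is resampled into train/validation parts, the
    trainer is fit on the shuffled training part, and validation metrics are
    recorded. A genuine model's metrics should sit far above this null.

    ``trainer(train, seed)`` must return an object with
    ``predict_proba(DescriptorMatrix) -> array`` (e.g. a closure around
    :func:`wormqsar.gbt.fit_gbt`, under-sampling included).
    """
    if modeling_set.y is None:
        raise ValueError("y_scramble requires labels")
    rng = np.random.default_rng(seed)
    reports: list[MetricReport] = []
    for i in range(n_repeats):
        perm = rng.permutation(modeling_set.y.to_numpy())
        shuffled = DescriptorMatrix(modeling_set.X, pd.Series(perm, index=modeling_set.X.index))
        sub_seed = int(rng.integers(2**31))
        train, val = resample_train_val(shuffled, train_fraction, seed=sub_seed)
        try:
            model = trainer(train, sub_seed)
            probs = model.predict_proba(val)
        except Exception as exc:  # propagate with the repeat index, per contract
            raise RuntimeError(f"y-scrambling trainer failed at repeat {i}") from exc
        reports.append(evaluate_predictions(val.y, probs))
    return reports


def make_undersampled_trainer(hp, mask_names: Sequence[str] | None = None):
    """Standard Y-scrambling trainer: under-sample then fit the GBT."""
    from .gbt import fit_gbt

    def trainer(train: DescriptorMatrix, seed: int):
        if mask_names is not None:
            train = train.select_descriptors(mask_names)
        return fit_gbt(under_sample(train, seed), hp, seed)

    return trainer
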