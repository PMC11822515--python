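"""Stacked two-model ensemble with a dual-threshold applicability domain.

The two base classifiers' toxic-class probabilities are combined additively
and normalized to zero by subtracting each model's 0.5 decision threshold:

    score = (p_a - 0.5) + (p_b - 0.5)  in [-1, 1].

A compound is called toxic when the score strictly exceeds the toxic
threshold (>= 0), nontoxic when it falls strictly below the nontoxic
threshold (<= 0), and *outside the applicability domain* otherwise —
abstention where the two models disagree or are unsure. Widening the
thresholds trades coverage (fraction of compounds given a verdict) for
performance on the covered compounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .gbt import FittedClassifier
from .metrics import coverage as coverage_ratio
from .metrics import confusion_from_predictions, compute_metrics


class Verdict(str, Enum):
    TOXIC = "toxic"
    NONTOXIC = "nontoxic"
    OUTSIDE_AD = "outside_AD"


@dataclass
class AdDecision:
    score: float
    verdict: Verdict


@dataclass
class AdEnsemble:
    """Two fitted models plus the (toxic, nontoxic) score thresholds."""

    model_a: FittedClassifier
    model_b: FittedClassifier
    t_tox: float = 0.0
    t_non: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t_non <= 0.0 <= self.t_tox):
            raise ValueError("thresholds must satisfy t_non <= 0 <= t_tox")

    def scores(self, compounds) -> np.ndarray:
        pa = self.model_a.predict_proba(compounds)
        pb = self.model_b.predict_proba(compounds)
        return np.array([ensemble_score(a, b) for a, b in zip(pa, pb)])

    def decide(self, compounds) -> list[AdDecision]:
        return [classify_with_ad(s, self.t_tox, self.t_non) for s in self.scores(compounds)]


def ensemble_score(p_a: float, p_b: float) -> float:
    """Additive stacked score, normalized to 0 at the per-model thresholds."""
    for p in (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability out of range: {p}")
    return (p_a - 0.5) + (p_b - 0.5)


def classify_with_ad(score: float, t_tox: float, t_non: float) -> AdDecision:
    """Dual-threshold verdict with strict inequalities at the boundaries."""
    if t_non > t_tox:
        raise ValueError("nontoxic threshold must not exceed the toxic threshold")
    if score > t_tox:
        verdict = Verdict.TOXIC
    elif score < t_non:
        verdict = Verdict.NONTOXIC
    else:
        verdict = Verdict.OUTSIDE_AD
    return AdDecision(score=float(score), verdict=verdict)


def default_grid(step: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    t = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return t, -t


@dataclass
class ThresholdSurface:
    """Coverage and metrics on the covered compounds per threshold pair."""

    table: pd.DataFrame  # columns: t_tox, t_non, coverage, sens, spec, balacc

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def threshold_scan(scores, labels, t_tox_grid=None, t_non_grid=None) -> ThresholdSurface:
    """Scan threshold pairs; metrics computed inside the AD only.

    Cells where a class vanishes inside the AD carry missing sens/spec; an
    empty AD leaves every metric missing.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    if t_tox_grid is None or t_non_grid is None:
        tox_default, non_default = default_grid()
        t_tox_grid = tox_default if t_tox_grid is None else t_tox_grid
        t_non_grid = non_default if t_non_grid is None else t_non_grid
    t_tox_grid = np.asarray(t_tox_grid, dtype=float)
    t_non_grid = np.asarray(t_non_grid, dtype=float)
    if t_tox_grid.size == 0 or t_non_grid.size == 0:
        raise ValueError("threshold grids must be nonempty")
    rows = []
    n = s.size
    for t_tox in t_tox_grid:
        tox_mask = s > t_tox
        for t_non in t_non_grid:
            inside = tox_mask | (s < t_non)
            row = {"t_tox": t_tox, "t_non": t_non,
                   "coverage": coverage_ratio(int(inside.sum()), n),
                   "sens": None, "spec": None, "balacc": None}
            if inside.any():
                pred = tox_mask[inside].astype(int)
                rep = compute_metrics(confusion_from_predictions(y[inside], pred))
                row.update(sens=rep.sens, spec=rep.spec,
                           balacc=rep.balacc if rep.sens is not None and rep.spec is not None
                           else None)
            rows.append(row)
    return ThresholdSurface(pd.DataFrame(rows))


def pick_operating_point(surface: ThresholdSurface, coverage_floor: float = 0.7
                         ) -> tuple[float, float]:
    """Best balanced accuracy subject to a coverage floor.

    Ties prefer larger coverage, then the narrower threshold pair
    (smaller |t_tox| + |t_non|).
    """
    t = surface.table
    ok = t[(t["coverage"] >= coverage_floor) & t["balacc"].notna()]
    if ok.empty:
        raise ValueError(
            f"no threshold pair reaches coverage >= {coverage_floor}; "
            f"maximum achievable coverage with defined metrics is "
            f"{t.loc[t['balacc'].notna(), 'coverage'].max() if t['balacc'].notna().any() else 0}"
        )
    width = ok["t_tox"].abs() + ok["t_non"].abs()
    ranked = ok.assign(_width=width).sort_values(
        ["balacc", "coverage", "_width"], ascending=[False, False, True], kind="stable")
    best = ranked.iloc[0]
    return float(best["t_tox"]), float(best["t_non"])
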