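"""Stochastic gradient-boosted tree classifier and Bayesian tuning.

The classifier is a boosting loop over depth-limited weak learners: each
tree is fit to the residuals (gradients) of the running prediction on a
seeded per-tree row subsample, with a per-split feature subsample, and the
prediction is updated by ``shrinkage`` times the tree output; boosting stops
early once the training loss plateaus. LightGBM provides this loop; the
wrapper pins it to single-threaded deterministic mode and embeds the
training schema so prediction inputs are validated by descriptor name.

Hyperparameters are tuned by a budgeted sequential model-based search: a
seeded random initial design followed by Gaussian-process expected-
improvement proposals, each evaluated by under-sampled k-fold
cross-validation (out-of-fold Brier score by default, favouring calibrated
probabilities).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd

from .curation import under_sample
from .data import DescriptorMatrix
from .metrics import brier_score


@dataclass(frozen=True)
class Hyperparameters:
    """Tunable GBT settings: learning rate, ensemble size, subsampling, depth."""

    shrinkage: float = 0.1
    n_trees: int = 200
    feature_fraction: float = 0.8  # fraction of descriptors considered per split
    row_fraction: float = 0.8      # fraction of compounds bagged per tree
    max_depth: int = 3

    def __post_init__(self) -> None:
        if self.shrinkage <= 0:
            raise ValueError("shrinkage must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be at least 1")
        for name in ("feature_fraction", "row_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be at least 1")


class SchemaMismatchError(ValueError):
    pass


@dataclass
class FittedClassifier:
    """A trained boosted-tree model exposing calibrated toxic-class probability."""

    booster: lgb.Booster
    descriptor_names: list[str]
    hp: Hyperparameters
    n_trees_used: int
    train_loss_curve: list[float]

    def _validate(self, compounds: DescriptorMatrix | pd.DataFrame) -> pd.DataFrame:
        X = compounds.X if isinstance(compounds, DescriptorMatrix) else compounds
        missing = [c for c in self.descriptor_names if c not in X.columns]
        if missing:
            raise SchemaMismatchError(f"input is missing trained descriptors: {missing}")
        return X[self.descriptor_names]

    def predict_proba(self, compounds: DescriptorMatrix | pd.DataFrame) -> np.ndarray:
        """Toxic-class probability per compound, in [0, 1]."""
        X = self._validate(compounds)
        if len(X) == 0:
            return np.empty(0)
        p = self.booster.predict(X.to_numpy(), num_iteration=self.n_trees_used)
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def predict_label(self, compounds: DescriptorMatrix | pd.DataFrame,
                      threshold: float = 0.5) -> np.ndarray:
        """Toxic iff probability exceeds the 0.5 threshold."""
        return (self.predict_proba(compounds) > threshold).astype(int)

    def predict_proba_array(self, rows: np.ndarray) -> np.ndarray:
        """Probability for raw rows already ordered as ``descriptor_names``."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        p = self.booster.predict(rows, num_iteration=self.n_trees_used)
        return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)

    def save(self, path: str | Path) -> None:
        """Persist as a JSON envelope with the model text and schema embedded."""
        payload = {
            "format": "wormqsar-gbt/1",
            "descriptor_names": self.descriptor_names,
            "hyperparameters": asdict(self.hp),
            "n_trees_used": self.n_trees_used,
            "train_loss_curve": self.train_loss_curve,
            "booster": self.booster.model_to_string(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "FittedClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "wormqsar-gbt/1":
            raise ValueError(f"unrecognized model format in {path}")
        return cls(
            booster=lgb.Booster(model_str=payload["booster"]),
            descriptor_names=payload["descriptor_names"],
            hp=Hyperparameters(**payload["hyperparameters"]),
            n_trees_used=payload["n_trees_used"],
            train_loss_curve=payload["train_loss_curve"],
        )


def _train_plateau_stop(patience: int, tol: float):
    """Stop boosting when the training loss stops improving by ``tol``."""
    state = {"best": math.inf, "best_iter": 0, "stall": 0}

    def callback(env) -> None:
        loss = env.evaluation_result_list[0][2]
        if loss < state["best"] - tol:
            state.update(best=loss, best_iter=env.iteration, stall=0)
        else:
            state["stall"] += 1
            if state["stall"] >= patience:
                raise lgb.callback.EarlyStopException(state["best_iter"],
                                                      env.evaluation_result_list)

    callback.order = 30  # run after the evaluation callback
    return callback


def fit_gbt(train: DescriptorMatrix, hp: Hyperparameters, seed: int,
            plateau_rounds: int = 25, plateau_tol: float = 1e-5) -> FittedClassifier:
    """Fit the stochastic GBT on labeled training data.

    Deterministic under ``seed``. Boosting stops once the training loss has
    not improved by ``plateau_tol`` for ``plateau_rounds`` consecutive
    rounds, and the ensemble is truncated at the best round; at most
    ``hp.n_trees`` trees are kept.
    """
    if train.y is None:
        raise ValueError("fit_gbt requires labels")
    n_tox, n_non = train.class_counts()
    if n_tox == 0 or n_non == 0:
        raise ValueError("training data contains a single class")
    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy(dtype=float)
    params = {
        "objective": "binary",
        "learning_rate": hp.shrinkage,
        "max_depth": hp.max_depth,
        "num_leaves": 2 ** hp.max_depth,
        "feature_fraction_bynode": hp.feature_fraction,
        "bagging_fraction": hp.row_fraction,
        "bagging_freq": 1 if hp.row_fraction < 1 else 0,
        "min_data_in_leaf": 1,
        "min_data_in_bin": 1,
        "min_sum_hessian_in_leaf": 1e-3,
        "verbosity": -1,
        "seed": int(seed) % (2**31),
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
    }
    evals: dict = {}
    dataset = lgb.Dataset(X, label=y, params={"verbosity": -1})
    callbacks = [lgb.record_evaluation(evals)]
    if hp.n_trees > plateau_rounds:
        callbacks.append(_train_plateau_stop(plateau_rounds, plateau_tol))
    booster = lgb.train(
        params, dataset, num_boost_round=hp.n_trees,
        valid_sets=[dataset], valid_names=["train"], callbacks=callbacks,
    )
    curve = [float(v) for v in evals["train"]["binary_logloss"]]
    best = booster.best_iteration if booster.best_iteration > 0 else len(curve)
    return FittedClassifier(
        booster=booster,
        descriptor_names=train.descriptor_names,
        hp=hp,
        n_trees_used=int(best),
        train_loss_curve=curve[:best],
    )


def predict_proba(model: FittedClassifier, compounds: DescriptorMatrix) -> np.ndarray:
    """Functional alias for :meth:`FittedClassifier.predict_proba`."""
    return model.predict_proba(compounds)


# ---------------------------------------------------------------------------
# Cross-validated objective


def cv_objective(modeling_train: DescriptorMatrix, mask, hp: Hyperparameters,
                 k: int = 5, seed: int = 0) -> float:
    """Mean out-of-fold Brier score under k-fold CV with in-fold under-sampling.

    Folds are stratified when ``k`` does not exceed the minority count and
    plain otherwise (e.g. leave-one-out on a tiny balanced set).
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if modeling_train.y is None:
        raise ValueError("cv_objective requires labels")
    data = modeling_train if mask is None else modeling_train.select_descriptors(mask)
    n = data.n_compounds
    if k > n or k < 2:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    y = data.y.to_numpy()
    minority = min(data.class_counts())
    if k <= minority:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        splits = splitter.split(data.X, y)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        splits = splitter.split(data.X)
    rng = np.random.default_rng(seed)
    losses = []
    for train_idx, val_idx in splits:
        fold_train = data.subset(data.X.index[train_idx])
        fold_val = data.subset(data.X.index[val_idx])
        fold_seed = int(rng.integers(2**31))
        model = fit_gbt(under_sample(fold_train, fold_seed), hp, fold_seed)
        losses.append(brier_score(fold_val.y, model.predict_proba(fold_val)))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# Search space and Bayesian optimization


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    scale: str = "linear"  # "linear" | "log"
    integer: bool = False

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")

    def from_unit(self, u: float) -> float:
        if self.scale == "log":
            v = math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low)))
        else:
            v = self.low + u * (self.high - self.low)
        if self.integer:
            v = int(round(v))
            v = min(max(v, int(math.ceil(self.low))), int(math.floor(self.high)))
        return v


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def decode(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(float(ui)) for d, ui in zip(self.dimensions, u)}


def default_search_space() -> SearchSpace:
    """Default GBT hyperparameter bounds (weak, depth-limited learners)."""
    return SearchSpace((
        Dimension("shrinkage", 0.01, 0.3, scale="log"),
        Dimension("n_trees", 50, 500, integer=True),
        Dimension("feature_fraction", 0.1, 1.0),
        Dimension("row_fraction", 0.5, 1.0),
        Dimension("max_depth", 1, 5, integer=True),
    ))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          xi: float = 0.01) -> np.ndarray:
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu - xi) / sigma
    return (best - mu - xi) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_optimize(
    objective: Callable[[Hyperparameters], float],
    space: SearchSpace | None = None,
    n_iterations: int = 32,
    seed: int = 0,
    n_candidates: int = 256,
) -> tuple[Hyperparameters, list[tuple[Hyperparameters, float]]]:
    """Minimize a hyperparameter objective under a fixed evaluation budget.

    A seeded random initial design (half the budget, at most 8 points) is
    followed by Gaussian-process surrogate proposals maximizing expected
    improvement over a seeded candidate set. Exactly ``n_iterations``
    objective evaluations are made; the best point seen is returned together
    with the full history.
    """
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

    if space is None:
        space = default_search_space()
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    rng = np.random.default_rng(seed)
    d = len(space.dimensions)
    n_init = max(1, min(8, n_iterations // 2)) if n_iterations > 1 else 1

    # When the space spans Hyperparameters fields the objective receives a
    # Hyperparameters object; otherwise (e.g. generic test functions) it
    # receives the decoded parameter dict.
    import dataclasses

    hp_fields = {f.name for f in dataclasses.fields(Hyperparameters)}
    as_hp = all(dim.name in hp_fields for dim in space.dimensions)

    units: list[np.ndarray] = []
    values: list[float] = []
    history: list[tuple] = []

    def evaluate(u: np.ndarray) -> None:
        decoded = space.decode(u)
        hp = Hyperparameters(**decoded) if as_hp else decoded
        val = float(objective(hp))
        units.append(u)
        values.append(val)
        history.append((hp, val))

    for _ in range(n_init):
        evaluate(rng.random(d))

    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * Matern(length_scale=np.full(d, 0.3), length_scale_bounds=(1e-2, 1e2), nu=2.5)
              + WhiteKernel(1e-6, (1e-10, 1e-1)))
    while len(values) < n_iterations:
        X = np.vstack(units)
        yv = np.asarray(values)
        y_mean, y_std = yv.mean(), yv.std()
        y_norm = (yv - y_mean) / (y_std if y_std > 0 else 1.0)
        gp = GaussianProcessRegressor(kernel=kernel, alpha=1e-8, normalize_y=False,
                                      n_restarts_optimizer=0, random_state=int(seed) % (2**31))
        try:
            import warnings

            cand = rng.random((n_candidates, d))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # surrogate kernel bound hits are benign
                gp.fit(X, y_norm)
                mu, sigma = gp.predict(cand, return_std=True)
            ei = _expected_improvement(mu, sigma, y_norm.min())
            u_next = cand[int(np.argmax(ei))]
        except Exception:
            u_next = rng.random(d)  # surrogate failure degrades to random search
        evaluate(u_next)

    best_idx = int(np.argmin(values))
    return history[best_idx][0], history
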