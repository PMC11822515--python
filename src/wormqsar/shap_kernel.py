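"""Kernel SHAP: additive explanations of boosted-tree predictions.

A prediction f(x) is explained by a linear surrogate g(z') = beta0 + sum_i
beta_i z'_i over binary coalition vectors z' of length M (the model's
descriptor count). Mapping a coalition back to descriptor space keeps x's
value where z'_i = 1 and imputes positions with 0 stochastically from the
background data (full-row draws, so the background's descriptor
co-distribution is respected). Coalitions are weighted by the Shapley
kernel

    pi(z') = (M - 1) / (C(M, |z'|) * |z'| * (M - |z'|)),

which concentrates weight on coalitions with a single descriptor present or
missing; the empty and full coalitions enter as equality constraints
(g(empty) = mean background prediction, g(full) = f(x)), making the
efficiency identity beta0 + sum(beta) = f(x) exact. Solving the weighted
least-squares problem over all 2^M coalitions recovers the Shapley values
exactly; models here carry 5-6 descriptors, so full enumeration is the
default and sampling is only needed for larger M.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .data import DescriptorMatrix
from .gbt import FittedClassifier


@dataclass(frozen=True)
class Coalition:
    z_prime: np.ndarray  # boolean, length M

    @property
    def size(self) -> int:
        return int(self.z_prime.sum())


@dataclass
class Explanation:
    compound_id: str
    beta0: float
    betas: pd.Series  # SHAP value per descriptor

    @property
    def prediction(self) -> float:
        return float(self.beta0 + self.betas.sum())

    def to_dict(self) -> dict:
        return {"compound_id": self.compound_id, "beta0": self.beta0,
                **self.betas.to_dict()}


def shap_kernel_weight(M: int, coalition_size: int) -> float:
    """Shapley kernel weight for a coalition of the given size."""
    if not 0 < coalition_size < M:
        raise ValueError(
            "empty and full coalitions are handled as constraints, not weighted points"
        )
    return (M - 1) / (comb(M, coalition_size) * coalition_size * (M - coalition_size))


def impute_coalition(x: np.ndarray, z_prime: np.ndarray,
                     background: DescriptorMatrix | np.ndarray, seed: int) -> np.ndarray:
    """Map a coalition to descriptor space: 1s keep x, 0s take a background row."""
    bg = background.X.to_numpy() if isinstance(background, DescriptorMatrix) else np.asarray(background)
    bg = np.atleast_2d(bg)
    if bg.shape[0] == 0:
        raise ValueError("background data must be nonempty")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z_prime, dtype=bool)
    if x.shape[0] != z.shape[0] or bg.shape[1] != x.shape[0]:
        raise ValueError("x, coalition and background widths must agree")
    rng = np.random.default_rng(seed)
    row = bg[rng.integers(bg.shape[0])]
    return np.where(z, x, row)


def _coalition_matrix(M: int, rng: np.random.Generator,
                      max_enumerate: int = 15, budget: int = 2048) -> np.ndarray:
    """All non-trivial coalitions when 2^M is small; kernel-sampled otherwise."""
    if M <= max_enumerate:
        rows = []
        for size in range(1, M):
            for idx in combinations(range(M), size):
                z = np.zeros(M, dtype=bool)
                z[list(idx)] = True
                rows.append(z)
        return np.array(rows)
    if M > 25:
        raise ValueError("M > 25 requires an explicit sampling budget via `budget`")
    sizes = np.arange(1, M)
    size_w = np.array([shap_kernel_weight(M, s) * comb(M, s) for s in sizes])
    size_w /= size_w.sum()
    rows = []
    for _ in range(budget):
        s = rng.choice(sizes, p=size_w)
        idx = rng.choice(M, size=s, replace=False)
        z = np.zeros(M, dtype=bool)
        z[idx] = True
        rows.append(z)
    return np.array(rows)


def explain(
    model: FittedClassifier,
    x: np.ndarray | pd.Series,
    background: DescriptorMatrix,
    n_imputation_replicates: int = 16,
    seed: int = 0,
    compound_id: str = "",
    budget: int = 2048,
) -> Explanation:
    """SHAP values of one compound's toxic-class probability.

    For every non-trivial coalition the model output is averaged over
    ``n_imputation_replicates`` seeded background-row imputations; the
    kernel-weighted L2 problem is then solved subject to the two coalition
    constraints. With a single background row the imputation is
    deterministic and the result equals the exact Shapley values.
    """
    names = model.descriptor_names
    M = len(names)
    if isinstance(x, pd.Series):
        x = x.reindex(names).to_numpy()
    x = np.asarray(x, dtype=float)
    if x.shape[0] != M:
        raise ValueError("x length must equal the model's descriptor count")
    bg = background.X[names].to_numpy(dtype=float)
    if bg.shape[0] == 0:
        raise ValueError("background data must be nonempty")
    rng = np.random.default_rng(seed)
    n_rep = min(n_imputation_replicates, bg.shape[0]) if bg.shape[0] == 1 else n_imputation_replicates

    Z = _coalition_matrix(M, rng, budget=budget)
    n_coal = Z.shape[0]
    # One background row per replicate, shared across coalitions: stack all
    # imputed rows and batch-predict.
    rep_rows = bg[rng.integers(bg.shape[0], size=n_rep)]
    stacked = np.where(Z[:, None, :], x[None, None, :], rep_rows[None, :, :])
    preds = model.predict_proba_array(stacked.reshape(n_coal * n_rep, M))
    v = preds.reshape(n_coal, n_rep).mean(axis=1)

    fx = float(model.predict_proba_array(x[None, :])[0])
    beta0 = float(model.predict_proba_array(rep_rows).mean()) if bg.shape[0] > 1 \
        else float(model.predict_proba_array(bg).mean())

    weights = np.array([shap_kernel_weight(M, int(z.sum())) for z in Z])
    betas = _solve_constrained_wls(Z.astype(float), v, weights, beta0, fx)
    return Explanation(compound_id=compound_id, beta0=beta0,
                       betas=pd.Series(betas, index=names))


def _solve_constrained_wls(Z: np.ndarray, v: np.ndarray, w: np.ndarray,
                           beta0: float, fx: float) -> np.ndarray:
    """Weighted least squares with the efficiency constraint eliminated.

    Substituting beta_M = (fx - beta0) - sum_{i<M} beta_i turns the
    constrained problem into an ordinary WLS in M-1 unknowns.
    """
    M = Z.shape[1]
    if M == 1:
        return np.array([fx - beta0])
    y = v - beta0 - Z[:, -1] * (fx - beta0)
    A = Z[:, :-1] - Z[:, -1:]
    sw = np.sqrt(w)
    beta_head, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    beta_last = (fx - beta0) - beta_head.sum()
    return np.append(beta_head, beta_last)


def importance_ranking(explanations: list[Explanation]) -> pd.DataFrame:
    """Descriptors ordered by decreasing mean |SHAP| over compounds.

    Ties break alphabetically. Returns columns (rank, descriptor, score).
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    frame = pd.DataFrame([e.betas for e in explanations])
    scores = frame.abs().mean(axis=0)
    order = sorted(scores.index, key=lambda name: (-scores[name], name))
    return pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "descriptor": order,
        "mean_abs_shap": [scores[name] for name in order],
    })


def explanations_to_csv(explanations: list[Explanation], path) -> None:
    pd.DataFrame([e.to_dict() for e in explanations]).to_csv(path, index=False)
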