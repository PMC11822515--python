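"""End-to-end workflow: data -> GA selection -> models A/B -> SHAP ->
ensemble applicability domain -> report bundle.

Stage seeds are derived from one global seed by hashing stage names, so the
whole run is reproducible and adding a stage does not shift the randomness
of the others.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curation
from .curation import resample_train_val, split_dataset, under_sample
from .data import DescriptorMatrix, derive_seed
from .ensemble import (AdEnsemble, Verdict, classify_with_ad, default_grid,
                       pick_operating_point, threshold_scan)
from .ga import GAConfig, HallOfFame, Individual, run_ga
from .gbt import FittedClassifier, SearchSpace, default_search_space, fit_gbt
from .metrics import (compute_metrics, confusion_from_predictions, coverage,
                      evaluate_predictions, make_undersampled_trainer, y_scramble)
from .shap_kernel import Explanation, explain, explanations_to_csv, importance_ranking
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # data: either a synthetic config or paths to descriptor/NOEC CSVs
    synthetic: SyntheticConfig | None = None
    descriptors_csv: str | None = None
    noec_csv: str | None = None
    breakpoint: float = curation.DEFAULT_BREAKPOINT
    test_size: int = 147
    stratified_split: bool = False
    ga: GAConfig = field(default_factory=lambda: GAConfig(
        population_size=20, n_generations=5, bayes_iterations=8))
    shap_replicates: int = 16
    shap_budget: int = 2048
    ad_grid_step: float = 0.02
    coverage_floor: float = 0.7
    yscramble_repeats: int = 100
    seed: int = 0
    outdir: str = "wormqsar_run"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


@dataclass
class PipelineResult:
    model_a: FittedClassifier
    model_b: FittedClassifier
    ensemble: AdEnsemble
    metrics_table: pd.DataFrame
    importance_table: pd.DataFrame
    surface_table: pd.DataFrame
    yscramble_table: pd.DataFrame
    summary: dict


def _load_data(config: PipelineConfig) -> DescriptorMatrix:
    if config.synthetic is not None:
        cfg = config.synthetic
        dataset = generate_dataset(cfg)
        return dataset.descriptor_matrix
    if not config.descriptors_csv:
        raise ValueError("config needs either a synthetic block or descriptor/NOEC CSV paths")
    X = pd.read_csv(config.descriptors_csv, index_col="compound_id")
    inline_labels = X.pop("label") if "label" in X.columns else None
    if config.noec_csv:
        noec = pd.read_csv(config.noec_csv, dtype={"noec": str})
        records = [curation.parse_noec(str(r.compound_id), r.noec) for r in noec.itertuples()]
        labels = curation.labels_from_records(records, config.breakpoint)
        keep = X.index.intersection(labels.index, sort=False)
        return DescriptorMatrix(X.loc[keep], labels.loc[keep])
    return DescriptorMatrix(X, inline_labels)


def _drop_constant(matrix: DescriptorMatrix) -> DescriptorMatrix:
    keep = matrix.X.columns[matrix.X.nunique() > 1]
    return matrix.select_descriptors(list(keep))


def _final_fit(modeling_set: DescriptorMatrix, ind: Individual, seed: int
               ) -> tuple[FittedClassifier, DescriptorMatrix, DescriptorMatrix, DescriptorMatrix]:
    """Refit a hall-of-fame mask on a fresh seeded resample of the pool."""
    data = modeling_set.select_descriptors(ind.mask)
    train, val = resample_train_val(data, 0.8, seed=seed)
    balanced = under_sample(train, seed)
    model = fit_gbt(balanced, ind.tuned_hp, seed)
    return model, train, val, balanced


def _report_row(model_name: str, set_name: str, y, probs) -> dict:
    rep = evaluate_predictions(y, probs)
    return {"model": model_name, "set": set_name, **rep.to_dict()}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the whole workflow and write the report bundle to ``config.outdir``.

    Produces a specificity-oriented Model A, a sensitivity-oriented Model B,
    and their stacked dual-threshold ensemble, plus metric tables, SHAP
    importances, the threshold surface, and a Y-scrambling summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load-data"
    try:
        full = _drop_constant(_load_data(config))
        if full.y is None:
            raise ValueError("pipeline requires labeled data")

        stage = "split"
        modeling_set, test_set = split_dataset(
            full, config.test_size, config.stage_seed("split"), config.stratified_split)

        stage = "ga-selection"
        ga_config = GAConfig(**{**asdict(config.ga), "seed": config.stage_seed("ga")})
        population, hof, ga_log = run_ga(modeling_set, ga_config)
        ga_log.to_csv(outdir / "ga_log.csv", index=False)
        if hof.best_specificity is None or hof.best_sensitivity is None:
            raise RuntimeError("GA produced no hall-of-fame individuals")

        stage = "final-fit"
        model_a, train_a, val_a, bg_a = _final_fit(
            modeling_set, hof.best_specificity, config.stage_seed("final-a"))
        model_b, train_b, val_b, bg_b = _final_fit(
            modeling_set, hof.best_sensitivity, config.stage_seed("final-b"))

        stage = "metrics"
        rows = []
        for name, model, train, val in (("A", model_a, train_a, val_a),
                                        ("B", model_b, train_b, val_b)):
            rows.append(_report_row(name, "train", train.y, model.predict_proba(train)))
            rows.append(_report_row(name, "val", val.y, model.predict_proba(val)))
            rows.append(_report_row(name, "test", test_set.y, model.predict_proba(test_set)))

        stage = "shap"
        importance_frames = []
        shap_seed = config.stage_seed("shap")
        for name, model, bg in (("A", model_a, bg_a), ("B", model_b, bg_b)):
            explanations = [
                explain(model, test_set.X.loc[cid, model.descriptor_names], bg,
                        n_imputation_replicates=config.shap_replicates,
                        seed=shap_seed + i, compound_id=str(cid), budget=config.shap_budget)
                for i, cid in enumerate(test_set.X.index)
            ]
            explanations_to_csv(explanations, outdir / f"shap_values_model_{name}.csv")
            ranking = importance_ranking(explanations)
            ranking.insert(1, "model", name)
            importance_frames.append(ranking)
        importance_table = pd.concat(importance_frames, ignore_index=True)

        stage = "ensemble"
        scores = np.array([
            (a - 0.5) + (b - 0.5)
            for a, b in zip(model_a.predict_proba(test_set), model_b.predict_proba(test_set))
        ])
        tox_grid, non_grid = default_grid(config.ad_grid_step)
        surface = threshold_scan(scores, test_set.y, tox_grid, non_grid)
        try:
            t_tox, t_non = pick_operating_point(surface, config.coverage_floor)
        except ValueError:
            log.warning("no threshold pair met the coverage floor %.2f; "
                        "falling back to (0, 0)", config.coverage_floor)
            t_tox = t_non = 0.0
        ad = AdEnsemble(model_a, model_b, t_tox, t_non)
        decisions = [classify_with_ad(s, t_tox, t_non) for s in scores]
        inside = np.array([d.verdict is not Verdict.OUTSIDE_AD for d in decisions])
        ens_row = {"model": "A&B", "set": "test", "acc": None, "sens": None, "spec": None,
                   "balacc": None, "mcc": None, "brier": None,
                   "coverage": coverage(int(inside.sum()), len(decisions))}
        if inside.any():
            pred = np.array([d.verdict is Verdict.TOXIC for d in decisions])[inside].astype(int)
            rep = compute_metrics(confusion_from_predictions(test_set.y.to_numpy()[inside], pred))
            ens_row.update({**rep.to_dict(), "coverage": ens_row["coverage"]})
        rows.append(ens_row)
        metrics_table = pd.DataFrame(rows)

        stage = "y-scrambling"
        ys_rows = []
        ys_seed = config.stage_seed("y-scramble")
        for name, ind in (("A", hof.best_specificity), ("B", hof.best_sensitivity)):
            mask_names = list(np.array(modeling_set.descriptor_names)[ind.mask])
            trainer = make_undersampled_trainer(ind.tuned_hp, mask_names)
            reports = y_scramble(modeling_set, trainer, config.yscramble_repeats, ys_seed)
            null_mcc = np.array([r.mcc for r in reports])
            ys_rows.append({
                "model": name,
                "n_repeats": config.yscramble_repeats,
                "null_mcc_mean": float(null_mcc.mean()),
                "null_mcc_sd": float(null_mcc.std(ddof=1)),
                "null_mcc_p95": float(np.percentile(null_mcc, 95)),
                "model_val_mcc": float(ind.val_report.mcc),
            })
        yscramble_table = pd.DataFrame(ys_rows)

        stage = "report"
        metrics_table.to_csv(outdir / "metrics_table.csv", index=False)
        importance_table.to_csv(outdir / "shap_importance.csv", index=False)
        surface.to_csv(outdir / "threshold_surface.csv")
        yscramble_table.to_csv(outdir / "yscrambling.csv", index=False)
        model_a.save(outdir / "model_a.json")
        model_b.save(outdir / "model_b.json")
        bg_a.to_csv(outdir / "background_a.csv")
        bg_b.to_csv(outdir / "background_b.csv")
        summary = {
            "seed": config.seed,
            "n_compounds": full.n_compounds,
            "n_modeling": modeling_set.n_compounds,
            "n_test": test_set.n_compounds,
            "model_a_descriptors": model_a.descriptor_names,
            "model_b_descriptors": model_b.descriptor_names,
            "thresholds": {"toxic": t_tox, "nontoxic": t_non},
            "test_coverage": ens_row["coverage"],
            "ensemble_test_balacc": ens_row["balacc"],
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        return PipelineResult(model_a, model_b, ad, metrics_table, importance_table,
                              surface.table, yscramble_table, summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}'") from exc


def predict_bundle(bundle_dir: str | Path, compounds_csv: str | Path,
                   out_csv: str | Path | None = None,
                   with_shap: bool = True, seed: int = 0) -> pd.DataFrame:
    """Score new compounds with a saved bundle: p_a, p_b, score, verdict, SHAP."""
    bundle = Path(bundle_dir)
    model_a = FittedClassifier.load(bundle / "model_a.json")
    model_b = FittedClassifier.load(bundle / "model_b.json")
    summary = json.loads((bundle / "summary.json").read_text())
    t_tox = summary["thresholds"]["toxic"]
    t_non = summary["thresholds"]["nontoxic"]
    X = pd.read_csv(compounds_csv, index_col="compound_id")

    columns = ["compound_id", "p_a", "p_b", "score", "verdict"]
    shap_cols = ([f"shap_a_{c}" for c in model_a.descriptor_names]
                 + [f"shap_b_{c}" for c in model_b.descriptor_names])
    if X.empty:
        out = pd.DataFrame(columns=columns + (shap_cols if with_shap else []))
    else:
        data = DescriptorMatrix(X)
        pa = model_a.predict_proba(data)
        pb = model_b.predict_proba(data)
        rows = []
        bg_a = DescriptorMatrix(pd.read_csv(bundle / "background_a.csv", index_col="compound_id"))
        bg_b = DescriptorMatrix(pd.read_csv(bundle / "background_b.csv", index_col="compound_id"))
        for i, cid in enumerate(X.index):
            decision = classify_with_ad(ensemble_scalar(pa[i], pb[i]), t_tox, t_non)
            row = {"compound_id": cid, "p_a": pa[i], "p_b": pb[i],
                   "score": decision.score, "verdict": decision.verdict.value}
            if with_shap:
                for tag, model, bg in (("a", model_a, bg_a), ("b", model_b, bg_b)):
                    exp = explain(model, X.loc[cid, model.descriptor_names], bg,
                                  seed=derive_seed(seed, f"predict-{tag}-{i}"),
                                  compound_id=str(cid))
                    for c, v in exp.betas.items():
                        row[f"shap_{tag}_{c}"] = v
            rows.append(row)
        out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out


def ensemble_scalar(p_a: float, p_b: float) -> float:
    from .ensemble import ensemble_score

    return ensemble_score(float(p_a), float(p_b))
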