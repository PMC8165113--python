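"""End-to-end orchestration: simulate/load -> match -> concordance ->
filter/PCA -> two-stage DE -> GA selection -> prediction bench ->
sex-chromosome variant.

A single global seed is fanned out to per-stage child seeds through a fixed
counter scheme (:func:`valvesex.core.stage_rng` numbering), so inserting a
stage never perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .cohort_sim import SimConfig, make_annotation, simulate_clinical, simulate_expression
from .concordance import quadrant_extremes, score_genes
from .core import ExpressionMatrix
from .expression_stats import (
    pca_embed,
    projection_score_optimize,
    select_sex_de_genes,
    variance_rank_filter,
)
from .matching import (
    DEFAULT_COVARIATES,
    balance_table,
    fit_propensity,
    greedy_match,
)
from .predictors import (
    CVConfig,
    GAConfig,
    cv_partition,
    extract_pure_trees,
    fit_models,
    ga_select,
    importance_weights,
    subset_sex_chromosomes,
)

# stage numbering for the seed fan-out (append-only)
STAGE_SEEDS = {
    "simulate": 0,
    "match": 1,
    "concordance": 2,
    "filter": 3,
    "de": 4,
    "ga": 5,
    "classify": 6,
    "sexchrom": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(STAGE_SEEDS[stage],))
    )
    return int(rng.integers(0, 2**31 - 1))


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    sim: SimConfig | None = None
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    clinical_path: str | None = None
    covariates: tuple = DEFAULT_COVARIATES
    caliper: float | str | None = "auto"
    concordance_fraction: float = 0.25
    q_threshold: float = 0.05
    fc_bounds: tuple = (0.8, 1.2)
    pca_components: int = 2
    projection_n_perm: int = 20
    ga: GAConfig = field(default_factory=GAConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    run_ga: bool = True
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        real = all(
            p is not None
            for p in (self.expression_path, self.sample_sheet_path, self.clinical_path)
        )
        if self.sim is None and not real:
            raise ValueError("config needs either a SimConfig or real-data paths")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimConfig):
            raw["sim"] = SimConfig(**raw["sim"])
        if "ga" in raw and isinstance(raw["ga"], dict):
            raw["ga"] = GAConfig(**raw["ga"])
        if "cv" in raw and isinstance(raw["cv"], dict):
            raw["cv"] = CVConfig(**raw["cv"])
        if "fc_bounds" in raw:
            raw["fc_bounds"] = tuple(raw["fc_bounds"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        seed = stage_seed(config.seed, "simulate")
        clinical = simulate_clinical(config.sim, seed)
        expr, truth = simulate_expression(clinical, config.sim, seed)
        annotation = make_annotation(truth)
        return expr, annotation, clinical, truth
    expr = vio.read_expression_matrix(config.expression_path, config.sample_sheet_path)
    annotation = (
        vio.read_annotation(config.annotation_path) if config.annotation_path else None
    )
    clinical = vio.read_clinical(config.clinical_path)
    return expr, annotation, clinical, None


def _tissue_binary_dataset(expr: ExpressionMatrix, genes):
    """Feature matrix / labels / patient groups for calcified-vs-nondiseased."""
    keep = expr.samples["tissue"].isin(["calcified", "nondiseased"])
    sub = expr.subset_samples(expr.sample_ids[keep.to_numpy()])
    x = sub.subset_genes(genes).values.to_numpy().T
    y = (sub.samples["tissue"] == "calcified").astype(int).to_numpy()
    groups = sub.samples["patient_id"].to_numpy()
    return x, y, groups, list(genes)


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written to disk
    when ``config.out_dir`` is set)."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def record(stage, **info):
        report["stages"][stage] = info

    expr, annotation, clinical, truth = _load_inputs(config)
    record("inputs", n_genes=expr.n_genes, n_samples=expr.n_samples, n_patients=len(clinical))
    if out:
        vio.write_expression(expr.values, out / "expression.tsv")
        vio.write_sample_sheet(expr.samples, out / "samples.tsv")
        vio.write_clinical(clinical, out / "clinical.csv")
        if annotation is not None:
            vio.write_annotation(annotation, out / "annotation.tsv")

    # --- matching -----------------------------------------------------
    prop = fit_propensity(clinical, config.covariates)
    match = greedy_match(
        prop.scores,
        clinical.set_index("patient_id")["sex"],
        caliper=config.caliper,
        seed=stage_seed(config.seed, "match"),
    )
    balance = balance_table(clinical, match, config.covariates)
    record(
        "match",
        n_pairs=match.n_pairs,
        caliper=match.caliper,
        separation=prop.separation,
        max_std_diff=float(balance["std_diff"].max()),
    )
    if out:
        vio.write_table(match.to_frame(), out / "pairs.tsv")
        vio.write_table(balance, out / "balance.tsv", index_label="covariate")

    matched_samples = expr.samples["patient_id"].isin(match.matched_patients())
    expr_m = expr.subset_samples(expr.sample_ids[matched_samples.to_numpy()])

    # --- concordance --------------------------------------------------
    scores = score_genes(expr_m, match)
    quads = quadrant_extremes(scores, fraction=config.concordance_fraction)
    record(
        "concordance",
        n_pairs=scores.n_pairs,
        n_patients=scores.n_patients,
        quadrant_sizes={k: len(v) for k, v in quads.sets.items()},
    )
    if out:
        vio.write_table(scores.frame, out / "concordance.tsv", index_label="gene_id")
        members = pd.DataFrame(
            [(g, q) for q, genes in quads.sets.items() for g in genes],
            columns=["gene_id", "quadrant"],
        )
        vio.write_table(members.set_index("gene_id"), out / "quadrants.tsv", index_label="gene_id")

    # --- variance filter + PCA ---------------------------------------
    ps = projection_score_optimize(
        expr_m,
        k_components=config.pca_components,
        n_perm=config.projection_n_perm,
        seed=stage_seed(config.seed, "filter"),
    )
    expr_f = variance_rank_filter(expr_m, threshold=ps.best_threshold)
    pca = pca_embed(expr_f, k=config.pca_components)
    record(
        "filter",
        best_threshold=ps.best_threshold,
        n_retained=expr_f.n_genes,
        pc_variance_fraction=pca.variance_fraction.tolist(),
    )
    if out:
        vio.write_table(ps.table, out / "projection_score.tsv")
        vio.write_table(pca.coordinates, out / "pca.tsv", index_label="sample_id")

    # --- two-stage differential expression ---------------------------
    selection = select_sex_de_genes(
        expr_m, q_threshold=config.q_threshold, fc_bounds=config.fc_bounds
    )
    record(
        "de",
        stage1_survivors=len(selection.stage1_survivors),
        selected=len(selection.genes),
    )
    if out:
        vio.write_table(selection.stage1.table, out / "de_stage1.tsv", index_label="gene_id")
        if selection.stage2 is not None:
            vio.write_table(selection.stage2.table, out / "de_stage2.tsv", index_label="gene_id")
        pd.Series(selection.genes, name="gene_id").to_csv(
            out / "selected_genes.tsv", sep="\t", index=False
        )

    # --- prediction on the selected genes ----------------------------
    if len(selection.genes) >= 1:
        x, y, groups, gene_names = _tissue_binary_dataset(expr_m, selection.genes)
        cv = CVConfig(
            k=config.cv.k,
            group_by_patient=config.cv.group_by_patient,
            stratify_by_class=config.cv.stratify_by_class,
            seed=stage_seed(config.seed, "classify"),
        )
        if config.run_ga:
            ga_cfg = GAConfig(
                **{
                    **{f: getattr(config.ga, f) for f in (
                        "population_size", "generations", "mutation_prob",
                        "crossover_prob", "elitism", "tournament_size", "rf_n_estimators",
                    )},
                    "seed": stage_seed(config.seed, "ga"),
                }
            )
            ga_res = ga_select(x, y, ga_cfg, cv, groups=groups)
            record(
                "ga",
                n_selected=int(ga_res.best_mask.sum()),
                best_fitness=ga_res.best_fitness,
                n_evaluations=ga_res.n_evaluations,
            )
            if out:
                pd.Series(
                    np.asarray(gene_names)[ga_res.best_mask], name="gene_id"
                ).to_csv(out / "ga_selected_genes.tsv", sep="\t", index=False)

        bench = fit_models(x, y, cv, groups=groups)
        from sklearn.ensemble import RandomForestClassifier

        folds = cv_partition(groups, y, cv)
        forest = RandomForestClassifier(n_estimators=100, random_state=cv.seed).fit(x, y)
        imp = importance_weights(forest, feature_names=gene_names)
        pure = extract_pure_trees(forest, x, y, feature_names=gene_names)
        record(
            "classify",
            accuracies={m: r["mean_accuracy"] for m, r in bench.results.items()},
            aucs={m: r["pooled_auc"] for m, r in bench.results.items()},
            model_errors=bench.errors,
            n_pure_trees=len(pure),
            n_folds=int(len(np.unique(folds))),
        )
        if out:
            (out / "model_report.json").write_text(json.dumps(bench.to_dict(), indent=2))
            vio.write_table(imp, out / "importance.tsv", index_label="feature")
            (out / "pure_trees.txt").write_text(
                "\n".join(f"# tree {i}\n{rules}" for i, _, rules in pure)
            )
    else:
        warnings.warn("no genes selected; prediction stage skipped")
        record("classify", skipped=True)

    # --- sex-chromosome-only variant ----------------------------------
    if annotation is not None:
        try:
            expr_xy = subset_sex_chromosomes(expr_m, annotation)
        except ValueError as exc:
            record("sexchrom", skipped=True, reason=str(exc))
        else:
            x, y, groups, gene_names = _tissue_binary_dataset(expr_xy, expr_xy.gene_ids)
            cv = CVConfig(
                k=config.cv.k,
                group_by_patient=config.cv.group_by_patient,
                stratify_by_class=config.cv.stratify_by_class,
                seed=stage_seed(config.seed, "sexchrom"),
            )
            bench_xy = fit_models(x, y, cv, groups=groups)
            record(
                "sexchrom",
                n_genes=expr_xy.n_genes,
                accuracies={m: r["mean_accuracy"] for m, r in bench_xy.results.items()},
                model_errors=bench_xy.errors,
            )
            if out:
                (out / "model_report_sexchrom.json").write_text(
                    json.dumps(bench_xy.to_dict(), indent=2)
                )

    if out:
        (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
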