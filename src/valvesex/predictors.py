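"""Calcification prediction: grouped cross-validation, genetic-algorithm
feature selection, the six-classifier bench, node-improvement importance,
pure-tree extraction and the sex-chromosome-only feature subset.

The genetic algorithm is a wrapper selector: binary feature masks evolved by
tournament selection, uniform crossover, bit-flip mutation and elitism,
scored by the mean cross-validated accuracy of a random forest restricted to
the masked features. Cross-validation is grouped by patient by default so
that two samples from the same valve never straddle a train/validation
split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import ExpressionMatrix

MODEL_NAMES = (
    "logistic",
    "knn",
    "naive_bayes",
    "gradient_boosted_trees",
    "random_forest",
    "deep_net",
)


def load_model_defaults() -> dict:
    with resources.files("valvesex").joinpath("model_defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_models(seed: int = 0, names=MODEL_NAMES) -> dict:
    """Instantiate the prediction bench with pinned hyperparameters."""
    params = load_model_defaults()
    factories = {
        "logistic": lambda: LogisticRegression(random_state=seed, **params["logistic"]),
        "knn": lambda: KNeighborsClassifier(**params["knn"]),
        "naive_bayes": lambda: GaussianNB(**params["naive_bayes"]),
        "gradient_boosted_trees": lambda: GradientBoostingClassifier(
            random_state=seed, **{k: v for k, v in params["gradient_boosted_trees"].items()}
        ),
        "random_forest": lambda: RandomForestClassifier(random_state=seed, **params["random_forest"]),
        # deep-learning toolkits standardize inputs by default; pin the same here
        "deep_net": lambda: make_pipeline(
            StandardScaler(),
            MLPClassifier(
                random_state=seed,
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in params["deep_net"].items()
                },
            ),
        ),
    }
    return {name: factories[name]() for name in names}


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class CVConfig:
    k: int = 6
    group_by_patient: bool = True
    stratify_by_class: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def cv_partition(groups, labels, cv: CVConfig) -> np.ndarray:
    """Assign each sample to one of ``cv.k`` folds.

    All samples of a group (patient) share a fold; groups are dealt
    round-robin after a seeded shuffle and a stable sort on the group's
    majority class, so fold sizes differ by at most one group and classes
    are balanced across folds where possible. With ``group_by_patient``
    off, every sample is its own group.
    """
    groups = np.asarray(groups)
    labels = np.asarray(labels)
    if not cv.group_by_patient:
        groups = np.arange(len(labels))
    unique = pd.unique(groups)
    if cv.k > len(unique):
        raise ValueError(f"k={cv.k} exceeds the {len(unique)} available groups")

    rng = np.random.default_rng(cv.seed)
    shuffled = list(rng.permutation(unique))
    if cv.stratify_by_class:
        def majority(g):
            vals, counts = np.unique(labels[groups == g], return_counts=True)
            return str(vals[np.argmax(counts)])

        shuffled.sort(key=majority)  # stable: keeps the shuffle within classes
    fold_of_group = {g: i % cv.k for i, g in enumerate(shuffled)}
    return np.array([fold_of_group[g] for g in groups])


@dataclass
class CVPerformance:
    fold_accuracy: list
    fold_auc: list
    mean_accuracy: float
    mean_auc: float
    pooled_scores: np.ndarray  # held-out decision scores, aligned to y
    pooled_mask: np.ndarray  # samples that were ever held out


def _decision_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


def cv_evaluate(model, features, labels, folds) -> CVPerformance:
    """Train/validate ``model`` over the precomputed fold assignment.

    Each fold is held out once while the model trains on the rest. Folds
    whose training split contains a single class are skipped with a warning.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    folds = np.asarray(folds)
    accs, aucs = [], []
    pooled = np.full(len(y), np.nan)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {f}: single-class training split, skipped")
            continue
        fitted = clone(model).fit(x[train], y[train])
        pred = fitted.predict(x[test])
        accs.append(float(np.mean(pred == y[test])))
        scores = _decision_scores(fitted, x[test])
        pooled[test] = scores
        if len(np.unique(y[test])) == 2:
            aucs.append(float(roc_auc_score(y[test], scores)))
    if not accs:
        raise ValueError("no evaluable fold (every training split was single-class)")
    return CVPerformance(
        fold_accuracy=accs,
        fold_auc=aucs,
        mean_accuracy=float(np.mean(accs)),
        mean_auc=float(np.mean(aucs)) if aucs else float("nan"),
        pooled_scores=pooled,
        pooled_mask=~np.isnan(pooled),
    )


# ----------------------------------------------------------------------
# genetic-algorithm wrapper selection
# ----------------------------------------------------------------------


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    generations: int = 10
    mutation_prob: float | None = None  # default 1 / n_features
    crossover_prob: float = 0.9
    elitism: int = 2
    tournament_size: int = 3
    rf_n_estimators: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("need 0 <= elitism < population_size")


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    history: list  # best fitness per generation
    n_evaluations: int


def ga_select(
    features, labels, ga: GAConfig, cv: CVConfig, groups=None, initial_population=None
) -> GAResult:
    """Evolve a binary feature mask maximising random-forest CV accuracy.

    Fitness of a mask is the mean grouped-CV accuracy of a seeded random
    forest on the masked feature columns; the empty mask scores 0. Fitness
    values are cached per mask, and elitism makes the best-ever fitness
    non-decreasing across generations.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n_features = x.shape[1]
    if n_features < 1:
        raise ValueError("need at least one feature")
    if groups is None:
        groups = np.arange(len(y))
    folds = cv_partition(groups, y, cv)
    rng = np.random.default_rng(ga.seed)
    p_mut = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / n_features
    forest = RandomForestClassifier(n_estimators=ga.rf_n_estimators, random_state=ga.seed)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            if mask.sum() == 0:
                cache[key] = 0.0
            else:
                cache[key] = cv_evaluate(forest, x[:, mask], y, folds).mean_accuracy
        return cache[key]

    if initial_population is not None:
        pop = np.asarray(initial_population, dtype=bool).copy()
        if pop.ndim != 2 or pop.shape[1] != n_features:
            raise ValueError("initial_population must be (n_individuals, n_features)")
    else:
        pop = rng.random((ga.population_size, n_features)) < 0.5
    if not pop.any():
        warnings.warn("all-zero initial population; reinitialized")
        pop = rng.random((ga.population_size, n_features)) < 0.5
    if initial_population is None:
        for row in pop:  # guarantee every individual selects something
            if not row.any():
                row[rng.integers(n_features)] = True

    best_mask, best_fit, history = None, -np.inf, []
    for _ in range(ga.generations):
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
        history.append(best_fit)

        order = np.argsort(-fits, kind="stable")
        next_pop = [pop[i].copy() for i in order[: ga.elitism]]
        while len(next_pop) < ga.population_size:
            def pick():
                idx = rng.integers(len(pop), size=ga.tournament_size)
                return pop[idx[np.argmax(fits[idx])]]

            a, b = pick().copy(), pick().copy()
            if rng.random() < ga.crossover_prob:
                swap = rng.random(n_features) < 0.5
                a[swap], b[swap] = b[swap].copy(), a[swap].copy()
            for child in (a, b):
                flip = rng.random(n_features) < p_mut
                child[flip] = ~child[flip]
                if len(next_pop) < ga.population_size:
                    next_pop.append(child)
        pop = np.array(next_pop)

    return GAResult(
        best_mask=best_mask, best_fitness=best_fit, history=history, n_evaluations=len(cache)
    )


# ----------------------------------------------------------------------
# model bench
# ----------------------------------------------------------------------


@dataclass
class ModelReport:
    """Per-model CV performance and pooled ROC curves."""

    results: dict  # name -> {mean_accuracy, fold_accuracy, mean_auc, pooled_auc, roc}
    errors: dict = field(default_factory=dict)

    def accuracy(self, name: str) -> float:
        return self.results[name]["mean_accuracy"]

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        out = {name: plain(res) for name, res in self.results.items()}
        out["_errors"] = dict(self.errors)
        return out


def fit_models(features, labels, cv: CVConfig, groups=None, models: dict | None = None) -> ModelReport:
    """Evaluate the six-model bench under one shared fold assignment.

    ROC curves are computed from held-out decision scores pooled across
    folds. A model that fails is recorded in ``errors``; the rest proceed.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) != 2:
        raise ValueError("binary labels required")
    if groups is None:
        groups = np.arange(len(y))
    folds = cv_partition(groups, y, cv)
    models = build_models(cv.seed) if models is None else models

    results, errors = {}, {}
    for name, model in models.items():
        try:
            perf = cv_evaluate(model, features, y, folds)
        except Exception as exc:  # noqa: BLE001 - per-model failures are reported
            errors[name] = f"{type(exc).__name__}: {exc}"
            continue
        mask = perf.pooled_mask
        fpr, tpr, thresholds = roc_curve(y[mask], perf.pooled_scores[mask])
        pooled_auc = float(roc_auc_score(y[mask], perf.pooled_scores[mask]))
        results[name] = {
            "fold_accuracy": perf.fold_accuracy,
            "mean_accuracy": perf.mean_accuracy,
            "fold_auc": perf.fold_auc,
            "mean_auc": perf.mean_auc,
            "pooled_auc": pooled_auc,
            "roc": {"fpr": fpr, "tpr": tpr, "thresholds": thresholds},
        }
    return ModelReport(results=results, errors=errors)


# ----------------------------------------------------------------------
# importance and pure trees
# ----------------------------------------------------------------------


def _iter_trees(ensemble):
    if hasattr(ensemble, "estimators_"):
        for est in np.asarray(ensemble.estimators_, dtype=object).ravel():
            yield est.tree_
    elif hasattr(ensemble, "tree_"):
        yield ensemble.tree_
    else:
        raise ValueError("not a fitted tree or tree ensemble")


def importance_weights(ensemble, feature_names=None) -> pd.DataFrame:
    """Per-feature weights: the sum over all nodes (all trees) splitting on
    the feature of the node impurity minus the weighted mean impurity of its
    children. Unused features get weight 0; rank 1 is the heaviest.
    """
    if not hasattr(ensemble, "estimators_") and not hasattr(ensemble, "tree_"):
        raise ValueError("not a fitted tree or tree ensemble")
    if hasattr(ensemble, "estimators_") and len(getattr(ensemble, "estimators_", [])) == 0:
        raise ValueError("ensemble is not fitted")
    n_features = ensemble.n_features_in_
    weights = np.zeros(n_features)
    for tree in _iter_trees(ensemble):
        left, right = tree.children_left, tree.children_right
        for node in range(tree.node_count):
            if left[node] == -1:  # leaf
                continue
            n = tree.weighted_n_node_samples[node]
            improvement = tree.impurity[node] - (
                tree.weighted_n_node_samples[left[node]] * tree.impurity[left[node]]
                + tree.weighted_n_node_samples[right[node]] * tree.impurity[right[node]]
            ) / n
            weights[tree.feature[node]] += improvement
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(n_features)]
    table = pd.DataFrame({"weight": weights}, index=pd.Index(feature_names, name="feature"))
    table["rank"] = table["weight"].rank(ascending=False, method="min").astype(int)
    return table.sort_values(["rank", "feature"])


def extract_pure_trees(forest, features, labels, feature_names=None) -> list:
    """Trees of a fitted forest that misclassify none of the supplied samples.

    Returns ``(index, estimator, rules)`` triples where ``rules`` is a
    plain-text rule list exposing the split thresholds.
    """
    from sklearn.tree import export_text

    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]
    pure = []
    for i, est in enumerate(getattr(forest, "estimators_", [])):
        pred = est.predict(x)
        if hasattr(forest, "classes_") and pred.dtype != y.dtype:
            pred = forest.classes_[pred.astype(int)]  # sub-estimators emit encoded classes
        if np.all(pred == y):
            pure.append((i, est, export_text(est, feature_names=list(feature_names))))
    return pure


def subset_sex_chromosomes(expr: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Restrict to genes annotated on chromosome X or Y (order preserved)."""
    if "chromosome" not in annotation.columns:
        raise ValueError("annotation needs a 'chromosome' column")
    missing = expr.gene_ids.difference(annotation.index)
    if len(missing):
        raise KeyError(f"annotation missing gene(s): {missing[:5].tolist()}")
    chrom = annotation.loc[expr.gene_ids, "chromosome"].astype(str)
    keep = expr.gene_ids[chrom.isin(["X", "Y"]).to_numpy()]
    if len(keep) == 0:
        raise ValueError("no sex-chromosome genes in the matrix")
    return expr.subset_genes(keep)
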