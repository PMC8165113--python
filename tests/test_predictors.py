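import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from valvesex import (
    CVConfig,
    GAConfig,
    cv_evaluate,
    cv_partition,
    extract_pure_trees,
    fit_models,
    ga_select,
    importance_weights,
    subset_sex_chromosomes,
)
from valvesex.predictors import build_models, MODEL_NAMES

from conftest import make_expr


class TestCVPartition:
    def test_leave_one_out_when_ungrouped(self):
        labels = np.array([0, 1] * 5)
        cv = CVConfig(k=10, group_by_patient=False, seed=0)
        folds = cv_partition(np.zeros(10), labels, cv)
        assert sorted(folds) == list(range(10))

    def test_patients_never_split(self):
        groups = np.repeat([f"p{i}" for i in range(6)], 2)
        labels = np.tile([0, 1], 6)
        folds = cv_partition(groups, labels, CVConfig(k=3, seed=1))
        frame = pd.DataFrame({"g": groups, "f": folds})
        assert (frame.groupby("g")["f"].nunique() == 1).all()

    def test_fold_sizes_differ_by_at_most_one_group(self):
        groups = np.array([f"p{i}" for i in range(13)])
        labels = np.array([0, 1] * 6 + [0])
        folds = cv_partition(groups, labels, CVConfig(k=4, seed=2))
        sizes = pd.Series(folds).value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert set(folds) == {0, 1, 2, 3}

    def test_k_exceeding_groups_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            cv_partition(np.array(["a", "a", "b"]), np.array([0, 1, 0]), CVConfig(k=3))

    def test_grouped_no_leakage_exhaustive(self, strong_cohort):
        _, _, expr, _ = strong_cohort
        keep = expr.samples["tissue"].isin(["calcified", "nondiseased"]).to_numpy()
        sub = expr.subset_samples(expr.sample_ids[keep])
        groups = sub.samples["patient_id"].to_numpy()
        y = (sub.samples["tissue"] == "calcified").astype(int).to_numpy()
        folds = cv_partition(groups, y, CVConfig(k=6, seed=3))
        for f in np.unique(folds):
            train_patients = set(groups[folds != f])
            test_patients = set(groups[folds == f])
            assert not (train_patients & test_patients)


class TestCVEvaluate:
    def test_constant_features_hit_majority_baseline(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 35 + [0] * 15)
        x = np.ones((50, 3))
        folds = cv_partition(np.arange(50), y, CVConfig(k=5, group_by_patient=False, seed=0))
        perf = cv_evaluate(LogisticRegression(), x, y, folds)
        majority = 0.7
        se = np.sqrt(majority * (1 - majority) / 50)
        assert abs(perf.mean_accuracy - majority) < 3 * se + 0.05

    def test_separable_data_perfect(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 20)
        x = np.column_stack([y * 10 + rng.normal(0, 0.1, 40), rng.normal(size=40)])
        folds = cv_partition(np.arange(40), y, CVConfig(k=4, group_by_patient=False, seed=0))
        for model in (RandomForestClassifier(n_estimators=20, random_state=0), LogisticRegression()):
            perf = cv_evaluate(model, x, y, folds)
            assert perf.mean_accuracy == 1.0

    def test_manual_fold_loop_reproduces_mean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, size=30)
        folds = cv_partition(np.arange(30), y, CVConfig(k=5, group_by_patient=False, seed=0))
        model = RandomForestClassifier(n_estimators=15, random_state=7)
        perf = cv_evaluate(model, x, y, folds)
        accs = []
        for f in np.unique(folds):
            m = RandomForestClassifier(n_estimators=15, random_state=7)
            m.fit(x[folds != f], y[folds != f])
            accs.append(np.mean(m.predict(x[folds == f]) == y[folds == f]))
        assert perf.mean_accuracy == pytest.approx(np.mean(accs), abs=1e-12)

    def test_single_class_training_fold_skipped(self):
        x = np.arange(4, dtype=float).reshape(-1, 1)
        y = np.array([0, 1, 0, 0])
        folds = np.array([0, 0, 1, 2])  # fold 0's complement is all class 0
        with pytest.warns(UserWarning, match="single-class"):
            perf = cv_evaluate(LogisticRegression(), x, y, folds)
        assert len(perf.fold_accuracy) == 2


def _xor_toy(n=40, n_noise=4, seed=0):
    """Two features jointly (not individually) predictive of the label."""
    rng = np.random.default_rng(seed)
    s1 = rng.integers(0, 2, n)
    s2 = rng.integers(0, 2, n)
    y = s1 ^ s2
    x = np.column_stack(
        [s1.astype(float), s2.astype(float)] + [rng.normal(size=n) for _ in range(n_noise)]
    )
    return x, y


def _exhaustive_best(x, y, folds, rf_seed):
    """Oracle: evaluate every nonempty feature subset with the same fitness."""
    n = x.shape[1]
    forest = RandomForestClassifier(n_estimators=10, random_state=rf_seed)
    best_fit, best_masks = -1.0, []
    for bits in itertools.product([0, 1], repeat=n):
        mask = np.array(bits, dtype=bool)
        if not mask.any():
            continue
        fit = cv_evaluate(forest, x[:, mask], y, folds).mean_accuracy
        if fit > best_fit + 1e-12:
            best_fit, best_masks = fit, [mask]
        elif abs(fit - best_fit) <= 1e-12:
            best_masks.append(mask)
    return best_fit, best_masks


class TestGASelect:
    def test_degenerate_single_generation_is_argmax(self):
        x, y = _xor_toy(n=30, n_noise=1, seed=3)
        cv = CVConfig(k=3, group_by_patient=False, seed=0)
        singletons = np.eye(3, dtype=bool)
        ga = GAConfig(population_size=3, generations=1, mutation_prob=0.0,
                      crossover_prob=0.0, elitism=1, rf_n_estimators=10, seed=0)
        res = ga_select(x, y, ga, cv, initial_population=singletons)
        folds = cv_partition(np.arange(len(y)), y, cv)
        forest = RandomForestClassifier(n_estimators=10, random_state=0)
        fits = [
            cv_evaluate(forest, x[:, m], y, folds).mean_accuracy for m in singletons
        ]
        assert res.best_fitness == pytest.approx(max(fits), abs=1e-12)
        assert res.best_mask.sum() == 1
        assert res.best_mask[int(np.argmax(fits))]

    def test_elitism_monotone_history(self):
        x, y = _xor_toy(seed=4)
        ga = GAConfig(population_size=8, generations=6, elitism=2, rf_n_estimators=10, seed=1)
        res = ga_select(x, y, ga, CVConfig(k=3, group_by_patient=False, seed=0))
        assert res.history == sorted(res.history)

    def test_recovers_exhaustive_optimum(self):
        """The informative pair is found in >= 90% of seeded runs."""
        x, y = _xor_toy(n=36, n_noise=4, seed=5)
        cv = CVConfig(k=3, group_by_patient=False, seed=0)
        folds = cv_partition(np.arange(len(y)), y, cv)
        best_fit, best_masks = _exhaustive_best(x, y, folds, rf_seed=0)
        assert all(m[0] and m[1] for m in best_masks)  # pair is required at optimum

        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            ga = GAConfig(population_size=14, generations=12, rf_n_estimators=10, seed=seed)
            res = ga_select(x, y, ga, cv)
            if res.best_fitness >= best_fit - 1e-12 and res.best_mask[0] and res.best_mask[1]:
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_empty_mask_fitness_zero(self):
        x, y = _xor_toy(n=20, n_noise=0, seed=6)
        ga = GAConfig(population_size=2, generations=1, mutation_prob=0.0,
                      crossover_prob=0.0, elitism=0, rf_n_estimators=5, seed=0)
        pop = np.array([[False, False], [True, True]])
        res = ga_select(x, y, ga, CVConfig(k=2, group_by_patient=False, seed=0),
                        initial_population=pop)
        assert res.best_mask.any()  # empty mask can never win


class TestFitModels:
    def test_random_labels_near_chance_auc(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 5))
        y = rng.integers(0, 2, 50)
        models = build_models(0, names=("logistic", "knn", "naive_bayes", "random_forest"))
        report = fit_models(x, y, CVConfig(k=5, group_by_patient=False, seed=0), models=models)
        se = 1.0 / np.sqrt(12 * 25)  # rough AUC null SE at n=50 balanced-ish
        for name, res in report.results.items():
            assert abs(res["pooled_auc"] - 0.5) < 3 * se + 0.1, name

    def test_separated_classes_all_trees_perfect(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 24)
        x = np.column_stack([y * 8 + rng.normal(0, 0.2, 48), rng.normal(size=48)])
        report = fit_models(x, y, CVConfig(k=6, group_by_patient=False, seed=0))
        for name in ("random_forest", "gradient_boosted_trees"):
            assert report.results[name]["mean_accuracy"] == 1.0

    def test_perfect_scorer_roc_hits_corner(self):
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1], 20)
        x = np.column_stack([y * 5 + rng.normal(0, 0.1, 40)])
        report = fit_models(
            x, y, CVConfig(k=4, group_by_patient=False, seed=0),
            models=build_models(0, names=("logistic",)),
        )
        roc = report.results["logistic"]["roc"]
        pts = set(zip(roc["fpr"].round(9), roc["tpr"].round(9)))
        assert (0.0, 1.0) in pts
        assert report.results["logistic"]["roc"]["fpr"][0] == 0.0

    def test_all_six_models_present(self, strong_cohort):
        _, _, expr, truth = strong_cohort
        keep = expr.samples["tissue"].isin(["calcified", "nondiseased"]).to_numpy()
        sub = expr.subset_samples(expr.sample_ids[keep])
        planted = truth.index[truth["role"] == "interaction"]
        x = sub.subset_genes(planted).values.to_numpy().T
        y = (sub.samples["tissue"] == "calcified").astype(int).to_numpy()
        report = fit_models(x, y, CVConfig(k=6, seed=0), groups=sub.samples["patient_id"].to_numpy())
        assert set(report.results) == set(MODEL_NAMES)
        assert not report.errors

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            fit_models(np.zeros((6, 2)), np.array([0, 1, 2, 0, 1, 2]), CVConfig(k=2))


class TestImportanceWeights:
    def test_unused_feature_zero(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 10)
        x = np.column_stack([y * 4.0, np.zeros(20)])  # second feature constant
        tree = DecisionTreeClassifier(random_state=0).fit(x, y)
        table = importance_weights(tree)
        assert table.loc["f1", "weight"] == 0.0

    def test_stump_hand_gini(self):
        # 4 samples, 2 per class, perfect split: 0.5 - 0 = 0.5
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        stump = DecisionTreeClassifier(max_depth=1, random_state=0).fit(x, y)
        table = importance_weights(stump)
        assert table.loc["f0", "weight"] == pytest.approx(0.5)

    def test_matches_brute_force_traversal(self):
        """Oracle: recompute Gini improvements from raw sample routing."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=(60, 5))
        y = (x[:, 0] + 0.5 * x[:, 2] + rng.normal(0, 0.5, 60) > 0).astype(int)
        forest = RandomForestClassifier(
            n_estimators=5, bootstrap=False, random_state=0
        ).fit(x, y)
        expected = np.zeros(5)

        def gini(labels):
            if len(labels) == 0:
                return 0.0
            p = np.bincount(labels, minlength=2) / len(labels)
            return 1.0 - np.sum(p**2)

        for est in forest.estimators_:
            t = est.tree_

            def walk(node, idx):
                if t.children_left[node] == -1:
                    return
                f, thr = t.feature[node], t.threshold[node]
                left = idx[x[idx, f] <= thr]
                right = idx[x[idx, f] > thr]
                improvement = gini(y[idx]) - (
                    len(left) * gini(y[left]) + len(right) * gini(y[right])
                ) / len(idx)
                expected[f] += improvement
                walk(t.children_left[node], left)
                walk(t.children_right[node], right)

            walk(0, np.arange(60))

        table = importance_weights(forest)
        got = table.sort_index()["weight"].to_numpy()
        assert np.allclose(got, expected, atol=1e-10)

    def test_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(40, 3))
        y = (x[:, 1] > 0).astype(int)
        t1 = importance_weights(DecisionTreeClassifier(random_state=0).fit(x, y))
        perm = [2, 0, 1]
        t2 = importance_weights(DecisionTreeClassifier(random_state=0).fit(x[:, perm], y))
        for new_pos, old_pos in enumerate(perm):
            assert t2.loc[f"f{new_pos}", "weight"] == pytest.approx(
                t1.loc[f"f{old_pos}", "weight"], abs=1e-10
            )

    def test_unfitted_rejected(self):
        with pytest.raises(ValueError):
            importance_weights(RandomForestClassifier())


class TestExtractPureTrees:
    def test_perfect_stump_returned(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        forest = RandomForestClassifier(n_estimators=1, bootstrap=False, random_state=0).fit(x, y)
        pure = extract_pure_trees(forest, x, y)
        assert len(pure) == 1
        assert "f0" in pure[0][2]  # rule text mentions the split feature

    def test_matches_per_tree_oracle(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=(30, 3))
        y = rng.integers(0, 2, 30)
        forest = RandomForestClassifier(n_estimators=5, max_depth=2, random_state=1).fit(x, y)
        pure = extract_pure_trees(forest, x, y)
        expected = [
            i for i, est in enumerate(forest.estimators_)
            if np.all(est.predict(x) == y)
        ]
        assert [i for i, _, _ in pure] == expected

    def test_empty_when_no_tree_is_pure(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(40, 2))
        y = rng.integers(0, 2, 40)
        forest = RandomForestClassifier(n_estimators=3, max_depth=1, random_state=2).fit(x, y)
        pure = extract_pure_trees(forest, x, y)
        for i, _, _ in pure:
            assert np.all(forest.estimators_[i].predict(x) == y)


class TestSubsetSexChromosomes:
    def _annotation(self, chroms):
        return pd.DataFrame(
            {"symbol": [f"G{i}" for i in range(len(chroms))], "chromosome": chroms},
            index=pd.Index([f"g{i}" for i in range(len(chroms))], name="gene_id"),
        )

    def _expr(self, n):
        samples = [("s0", "p0", "M", "nondiseased"), ("s1", "p0", "M", "calcified")]
        return make_expr({f"g{i}": [float(i), float(i)] for i in range(n)}, samples)

    def test_counts(self):
        ann = self._annotation(["1", "X", "2", "X", "Y", "3", "X", "4", "5", "6"])
        out = subset_sex_chromosomes(self._expr(10), ann)
        assert out.n_genes == 4

    def test_all_autosomal_rejected(self):
        ann = self._annotation(["1", "2", "3"])
        with pytest.raises(ValueError, match="sex-chromosome"):
            subset_sex_chromosomes(self._expr(3), ann)

    def test_all_x_is_identity(self):
        ann = self._annotation(["X", "X"])
        out = subset_sex_chromosomes(self._expr(2), ann)
        assert list(out.gene_ids) == ["g0", "g1"]

    def test_missing_annotation_rejected(self):
        ann = self._annotation(["X"])
        with pytest.raises(KeyError):
            subset_sex_chromosomes(self._expr(2), ann)
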