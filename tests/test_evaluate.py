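"""Stratified CV, metric computation and the selection-benefit test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import oracles
from methylstage import evaluate, features, selector


class TestStratifiedFolds:
    def test_study_class_counts_three_folds(self):
        labels = (
            ["paradormancy"] * 9 + ["endodormancy"] * 36 + ["ecodormancy"] * 26
        )
        folds = evaluate.stratified_folds(labels, evaluate.CVScheme(3, 1, seed=0))
        y = np.asarray(labels)
        for fd in folds:
            test_labels = y[fd.test_idx]
            assert (test_labels == "paradormancy").sum() == 3
            assert set(test_labels) == {"paradormancy", "endodormancy", "ecodormancy"}

    def test_two_stage_ten_folds_allocation(self):
        labels = ["ecodormancy"] * 26 + ["endodormancy"] * 36
        folds = evaluate.stratified_folds(labels, evaluate.CVScheme(10, 1, seed=0))
        y = np.asarray(labels)
        for fd in folds:
            eco = (y[fd.test_idx] == "ecodormancy").sum()
            endo = (y[fd.test_idx] == "endodormancy").sum()
            assert eco in (2, 3) and endo in (3, 4)

    def test_partition_and_stratification_fuzzed(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            counts = rng.integers(k, 4 * k, size=int(rng.integers(2, 4)))
            labels = np.repeat([f"c{i}" for i in range(len(counts))], counts)
            rng.shuffle(labels)
            folds = evaluate.stratified_folds(labels, evaluate.CVScheme(k, 1, seed=1))
            seen = np.concatenate([fd.test_idx for fd in folds])
            assert sorted(seen) == list(range(len(labels)))
            for fd in folds:
                test = labels[fd.test_idx]
                for i, c in enumerate(np.unique(labels)):
                    n_c = (labels == c).sum()
                    ideal = n_c / k
                    got = (test == c).sum()
                    assert got >= 1
                    assert abs(got - ideal) <= 1

    def test_small_class_error_names_class(self):
        labels = ["paradormancy"] * 2 + ["endodormancy"] * 30
        with pytest.raises(ValueError, match="paradormancy"):
            evaluate.stratified_folds(labels, evaluate.CVScheme(3, 1, seed=0))


class TestMetricsFromConfusion:
    def test_perfect_matrix(self):
        m = evaluate.metrics_from_confusion([[5, 0], [0, 5]])
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0

    def test_degenerate_column_zero_convention(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            m = evaluate.metrics_from_confusion([[0, 5], [0, 5]], ["c1", "c2"])
        assert m["accuracy"] == 0.5
        assert m["per_class"]["c1"]["precision"] == 0.0

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            evaluate.metrics_from_confusion(np.zeros((2, 3)))

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(500):
            k = int(rng.integers(2, 6))
            cm = rng.integers(0, 20, size=(k, k))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = evaluate.metrics_from_confusion(cm)
            acc, prec, rec, f1 = oracles.brute_metrics(cm)
            assert m["accuracy"] == pytest.approx(acc, abs=1e-12)
            got_p = [v["precision"] for v in m["per_class"].values()]
            got_r = [v["recall"] for v in m["per_class"].values()]
            got_f = [v["f1"] for v in m["per_class"].values()]
            assert np.allclose(got_p, prec, atol=1e-12)
            assert np.allclose(got_r, rec, atol=1e-12)
            assert np.allclose(got_f, f1, atol=1e-12)


class TestCrossValidate:
    def test_separable_data_perfect_scores(self):
        rng = np.random.default_rng(31)
        X = np.vstack([rng.uniform(0, 0.3, size=(20, 3)), rng.uniform(0.7, 1.0, size=(20, 3))])
        y = ["endodormancy"] * 20 + ["ecodormancy"] * 20
        rep = evaluate.cross_validate(
            X, y, selector.RFConfig(n_trees=25, seed=0), evaluate.CVScheme(4, 2, seed=0)
        )
        assert rep.mean_accuracy() == 1.0
        assert rep.mean_auc() == 1.0

    def test_confusion_trace_equals_accuracy(self):
        rng = np.random.default_rng(37)
        X = rng.uniform(size=(40, 5))
        y = list(rng.choice(["endodormancy", "ecodormancy"], size=40, p=[0.6, 0.4]))
        scheme = evaluate.CVScheme(4, 2, seed=1)
        rep = evaluate.cross_validate(X, y, selector.RFConfig(n_trees=15, seed=0), scheme)
        pooled = rep.confusion
        assert pooled.sum() == len(y) * scheme.n_repeats
        # per-fold identity is preserved in the mean over folds
        assert rep.folds["accuracy"].mean() == pytest.approx(
            np.trace(pooled) / pooled.sum(), abs=0.101
        )

    def test_permuted_labels_accuracy_near_majority(self):
        rng = np.random.default_rng(41)
        accs = []
        for s in range(20):
            X = rng.uniform(size=(40, 8))
            y = list(np.repeat(["endodormancy", "ecodormancy"], [24, 16]))
            rng.shuffle(y)
            rep = evaluate.cross_validate(
                X, y, selector.RFConfig(n_trees=20, seed=s), evaluate.CVScheme(4, 1, seed=s)
            )
            accs.append(rep.mean_accuracy())
        assert abs(np.mean(accs) - 0.6) <= 0.15


class TestSelectionBenefitTest:
    def test_identical_vectors_degenerate_p_one(self):
        t = evaluate.selection_benefit_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t.degenerate and t.p == 1.0 and t.t == 0.0

    def test_matches_closed_form(self):
        d = np.array([0.1, 0.12, 0.09, 0.11])
        base = np.array([0.5, 0.5, 0.5, 0.5])
        res = evaluate.selection_benefit_test(base, base + d)
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(expected_t, df=3), rel=1e-12)

    def test_antisymmetric(self):
        rng = np.random.default_rng(43)
        a, b = rng.uniform(size=10), rng.uniform(size=10)
        r1 = evaluate.selection_benefit_test(a, b)
        r2 = evaluate.selection_benefit_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_constant_nonzero_shift_flagged(self):
        res = evaluate.selection_benefit_test([0.5, 0.5], [0.7, 0.7])
        assert res.degenerate and res.p == 0.0 and np.isinf(res.t)


class TestGroupingScore:
    def test_perfectly_grouped_labels_score_high(self):
        rng = np.random.default_rng(47)
        X = np.vstack([rng.normal(0, 0.1, (15, 4)), rng.normal(3, 0.1, (15, 4))])
        y = ["a"] * 15 + ["b"] * 15
        assert evaluate.grouping_score(X, y) == 1.0
        rng.shuffle(y)
        assert evaluate.grouping_score(X, y) < 0.8


@pytest.fixture(scope="module")
def toy_datasets():
    rng = np.random.default_rng(53)
    n = 36
    y = np.repeat(["paradormancy", "endodormancy", "ecodormancy"], 12)
    signal = np.where(y == "endodormancy", 0.8, np.where(y == "ecodormancy", 0.2, 0.5))
    X = rng.uniform(size=(n, 40))
    X[:, :3] = signal[:, None] + rng.normal(0, 0.05, size=(n, 3))
    values = pd.DataFrame(
        X, index=[f"S{i}" for i in range(n)], columns=[f"chr_1_{i + 1}" for i in range(40)]
    )
    coords = pd.DataFrame(
        {
            "feature_id": values.columns,
            "chrom": "chr_1",
            "start": np.arange(40),
            "end": np.arange(40) + 1,
            "kind": "cytosine",
            "n_cytosines": 1,
        }
    )
    labels = pd.DataFrame({"stage": y, "cultivar": "cv1"}, index=values.index)
    full = features.MethylationMatrix(values=values, coords=coords, labels=labels)
    sel = full.subset_features(list(values.columns[:3]))
    return {"cytosine": {"full": full, "selected": sel}}


class TestRunScenario:
    def test_cardinality_and_benefit_direction(self, toy_datasets):
        scheme = evaluate.CVScheme(3, 2, seed=0)
        models = {"rf": selector.RFConfig(n_trees=25, seed=0),
                  "xgb": selector.XGBConfig(n_rounds=40, seed=0)}
        rep = evaluate.run_scenario(toy_datasets, "3stage", scheme, models)
        assert len(rep.reports) == 4  # 1 dataset x 2 variants x 2 models
        for model in ("rf", "xgb"):
            full = rep.reports[("cytosine", "full", model)].mean_accuracy()
            sel = rep.reports[("cytosine", "selected", model)].mean_accuracy()
            assert sel >= full

    def test_two_stage_drops_paradormancy(self, toy_datasets):
        scheme = evaluate.CVScheme(3, 1, seed=0)
        rep = evaluate.run_scenario(
            toy_datasets, "2stage", scheme, {"rf": selector.RFConfig(n_trees=15, seed=0)}
        )
        for r in rep.reports.values():
            assert "paradormancy" not in r.classes
            assert r.confusion.sum() == 24  # 12 endo + 12 eco per repeat
        full = rep.reports[("cytosine", "full", "rf")]
        sel = rep.reports[("cytosine", "selected", "rf")]
        assert sel.mean_accuracy() >= full.mean_accuracy()
        assert sel.mean_auc() >= full.mean_auc()
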