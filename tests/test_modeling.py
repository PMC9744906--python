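"""Split plans, undersampling, metric definitions, tuning contract and
leakage guards."""

import math

import numpy as np
import pandas as pd
import pytest

from icp_horizon.modeling import (DEFAULT_PARAMS, FAMILIES, LeakageError,
                                  evaluate, make_splits, score_metrics,
                                  tune_and_fit)
from icp_horizon.search import Integer, Real, smbo_minimize


def _table(n_cases, n_controls, n_features=4, seed=0, separation=0.0):
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    labels = ["case"] * n_cases + ["control"] * n_controls
    df = pd.DataFrame({
        "segment_id": [f"s{i}" for i in range(n)],
        "patient_id": [f"p{i % 7}" for i in range(n)],
        "label": labels,
    })
    for j in range(n_features):
        x = rng.normal(0, 1, n)
        x[:n_cases] += separation
        df[f"ICP__f{j}"] = x
    return df


class TestMakeSplits:
    def test_221_segments_split_154_67(self):
        plans = make_splits(_table(21, 200), n_iter=3, seed=1)
        for p in plans:
            assert len(p.train_ids) == 154
            assert len(p.test_ids) == 67
            assert not set(p.train_ids) & set(p.test_ids)

    def test_fixed_seed_reproducible(self):
        a = make_splits(_table(21, 200), n_iter=10, seed=5)
        b = make_splits(_table(21, 200), n_iter=10, seed=5)
        for pa, pb in zip(a, b):
            assert pa.train_ids == pb.train_ids
            assert pa.undersampled_ids == pb.undersampled_ids

    def test_undersampled_subset_is_one_to_one(self):
        table = _table(21, 200)
        labels = dict(zip(table.segment_id, table.label))
        for p in make_splits(table, n_iter=5, seed=2):
            under = [labels[s] for s in p.undersampled_ids]
            assert under.count("case") == under.count("control")
            assert set(p.undersampled_ids) <= set(p.train_ids)

    def test_test_set_keeps_natural_imbalance(self):
        table = _table(21, 200)
        labels = dict(zip(table.segment_id, table.label))
        for p in make_splits(table, n_iter=5, seed=2):
            test = [labels[s] for s in p.test_ids]
            prev = test.count("case") / len(test)
            assert 0.05 <= prev <= 0.15

    def test_too_few_cases_errors(self):
        with pytest.raises(ValueError, match="cases"):
            make_splits(_table(1, 50), n_iter=2, seed=0)

    def test_patient_grouped_mode(self):
        table = _table(21, 200)
        for p in make_splits(table, n_iter=3, seed=3,
                             group_by_patient=True):
            pat = dict(zip(table.segment_id, table.patient_id))
            train_p = {pat[s] for s in p.train_ids}
            test_p = {pat[s] for s in p.test_ids}
            assert not train_p & test_p


class TestMetrics:
    def test_auroc_three_of_four_pairs_concordant(self):
        m = score_metrics([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2])
        assert m["auroc"] == pytest.approx(0.75)

    def test_perfect_scorer(self):
        m = score_metrics([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2])
        assert m["auroc"] == 1.0
        assert m["auprc"] == 1.0
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_random_scores_auprc_near_prevalence(self):
        """With random scores, average precision converges to the test
        prevalence -- the no-skill AUPRC baseline (~0.095 at a 21:200
        case:control mix, consistent with a 0.10 expected baseline)."""
        rng = np.random.default_rng(42)
        prevalence = 21 / 221
        n = 10_000
        y = (rng.random(n) < prevalence).astype(int)
        m = score_metrics(y, rng.random(n))
        assert m["auprc"] == pytest.approx(prevalence, abs=0.02)
        assert abs(m["auprc"] - 0.10) < 0.03
        assert m["auroc"] == pytest.approx(0.5, abs=0.03)

    def test_single_class_test_undefined(self):
        m = score_metrics([0, 0, 0], [0.2, 0.4, 0.6])
        assert math.isnan(m["auroc"]) and math.isnan(m["auprc"])

    def test_threshold_metrics(self):
        m = score_metrics([1, 0, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["ppv"] == 0.5
        assert m["npv"] == 1.0


class TestTuneAndFit:
    def test_budget_one_returns_family_defaults(self):
        train = _table(10, 10, separation=2.0)
        model = tune_and_fit("xgb", train, budget=1, seed=0)
        assert model.params == DEFAULT_PARAMS["xgb"]

    def test_fixed_seed_fixed_budget_same_hyperparameters(self):
        train = _table(12, 12, separation=1.0, seed=3)
        a = tune_and_fit("lr", train, budget=6, seed=9)
        b = tune_and_fit("lr", train, budget=6, seed=9)
        assert a.params == b.params

    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_training_auroc_one(self, family):
        train = _table(15, 15, separation=8.0, seed=1)
        model = tune_and_fit(family, train, budget=1, seed=0)
        m = evaluate(model, train)
        assert m["auroc"] == 1.0

    def test_single_class_training_errors(self):
        bad = _table(0, 20)
        with pytest.raises(ValueError):
            tune_and_fit("lr", bad, budget=1, seed=0)

    def test_leakage_guard_raises(self):
        train = _table(10, 10)
        with pytest.raises(LeakageError):
            tune_and_fit("lr", train, budget=1, seed=0,
                         forbidden_ids={"s3"})


class TestSearch:
    def test_smbo_deterministic_and_improves(self):
        space = [Real("x", -2.0, 2.0), Integer("k", 1, 10)]

        def objective(p):
            return (p["x"] - 0.7) ** 2 + 0.01 * (p["k"] - 4) ** 2

        best1, hist1 = smbo_minimize(objective, space, n_calls=20, seed=3)
        best2, _ = smbo_minimize(objective, space, n_calls=20, seed=3)
        assert best1 == best2
        init_best = min(v for _, v in hist1[:8])
        assert min(v for _, v in hist1) <= init_best
        assert abs(best1["x"] - 0.7) < 0.5
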