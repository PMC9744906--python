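"""Imbalance-aware Monte-Carlo benchmarking of four classifier families.

For each analysis window the labeled feature table is split 70/30 into
training and test sets ten times (Monte-Carlo iterations).  Within each
training set the heavy control excess is removed by random undersampling to
a 1:1 case:control ratio; hyperparameters are then chosen by sequential
model-based search on an inner validation split of the (undersampled)
training data, and the tuned model is scored on the untouched test set,
which keeps its natural imbalance.  Metrics: AUROC, AUPRC (average
precision), and sensitivity/specificity/PPV/NPV at a 0.5 probability
threshold, summarized across iterations as mean with a normal-approximation
95% CI.

Undefined feature values (NaN markers) are median-imputed inside the
LR/SVM pipelines; the tree families consume the marker natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import ID_COLUMNS
from .search import Integer, Real, smbo_minimize

FAMILIES = ("lr", "svm", "rf", "xgb")

SEARCH_SPACES = {
    "lr": [Real("C", 1e-3, 1e3, log=True)],
    "svm": [Real("C", 1e-2, 1e3, log=True),
            Real("gamma", 1e-4, 1e1, log=True)],
    "rf": [Integer("n_estimators", 50, 300),
           Integer("max_depth", 2, 10),
           Integer("min_samples_leaf", 1, 8),
           Real("max_features", 0.2, 1.0)],
    "xgb": [Integer("n_estimators", 50, 300),
            Integer("max_depth", 2, 6),
            Real("learning_rate", 0.01, 0.3, log=True),
            Real("subsample", 0.5, 1.0),
            Real("colsample_bytree", 0.3, 1.0),
            Integer("min_child_weight", 1, 8)],
}

DEFAULT_PARAMS = {
    "lr": {"C": 1.0},
    "svm": {"C": 1.0, "gamma": "scale"},
    "rf": {"n_estimators": 200, "max_depth": 6, "min_samples_leaf": 2,
           "max_features": 0.5},
    "xgb": {"n_estimators": 150, "max_depth": 3, "learning_rate": 0.1,
            "subsample": 0.9, "colsample_bytree": 0.8,
            "min_child_weight": 1},
}


class LeakageError(RuntimeError):
    """Raised when a fit is attempted on rows reserved for testing."""


@dataclass
class SplitPlan:
    """One Monte-Carlo 70/30 split with a 1:1 undersampled training subset."""

    iteration: int
    train_ids: list[str]
    test_ids: list[str]
    undersampled_ids: list[str]
    seed: int


@dataclass
class FittedModel:
    family: str
    estimator: object
    params: dict
    feature_names: list[str]

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(X[self.feature_names])[:, 1]


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate one classifier family with the given hyperparameters."""
    if family == "lr":
        return Pipeline([
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed,
                                       **params)),
        ])
    if family == "svm":
        return Pipeline([
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", probability=True, random_state=seed,
                        **params)),
        ])
    if family == "rf":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "xgb":
        return XGBClassifier(random_state=seed, eval_metric="logloss",
                             n_jobs=1, tree_method="hist", **params)
    raise ValueError(f"unknown model family: {family}")


def feature_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    cols = [c for c in table.columns if c not in ID_COLUMNS]
    X = table[cols]
    y = (table["label"] == "case").to_numpy(dtype=int)
    return X, y


def make_splits(table: pd.DataFrame, n_iter: int = 10,
                train_frac: float = 0.70, seed: int = 0,
                group_by_patient: bool = False) -> list[SplitPlan]:
    """Monte-Carlo segment-level splits, stratified by label; the training
    subset is undersampled to all cases plus an equal count of controls.

    ``group_by_patient`` instead assigns whole patients to train or test
    (offered because sample-level splitting lets one patient straddle both
    sides).
    """
    ids = table["segment_id"].to_numpy()
    labels = (table["label"] == "case").to_numpy()
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases < 2 or n_controls < 2:
        raise ValueError(
            f"need >= 2 cases and >= 2 controls; got {n_cases} cases "
            f"and {n_controls} controls")
    rng = np.random.default_rng(seed)
    plans: list[SplitPlan] = []
    for it in range(1, n_iter + 1):
        it_seed = int(rng.integers(2**31))
        if group_by_patient:
            patients = table["patient_id"].unique()
            prng = np.random.default_rng(it_seed)
            prng.shuffle(patients)
            n_train_p = int(math.floor(train_frac * len(patients)))
            train_p = set(patients[:n_train_p])
            in_train = table["patient_id"].isin(train_p).to_numpy()
            train_ids, test_ids = ids[in_train], ids[~in_train]
        else:
            train_ids, test_ids = train_test_split(
                ids, train_size=train_frac, stratify=labels,
                random_state=it_seed % (2**32 - 1))
        train_mask = np.isin(ids, train_ids)
        case_ids = ids[train_mask & labels]
        ctrl_ids = ids[train_mask & ~labels]
        srng = np.random.default_rng(it_seed + 1)
        chosen = srng.choice(ctrl_ids, size=min(len(case_ids), len(ctrl_ids)),
                             replace=False)
        under = np.concatenate([case_ids, chosen])
        plans.append(SplitPlan(iteration=it,
                               train_ids=list(train_ids),
                               test_ids=list(test_ids),
                               undersampled_ids=list(under),
                               seed=it_seed))
    return plans


def tune_and_fit(family: str, train: pd.DataFrame, budget: int = 25,
                 seed: int = 0, forbidden_ids: set[str] | None = None,
                 ) -> FittedModel:
    """Hyperparameter search on an inner validation split, then refit.

    ``forbidden_ids`` is a leakage guard: segment ids reserved for testing
    must never appear in the training table.
    """
    if forbidden_ids:
        leaked = set(train["segment_id"]) & set(forbidden_ids)
        if leaked:
            raise LeakageError(f"test segments in training data: {leaked}")
    X, y = feature_matrix(train)
    if len(np.unique(y)) < 2:
        raise ValueError("training subset contains a single class")
    feature_names = list(X.columns)

    if budget <= 1:
        params = dict(DEFAULT_PARAMS[family])
    else:
        # inner validation: stratified 3-fold CV AUROC on the training
        # subset only (a single small held-out split is too noisy to
        # rank hyperparameters at this cohort size)
        skf = StratifiedKFold(n_splits=3, shuffle=True,
                              random_state=seed % (2**32 - 1))
        folds = list(skf.split(X, y))

        def objective(params: dict) -> float:
            aucs = []
            for tr, val in folds:
                est = build_estimator(family, params, seed=seed)
                est.fit(X.iloc[tr], y[tr])
                scores = est.predict_proba(X.iloc[val])[:, 1]
                aucs.append(roc_auc_score(y[val], scores))
            return -float(np.mean(aucs))

        params, _ = smbo_minimize(objective, SEARCH_SPACES[family],
                                  n_calls=budget, seed=seed)
    est = build_estimator(family, params, seed=seed)
    est.fit(X, y)
    return FittedModel(family=family, estimator=est, params=params,
                       feature_names=feature_names)


METRIC_NAMES = ("auroc", "auprc", "sensitivity", "specificity", "ppv", "npv")


def evaluate(model: FittedModel, test: pd.DataFrame,
             threshold: float = 0.5) -> dict[str, float]:
    """Test-set metrics; single-class tests yield NaN rank metrics."""
    X, y = feature_matrix(test)
    scores = model.predict_proba(test)
    return score_metrics(y, scores, threshold=threshold)


def score_metrics(y: np.ndarray, scores: np.ndarray,
                  threshold: float = 0.5) -> dict[str, float]:
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    out: dict[str, float] = {}
    if len(np.unique(y)) < 2:
        out["auroc"] = math.nan
        out["auprc"] = math.nan
    else:
        out["auroc"] = float(roc_auc_score(y, scores))
        out["auprc"] = float(average_precision_score(y, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    out["sensitivity"] = tp / (tp + fn) if tp + fn else math.nan
    out["specificity"] = tn / (tn + fp) if tn + fp else math.nan
    out["ppv"] = tp / (tp + fp) if tp + fp else math.nan
    out["npv"] = tn / (tn + fn) if tn + fn else math.nan
    return out


@dataclass
class BenchmarkResult:
    """Raw per-iteration metrics, their across-iteration summary, and the
    fitted XGB bundles kept for attribution."""

    raw: pd.DataFrame
    summary: pd.DataFrame
    xgb_bundles: dict[tuple[int, int], tuple[FittedModel, pd.DataFrame]] = \
        field(default_factory=dict, repr=False)
    split_plans: list[SplitPlan] = field(default_factory=list, repr=False)


def summarize(raw: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% CI (mean +/- 1.96 * SE) per (family, window, metric)."""
    rows = []
    for (family, window), grp in raw.groupby(["family", "window"]):
        for metric in METRIC_NAMES:
            vals = grp[metric].dropna().to_numpy()
            if len(vals) == 0:
                mean = lo = hi = math.nan
            else:
                mean = float(np.mean(vals))
                se = (float(np.std(vals, ddof=1)) / math.sqrt(len(vals))
                      if len(vals) > 1 else 0.0)
                lo = max(mean - 1.96 * se, 0.0)
                hi = min(mean + 1.96 * se, 1.0)
            rows.append({"family": family, "window": window,
                         "metric": metric, "mean": mean,
                         "ci_lo": lo, "ci_hi": hi, "n_iter": len(vals)})
    return pd.DataFrame(rows)


def benchmark(tables: dict[int, pd.DataFrame],
              families: tuple[str, ...] = FAMILIES, n_iter: int = 10,
              train_frac: float = 0.70, budget: int = 25, seed: int = 0,
              threshold: float = 0.5, group_by_patient: bool = False,
              keep_bundles: bool = True) -> BenchmarkResult:
    """Full (family x window x iteration) benchmark grid.

    The same ten segment-level splits are reused across windows and
    families so comparisons share common random numbers.
    """
    first = tables[min(tables)]
    plans = make_splits(first, n_iter=n_iter, train_frac=train_frac,
                        seed=seed, group_by_patient=group_by_patient)
    records = []
    bundles: dict[tuple[int, int], tuple[FittedModel, pd.DataFrame]] = {}
    for w, table in sorted(tables.items()):
        indexed = table.set_index("segment_id", drop=False)
        for plan in plans:
            train = indexed.loc[plan.undersampled_ids]
            test = indexed.loc[plan.test_ids]
            for family in families:
                model = tune_and_fit(
                    family, train, budget=budget,
                    seed=(plan.seed + 1000 * FAMILIES.index(family) + w)
                         % (2**31),
                    forbidden_ids=set(plan.test_ids))
                metrics = evaluate(model, test, threshold=threshold)
                records.append({"family": family, "window": w,
                                "iteration": plan.iteration, **metrics})
                if family == "xgb" and keep_bundles:
                    bundles[(w, plan.iteration)] = (model, test)
    raw = pd.DataFrame(records)
    return BenchmarkResult(raw=raw, summary=summarize(raw),
                           xgb_bundles=bundles, split_plans=plans)
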