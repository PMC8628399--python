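"""Monte-Carlo cross-validation benchmark and significance comparisons.

The benchmark repeats a stratified random train/test split many times
(repeated random sub-sampling validation).  Within a repeat every
augmentation method and every classifier sees the *identical* split; only the
training partition is ever augmented, so method contrasts are paired by
construction and the test partition never leaks into training.

Per-repeat metric vectors are compared between each augmentation method and
the null model (no augmentation) with Student's two-sample t-tests, and the
whole family of p-values for a dataset is adjusted with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .augmentation import augment
from .data_model import LabeledTable
from .metrics import METRIC_NAMES, metric_set

logger = logging.getLogger(__name__)

__all__ = [
    "MCCVResult",
    "mccv_split",
    "run_mccv",
    "compare_methods",
    "permutation_calibration",
    "benjamini_hochberg",
    "make_classifier",
    "derive_seed",
    "MODELS",
    "BENCH_METHODS",
]

MODELS = ("lr", "rf", "svm_linear", "svm_rbf", "svm_poly")
BENCH_METHODS = ("null", "upsample", "gnus", "smote", "adasyn")


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-cell seed from the master seed and an integer key.

    Every repeat/method/model cell gets its own stream, so any single cell is
    reproducible without re-running the whole benchmark.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def mccv_split(
    n: int,
    labels,
    test_fraction: float = 0.2,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One stratified random train/test split.

    Per class the test count is the rounded share of ``test_fraction``,
    clamped so both partitions keep at least one sample of each class.
    Returns sorted, disjoint, exhaustive index arrays (train, test).
    """
    labels = np.asarray(labels)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    if len(labels) != n:
        raise ValueError("labels length must equal n")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    test_parts = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(labels == cls)
        if cls_idx.size < 2:
            raise ValueError(f"class {cls} needs at least 2 samples to appear in both partitions")
        n_test = int(round(test_fraction * cls_idx.size))
        if n_test < 1 or n_test > cls_idx.size - 1:
            warnings.warn(
                f"class {cls}: stratified test count clamped to keep one sample per partition",
                stacklevel=2,
            )
            n_test = min(max(n_test, 1), cls_idx.size - 1)
        shuffled = rng.permutation(cls_idx)
        test_parts.append(shuffled[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


# -- classifier contract ------------------------------------------------------


class _SkClassifier:
    """Thin wrapper giving scikit-learn estimators the fit/score contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, features, labels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.estimator.fit(features, labels)
        return self

    def predict_case_probability(self, features) -> np.ndarray:
        proba = self.estimator.predict_proba(features)
        case_col = int(np.flatnonzero(self.estimator.classes_ == 1)[0])
        return proba[:, case_col]


def make_classifier(name: str, seed: int = 0, **overrides):
    """Build a classifier by name with the benchmark's default settings.

    lr: unpenalised logistic regression (logit link).  rf: random forest with
    500 trees and sqrt(p) candidate features per split.  svm_*: C-SVM with the
    linear / RBF / cubic-polynomial kernel, bandwidth by the 'scale'
    heuristic, Platt-scaled probabilities.
    """
    if name == "lr":
        # C=inf => unpenalised maximum-likelihood fit (logit link, as in glm)
        params = {"C": np.inf, "max_iter": 1000, "solver": "lbfgs"}
        params.update(overrides)
        return _SkClassifier(LogisticRegression(**params))
    if name == "rf":
        params = {"n_estimators": 500, "max_features": "sqrt", "random_state": seed, "n_jobs": 1}
        params.update(overrides)
        return _SkClassifier(RandomForestClassifier(**params))
    if name.startswith("svm_"):
        kernel = {"svm_linear": "linear", "svm_rbf": "rbf", "svm_poly": "poly"}.get(name)
        if kernel is None:
            raise ValueError(f"unknown model {name!r}")
        params = {"kernel": kernel, "probability": True, "gamma": "scale", "degree": 3,
                  "random_state": seed}
        params.update(overrides)
        return _SkClassifier(SVC(**params))
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


# -- the benchmark ------------------------------------------------------------


@dataclass
class MCCVResult:
    """Per-repeat, per-method, per-model metric records plus the run config.

    ``records`` has one row per (repeat, method, model) with columns
    repeat, method, model, split_seed, auc, pr_auc, f1, mcc; metric columns
    are NaN for cells marked missing (degenerate test partitions or fit
    failures).  ``splits`` holds the (train, test) index pair per repeat when
    the run was asked to keep them.
    """

    records: pd.DataFrame
    config: dict
    splits: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def run_mccv(
    table: LabeledTable,
    methods: Sequence[str] = ("null", "gnus", "smote", "adasyn"),
    models: Sequence[str] = ("lr", "rf", "svm_linear", "svm_rbf", "svm_poly"),
    repeats: int = 1000,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    threshold: float = 0.5,
    k: int = 5,
    noise_scale: float = 0.001,
    model_params: dict | None = None,
    keep_splits: bool = False,
    progress: bool = False,
) -> MCCVResult:
    """Repeated random sub-sampling benchmark over methods and models.

    Per repeat: draw one stratified split (shared by all methods and models),
    augment only the training partition per method (null = none), fit each
    model on the augmented training data and score the untouched test
    partition.  All randomness derives from ``master_seed``.
    """
    for m in methods:
        if m not in BENCH_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {BENCH_METHODS}")
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}; choose from {MODELS}")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    model_params = model_params or {}
    rows = []
    splits = []
    n_missing = 0
    for r in range(repeats):
        split_seed = derive_seed(master_seed, 0, r)
        train_idx, test_idx = mccv_split(table.n_samples, table.labels, test_fraction, split_seed)
        if keep_splits:
            splits.append((train_idx, test_idx))
        train = table.subset(train_idx, name=f"{table.name}_train")
        x_test = table.features[test_idx]
        y_test = table.labels[test_idx]
        for mi, method in enumerate(methods):
            if method == "null":
                fit_table = train
            else:
                aug_seed = derive_seed(master_seed, 1, r, mi)
                fit_table = augment(train, method, rng_seed=aug_seed,
                                    k=k, noise_scale=noise_scale).table
            for gi, model_name in enumerate(models):
                model_seed = derive_seed(master_seed, 2, r, mi, gi)
                row = {"repeat": r, "method": method, "model": model_name,
                       "split_seed": split_seed,
                       **{m: np.nan for m in METRIC_NAMES}}
                try:
                    clf = make_classifier(model_name, model_seed,
                                          **model_params.get(model_name, {}))
                    clf.fit(fit_table.features, fit_table.labels)
                    scores = clf.predict_case_probability(x_test)
                    row.update(metric_set(y_test, scores, threshold).as_dict())
                except Exception as exc:  # degenerate split or fit failure: cell missing
                    n_missing += 1
                    logger.warning("repeat %d %s/%s failed: %s", r, method, model_name, exc)
                rows.append(row)
        if progress and (r + 1) % max(1, repeats // 20) == 0:
            logger.info("%s: repeat %d/%d", table.name, r + 1, repeats)
    if n_missing:
        logger.info("%s: %d missing cells out of %d", table.name, n_missing, len(rows))
    config = {
        "dataset": table.name, "methods": list(methods), "models": list(models),
        "repeats": repeats, "test_fraction": test_fraction, "master_seed": master_seed,
        "threshold": threshold, "k": k, "noise_scale": noise_scale,
        "n_missing_cells": n_missing,
    }
    return MCCVResult(pd.DataFrame(rows), config, splits)


def permutation_calibration(
    table: LabeledTable,
    model: str = "lr",
    repeats: int = 200,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    threshold: float = 0.5,
) -> np.ndarray:
    """Null-calibration AUCs: fresh label permutation per repeat.

    A single fixed permutation is not a valid null for repeated splitting of
    one finite dataset: the spurious feature-label correlation realised in
    the training partition is anti-correlated with the one in the test
    partition (their weighted sum is pinned to the dataset's fixed total), so
    held-out AUC is biased below 0.5.  Redrawing the permutation every repeat
    cancels that bias exactly; the mean of the returned AUCs is the quantity
    that should sit near 0.5 for a well-calibrated pipeline.
    """
    from .synthetic_data import permute_labels  # local import: avoid cycle

    aucs = []
    for r in range(repeats):
        permuted = permute_labels(table, seed=derive_seed(master_seed, 3, r))
        res = run_mccv(permuted, methods=("null",), models=(model,), repeats=1,
                       test_fraction=test_fraction,
                       master_seed=derive_seed(master_seed, 4, r), threshold=threshold)
        aucs.append(res.records["auc"].iloc[0])
    return np.asarray(aucs)


# -- statistical comparison ---------------------------------------------------


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t-test with degenerate-variance conventions."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 non-missing repeats per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:  # both vectors constant
        if a.mean() == b.mean():
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: p=0 boundary case")
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def compare_methods(
    result: MCCVResult,
    metrics: Sequence[str] = METRIC_NAMES,
    paired: bool = False,
) -> pd.DataFrame:
    """Per (model, metric, method) t-tests of each method against null.

    Missing cells are dropped per comparison (pairwise for the paired test).
    BH adjustment spans the whole family of tests within the dataset: all
    models x metrics x methods.  ``direction`` is the sign of
    mean_method - mean_null.
    """
    rec = result.records
    if "null" not in set(rec["method"]):
        raise ValueError("comparison requires the null method in the benchmark")
    methods = [m for m in rec["method"].unique() if m != "null"]
    rows = []
    for model in rec["model"].unique():
        sub = rec[rec["model"] == model]
        null_block = sub[sub["method"] == "null"].set_index("repeat")
        for metric in metrics:
            for method in methods:
                meth_block = sub[sub["method"] == method].set_index("repeat")
                if paired:
                    joined = null_block[[metric]].join(
                        meth_block[[metric]], lsuffix="_null", rsuffix="_m").dropna()
                    a = joined[f"{metric}_m"].to_numpy()
                    b = joined[f"{metric}_null"].to_numpy()
                    if len(a) < 2:
                        raise ValueError("need at least 2 paired non-missing repeats")
                    d = a - b
                    if np.var(d, ddof=1) == 0:
                        t, p = (0.0, 1.0) if d.mean() == 0 else (
                            np.inf if d.mean() > 0 else -np.inf, 0.0)
                    else:
                        t, p = stats.ttest_rel(a, b)
                else:
                    a = meth_block[metric].dropna().to_numpy()
                    b = null_block[metric].dropna().to_numpy()
                    t, p = _student_t(a, b)
                rows.append({
                    "model": model, "metric": metric, "method": method,
                    "mean_null": float(np.nanmean(null_block[metric])),
                    "mean_method": float(np.nanmean(meth_block[metric])),
                    "t_statistic": float(t), "p_raw": float(p),
                    "direction": int(np.sign(np.nanmean(meth_block[metric])
                                             - np.nanmean(null_block[metric]))),
                })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p_raw"].to_numpy())
    cols = ["model", "metric", "method", "mean_null", "mean_method",
            "t_statistic", "p_raw", "p_adjusted", "direction"]
    return out[cols]
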