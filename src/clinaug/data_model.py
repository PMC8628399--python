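"""Labeled clinical tables: loading, validation, missing-value policy, summaries.

A :class:`LabeledTable` is the exchange type used throughout the package: a
numeric feature matrix plus a binary label vector where ``1`` marks the case
(minority) class and ``0`` the control (majority) class.  Clinical tables are
read from CSV with a two-pass missing-value policy: first drop feature columns
that are mostly missing, then drop any sample row that still has a missing
entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledTable",
    "DatasetManifest",
    "LoadReport",
    "ManifestSummary",
    "SummaryStats",
    "load_csv",
    "summarize_manifests",
    "quantile_type7",
    "clinical_manifests",
    "read_manifests",
    "write_manifests",
]

DEFAULT_NA_TOKENS = ("", "NA", "?")


@dataclass
class LabeledTable:
    """Numeric feature matrix with one binary case/control label per row.

    Invariants enforced at construction: no missing values, labels restricted
    to {0, 1} with both classes present, and class 1 is the minority (ties
    allowed).  If the declared positive class turns out to be the majority the
    labels are flipped with a warning so that downstream oversampling always
    targets class 1.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.ndim != 1 or len(self.labels) != self.features.shape[0]:
            raise ValueError("labels must be a vector with one entry per feature row")
        if not np.isfinite(self.features).all():
            raise ValueError(f"{self.name}: features contain missing/non-finite values")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"{self.name}: labels must be 0/1, got {sorted(uniq)}")
        if uniq != {0, 1}:
            raise ValueError(f"{self.name}: both classes must be present")
        self.labels = self.labels.astype(np.int64)
        if not self.feature_names:
            self.feature_names = [f"x{i}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match number of columns")
        if (self.labels == 1).sum() > (self.labels == 0).sum():
            warnings.warn(
                f"{self.name}: declared positive class is the majority; "
                "flipping labels so the minority class is 1",
                stacklevel=2,
            )
            self.labels = 1 - self.labels

    # -- convenience accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    @property
    def case_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def control_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    def subset(self, indices: np.ndarray, name: str | None = None) -> "LabeledTable":
        """Row subset as a new table (both classes must survive)."""
        return LabeledTable(
            self.features[indices],
            self.labels[indices],
            list(self.feature_names),
            name or self.name,
        )

    def to_frame(self, label_column: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[label_column] = self.labels
        return df

    def manifest(self) -> "DatasetManifest":
        return DatasetManifest(self.name, self.n_samples, self.n_cases, self.n_features)


@dataclass(frozen=True)
class DatasetManifest:
    """Descriptive record of a dataset: sample, case and feature counts."""

    name: str
    n_samples: int
    n_cases: int
    n_features: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_cases <= 0:
            raise ValueError("sample and case counts must be positive")
        if self.n_cases >= self.n_samples:
            raise ValueError("n_cases must be smaller than n_samples")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    @property
    def case_pct(self) -> float:
        """Case percentage rounded to 2 decimals (printed precision)."""
        return round(100.0 * self.n_cases / self.n_samples, 2)


@dataclass(frozen=True)
class LoadReport:
    """Counts of what the missing-value policy removed."""

    n_rows_in: int
    n_cols_in: int
    n_cols_dropped_missing: int
    n_cols_dropped_non_numeric: int
    n_rows_dropped: int

    @property
    def n_rows_out(self) -> int:
        return self.n_rows_in - self.n_rows_dropped

    @property
    def n_cols_out(self) -> int:
        return self.n_cols_in - self.n_cols_dropped_missing - self.n_cols_dropped_non_numeric


def load_csv(
    path,
    label_column: str,
    positive_label,
    missing_feature_threshold: float = 0.5,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
    drop_non_numeric: bool = False,
    name: str | None = None,
    return_report: bool = False,
):
    """Read a clinical CSV and apply the two-pass missing-value policy.

    Pass 1 drops every feature column whose missing fraction is at least
    ``missing_feature_threshold``; pass 2 drops every sample row with any
    remaining missing value (including a missing label).  Non-numeric feature
    columns are a fatal error unless ``drop_non_numeric`` is set.

    Returns the :class:`LabeledTable` (and the :class:`LoadReport` when
    ``return_report`` is true); drop counts are also logged.
    """
    if not 0 <= missing_feature_threshold <= 1:
        raise ValueError("missing_feature_threshold must be in [0, 1]")
    df = pd.read_csv(path, na_values=list(na_tokens), keep_default_na=False, skipinitialspace=True)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    n_rows_in = len(df)
    feat = df.drop(columns=[label_column])
    n_cols_in = feat.shape[1]

    # non-numeric columns: fatal unless explicitly dropped
    non_numeric = []
    for col in feat.columns:
        coerced = pd.to_numeric(feat[col], errors="coerce")
        introduced = coerced.isna() & feat[col].notna()
        if introduced.any():
            non_numeric.append(col)
        else:
            feat[col] = coerced
    if non_numeric:
        if not drop_non_numeric:
            raise ValueError(
                f"non-numeric feature columns {non_numeric}; "
                "pass drop_non_numeric=True to discard them"
            )
        feat = feat.drop(columns=non_numeric)

    # pass 1: mostly-missing columns
    miss_frac = feat.isna().mean()
    cols_drop = miss_frac[miss_frac >= missing_feature_threshold].index.tolist()
    feat = feat.drop(columns=cols_drop)

    # pass 2: rows with any remaining missing value (features or label)
    keep = feat.notna().all(axis=1) & df[label_column].notna()
    n_rows_dropped = int((~keep).sum())
    feat = feat.loc[keep]
    label_raw = df.loc[keep, label_column]

    if feat.shape[0] == 0 or feat.shape[1] == 0:
        raise ValueError(
            f"{path}: no data left after missing-value filtering "
            f"(dropped {n_rows_dropped} rows, {len(cols_drop)} columns)"
        )
    levels = pd.unique(label_raw)
    if len(levels) != 2:
        raise ValueError(
            f"{path}: label column must have exactly two levels after filtering, "
            f"got {list(levels)[:5]}"
        )
    if positive_label not in set(levels):
        raise ValueError(f"{path}: positive label {positive_label!r} not among {list(levels)}")
    labels = (label_raw == positive_label).astype(int).to_numpy()

    report = LoadReport(n_rows_in, n_cols_in, len(cols_drop), len(non_numeric), n_rows_dropped)
    logger.info(
        "%s: dropped %d/%d columns (missing>=%.0f%%: %d, non-numeric: %d) "
        "and %d/%d rows with missing values",
        path, n_cols_in - report.n_cols_out, n_cols_in,
        100 * missing_feature_threshold, report.n_cols_dropped_missing,
        report.n_cols_dropped_non_numeric, n_rows_dropped, n_rows_in,
    )
    table = LabeledTable(
        feat.to_numpy(dtype=float),
        labels,
        [str(c) for c in feat.columns],
        name or str(path),
    )
    return (table, report) if return_report else table


# -- summary statistics -------------------------------------------------------


def quantile_type7(values, q: float) -> float:
    """Linear-interpolation sample quantile (the type-7 convention).

    With sorted values x_(1..n), the quantile sits at rank h = (n-1)*q + 1 and
    interpolates linearly between the bracketing order statistics; q=0 gives
    the minimum and q=1 the maximum.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("quantile of empty list is undefined")
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    return float(np.quantile(values, q, method="linear"))


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    median: float
    q1: float
    q3: float


@dataclass(frozen=True)
class ManifestSummary:
    n_datasets: int
    sample_size: SummaryStats
    case_pct: SummaryStats


def _stats(values) -> SummaryStats:
    values = np.asarray(values, dtype=float)
    return SummaryStats(
        mean=float(values.mean()),
        median=quantile_type7(values, 0.5),
        q1=quantile_type7(values, 0.25),
        q3=quantile_type7(values, 0.75),
    )


def summarize_manifests(manifests: Sequence[DatasetManifest]) -> ManifestSummary:
    """Mean/median/quartiles of sample sizes and case percentages.

    Case percentages are rounded to two decimals before summarising, matching
    the precision at which such tables are conventionally reported.
    """
    if not manifests:
        raise ValueError("cannot summarize an empty manifest list")
    sizes = [m.n_samples for m in manifests]
    pcts = [m.case_pct for m in manifests]
    return ManifestSummary(len(manifests), _stats(sizes), _stats(pcts))


def read_manifests(path) -> list[DatasetManifest]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        nf = row.get("n_features")
        nf = None if pd.isna(nf) else int(nf)
        out.append(DatasetManifest(str(row["name"]), int(row["n_samples"]), int(row["n_cases"]), nf))
    return out


def write_manifests(manifests: Sequence[DatasetManifest], path) -> None:
    pd.DataFrame(
        [
            {"name": m.name, "n_samples": m.n_samples, "n_cases": m.n_cases, "n_features": m.n_features}
            for m in manifests
        ]
    ).to_csv(path, index=False)


def clinical_manifests() -> list[DatasetManifest]:
    """The ten UCI clinical benchmark datasets (post missing-value filtering).

    These are the published sample/case/feature counts of the reference
    benchmark collection (breast cancer diagnosis and prognosis, Haberman
    survival, two cervical-cancer sets, fertility, female heroin users, HCV,
    NAFLD, cardiotocography).  The HCV feature count is not part of the
    published running text and is left unset.
    """
    return [
        DatasetManifest("wdbc", 569, 212, 30),
        DatasetManifest("wpbc", 198, 47, 32),
        DatasetManifest("haberman", 306, 81, 3),
        DatasetManifest("ccrf", 761, 17, 7),
        DatasetManifest("ccbr", 72, 21, 19),
        DatasetManifest("fertility", 100, 12, 9),
        DatasetManifest("heroin", 942, 97, 11),
        DatasetManifest("hcv", 546, 20, None),
        DatasetManifest("nafld", 74, 22, 9),
        DatasetManifest("ctg", 1831, 176, 22),
    ]
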