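"""Minority-class oversampling: random up-sampling, GNUS, SMOTE and ADASYN.

All four augmenters append synthetic minority rows (label 1) after the
original rows, which are preserved verbatim and in order.  The default target
is a balanced table: exactly ``n_controls - n_cases`` synthetic rows (ADASYN:
``round(beta * deficit)``).

* ``random_upsample`` duplicates minority rows drawn uniformly with
  replacement.
* ``gnus`` (Gaussian Noise Up-Sampling) does the same and then perturbs each
  copy with independent per-feature Gaussian noise whose mean and standard
  deviation are ``scale`` times the minority-class feature mean and standard
  deviation (``scale`` defaults to 0.001).
* ``smote`` interpolates between a minority row and one of its k nearest
  minority neighbours: ``base + u * (neighbour - base)`` with u ~ U[0, 1].
* ``adasyn`` uses the same interpolation but allocates the synthesis budget
  adaptively: each minority row receives a share proportional to the fraction
  of majority rows among its k nearest neighbours in the full dataset, so
  harder-to-learn regions get more synthetic points.

Distances are Euclidean on raw feature values; ties are broken towards the
lower row index so seeded runs are reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import LabeledTable

__all__ = [
    "AugmentationResult",
    "NoiseSpec",
    "knn_indices",
    "random_upsample",
    "gnus",
    "smote",
    "adasyn",
    "augment",
    "METHODS",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian jitter specification for GNUS.

    Per feature i the noise is Normal(scale * mean_i, scale * sd_i), with the
    minority-class sample mean and standard deviation (n-1 denominator).  With
    ``zero_centered`` the noise mean is 0 instead of scale * mean_i, removing
    the small systematic shift the scaled mean introduces.
    """

    scale: float = 0.001
    zero_centered: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("noise scale must be positive")


@dataclass
class AugmentationResult:
    """Augmented table plus provenance of the synthetic rows."""

    table: LabeledTable
    synthetic_mask: np.ndarray
    method: str
    params: dict
    seed: int
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_synthetic(self) -> int:
        return int(self.synthetic_mask.sum())


def knn_indices(
    reference: np.ndarray,
    query_row: np.ndarray,
    k: int,
    exclude_self: bool = False,
    self_index: int | None = None,
) -> np.ndarray:
    """Indices of the k nearest reference rows to a query (Euclidean).

    Returned ascending by distance, ties broken by lower row index.  With
    ``exclude_self`` the query's own row is removed: at ``self_index`` when
    given, otherwise the first row identical to the query.
    """
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query_row, dtype=float)
    d = np.sqrt(((reference - query) ** 2).sum(axis=1))
    if exclude_self:
        if self_index is None:
            matches = np.flatnonzero(d == 0.0)
            if matches.size == 0:
                raise ValueError("exclude_self requested but query not found in reference")
            self_index = int(matches[0])
        d[self_index] = np.inf
    order = np.argsort(d, kind="stable")
    avail = int(np.isfinite(d).sum())
    if k > avail:
        raise ValueError(f"k={k} exceeds the {avail} available reference rows")
    return order[:k]


def _minority_knn(x_min: np.ndarray, k: int) -> np.ndarray:
    """k nearest minority neighbours of every minority row (self excluded)."""
    d = cdist(x_min, x_min)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def _append(table: LabeledTable, synth: np.ndarray, method: str,
            params: dict, seed: int, provenance: pd.DataFrame) -> AugmentationResult:
    n = table.n_samples
    m = len(synth)
    if m:
        feats = np.vstack([table.features, synth])
        labels = np.concatenate([table.labels, np.ones(m, dtype=np.int64)])
    else:
        feats, labels = table.features.copy(), table.labels.copy()
    out = LabeledTable(feats, labels, list(table.feature_names), table.name)
    mask = np.zeros(n + m, dtype=bool)
    mask[n:] = True
    return AugmentationResult(out, mask, method, params, seed, provenance)


def _upsample_draw(rng: np.random.Generator, case_idx: np.ndarray, deficit: int) -> np.ndarray:
    return rng.choice(case_idx, size=deficit, replace=True)


def random_upsample(table: LabeledTable, rng_seed: int = 0) -> AugmentationResult:
    """Balance by duplicating minority rows drawn uniformly with replacement."""
    deficit = table.n_controls - table.n_cases
    rng = np.random.default_rng(rng_seed)
    params = {"deficit": deficit}
    if deficit == 0:
        return _append(table, np.empty((0, table.n_features)), "upsample", params, rng_seed,
                       pd.DataFrame(columns=["source"]))
    src = _upsample_draw(rng, table.case_indices, deficit)
    return _append(table, table.features[src], "upsample", params, rng_seed,
                   pd.DataFrame({"source": src}))


def gnus(
    table: LabeledTable,
    noise: NoiseSpec | None = None,
    rng_seed: int = 0,
) -> AugmentationResult:
    """Gaussian Noise Up-Sampling: duplicate minority rows, then jitter them.

    Each duplicated row gets independent per-feature Gaussian noise with mean
    ``scale * mean_i`` and sd ``scale * sd_i`` computed over the minority rows
    of the input table.  A singleton minority class has no sample sd; the sd
    is then taken as 0 (duplication plus mean shift) with a warning.
    """
    noise = noise or NoiseSpec()
    deficit = table.n_controls - table.n_cases
    rng = np.random.default_rng(rng_seed)
    params = {"deficit": deficit, "scale": noise.scale, "zero_centered": noise.zero_centered}
    if deficit == 0:
        return _append(table, np.empty((0, table.n_features)), "gnus", params, rng_seed,
                       pd.DataFrame(columns=["source"]))
    x_min = table.features[table.case_indices]
    mean = x_min.mean(axis=0)
    if len(x_min) < 2:
        warnings.warn("minority class of size 1: GNUS noise sd undefined, using 0", stacklevel=2)
        sd = np.zeros(table.n_features)
    else:
        sd = x_min.std(axis=0, ddof=1)
    mu = np.zeros_like(mean) if noise.zero_centered else noise.scale * mean
    sigma = noise.scale * sd
    src = _upsample_draw(rng, table.case_indices, deficit)
    synth = table.features[src] + rng.normal(loc=mu, scale=sigma, size=(deficit, table.n_features))
    return _append(table, synth, "gnus", params, rng_seed, pd.DataFrame({"source": src}))


def _interpolate(rng, x_min, base_local, neighbours):
    """One SMOTE-style synthesis: base + u * (neighbour - base)."""
    nbr_local = int(neighbours[base_local][rng.integers(len(neighbours[base_local]))])
    u = float(rng.uniform())
    row = x_min[base_local] + u * (x_min[nbr_local] - x_min[base_local])
    return row, nbr_local, u


def smote(table: LabeledTable, k: int = 5, rng_seed: int = 0) -> AugmentationResult:
    """SMOTE: interpolate between minority rows and their k nearest minority
    neighbours.

    Base rows are chosen by cycling through a random permutation of the
    minority set, so per-row synthesis counts differ by at most one.  k is
    shrunk to ``n_cases - 1`` when the minority class is smaller than k + 1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_min = table.n_cases
    if n_min < 2:
        raise ValueError(
            "SMOTE needs at least 2 minority samples; use gnus or random_upsample"
        )
    deficit = table.n_controls - n_min
    k_eff = min(k, n_min - 1)
    rng = np.random.default_rng(rng_seed)
    params = {"k": k, "k_eff": k_eff, "deficit": deficit}
    cols = ["base", "neighbor", "u"]
    if deficit == 0:
        return _append(table, np.empty((0, table.n_features)), "smote", params, rng_seed,
                       pd.DataFrame(columns=cols))
    case_idx = table.case_indices
    x_min = table.features[case_idx]
    neighbours = _minority_knn(x_min, k_eff)
    perm = rng.permutation(n_min)
    rows, prov = [], []
    for j in range(deficit):
        base_local = int(perm[j % n_min])
        row, nbr_local, u = _interpolate(rng, x_min, base_local, neighbours)
        rows.append(row)
        prov.append((int(case_idx[base_local]), int(case_idx[nbr_local]), u))
    return _append(table, np.array(rows), "smote", params, rng_seed,
                   pd.DataFrame(prov, columns=cols))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerize total*weights so the parts sum to total exactly.

    Floor the ideal shares, then hand the remaining units to the largest
    fractional parts; ties go to the lower index.
    """
    shares = total * weights
    base = np.floor(shares).astype(int)
    rem = total - int(base.sum())
    if rem:
        frac = shares - base
        order = np.lexsort((np.arange(len(weights)), -frac))
        base[order[:rem]] += 1
    return base


def adasyn(
    table: LabeledTable,
    k: int = 5,
    beta: float = 1.0,
    rng_seed: int = 0,
) -> AugmentationResult:
    """ADASYN: density-adaptive SMOTE-style oversampling.

    The synthesis budget G = round(beta * deficit) is distributed across
    minority rows proportionally to r_i, the fraction of majority rows among
    each row's k nearest neighbours in the full dataset, integerised by the
    largest-remainder rule so the total is exact.  Each synthesis then
    interpolates towards one of the row's k nearest *minority* neighbours.
    When no minority row has a majority neighbour (fully separated classes)
    the allocation falls back to uniform with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= beta:
        raise ValueError("beta must be non-negative")
    n_min = table.n_cases
    if n_min < 2:
        raise ValueError(
            "ADASYN needs at least 2 minority samples; use gnus or random_upsample"
        )
    deficit = table.n_controls - n_min
    G = int(round(beta * deficit))
    k_eff = min(k, n_min - 1)
    k_full = min(k, table.n_samples - 1)
    rng = np.random.default_rng(rng_seed)
    params = {"k": k, "k_eff": k_eff, "beta": beta, "G": G}
    cols = ["base", "neighbor", "u"]
    if G == 0:
        return _append(table, np.empty((0, table.n_features)), "adasyn", params, rng_seed,
                       pd.DataFrame(columns=cols))
    case_idx = table.case_indices
    x_min = table.features[case_idx]

    # density ratio r_i from the k nearest neighbours in the FULL dataset
    d_full = cdist(x_min, table.features)
    for local, glob in enumerate(case_idx):
        d_full[local, glob] = np.inf
    order = np.argsort(d_full, axis=1, kind="stable")[:, :k_full]
    r = (table.labels[order] == 0).mean(axis=1)
    if r.sum() == 0:
        warnings.warn(
            "ADASYN: no majority rows among any minority neighbourhood; "
            "falling back to uniform allocation",
            stacklevel=2,
        )
        weights = np.full(n_min, 1.0 / n_min)
    else:
        weights = r / r.sum()
    g = _largest_remainder(weights, G)

    neighbours = _minority_knn(x_min, k_eff)
    rows, prov = [], []
    for base_local in range(n_min):
        for _ in range(int(g[base_local])):
            row, nbr_local, u = _interpolate(rng, x_min, base_local, neighbours)
            rows.append(row)
            prov.append((int(case_idx[base_local]), int(case_idx[nbr_local]), u))
    return _append(table, np.array(rows) if rows else np.empty((0, table.n_features)),
                   "adasyn", params, rng_seed, pd.DataFrame(prov, columns=cols))


METHODS = ("upsample", "gnus", "smote", "adasyn")


def augment(table: LabeledTable, method: str, rng_seed: int = 0, *,
            k: int = 5, noise_scale: float = 0.001, beta: float = 1.0) -> AugmentationResult:
    """Dispatch to one of the oversampling methods by name."""
    if method == "upsample":
        return random_upsample(table, rng_seed)
    if method == "gnus":
        return gnus(table, NoiseSpec(scale=noise_scale), rng_seed)
    if method == "smote":
        return smote(table, k=k, rng_seed=rng_seed)
    if method == "adasyn":
        return adasyn(table, k=k, beta=beta, rng_seed=rng_seed)
    raise ValueError(f"unknown augmentation method {method!r}; choose from {METHODS}")
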