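"""Synthetic imbalanced clinical-like tabular data.

Two-class Gaussian generator: controls and cases share an AR(1) covariance
(corr(x_i, x_j) = rho^|i-j|, unit variances); cases are shifted by a
standardized effect ``delta`` on the first ``n_informative`` features.  The
case count is fixed by rounding (not Bernoulli draws) so class-count
arithmetic in the oversamplers is exactly testable.

``benchmark_presets`` mirrors the design space of the ten-dataset clinical
benchmark collection: n from 72 to 1831, 3-32 numeric features, case
fractions from 2.23% to 37.26%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .data_model import LabeledTable

__all__ = ["SyntheticSpec", "generate", "benchmark_presets", "preset", "permute_labels"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the two-class Gaussian generator.

    effect_size is the standardized mean shift of the case class on each of
    the first n_informative features; correlation is the AR(1) parameter rho
    between adjacent features (covariance rho^|i-j|, positive definite for
    |rho| < 1 by construction).
    """

    n_samples: int
    n_features: int
    case_fraction: float
    n_informative: int | None = None
    effect_size: float = 1.0
    correlation: float = 0.3
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 < self.case_fraction <= 0.5:
            raise ValueError("case_fraction must be in (0, 0.5]")
        if not 0 <= self.correlation < 1:
            raise ValueError("correlation must be in [0, 1)")
        if self.n_informative is None:
            object.__setattr__(self, "n_informative", math.ceil(self.n_features / 2))
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")

    @property
    def n_cases(self) -> int:
        return int(round(self.case_fraction * self.n_samples))


def generate(spec: SyntheticSpec) -> LabeledTable:
    """Draw a LabeledTable from the spec; deterministic under the spec seed."""
    n_cases = spec.n_cases
    if n_cases < 2:
        raise ValueError(
            f"case_fraction {spec.case_fraction} at n={spec.n_samples} yields "
            f"{n_cases} case(s); at least 2 required"
        )
    if n_cases > spec.n_samples - n_cases:
        raise ValueError("cases must not outnumber controls")
    rng = np.random.default_rng(spec.seed)
    p = spec.n_features
    idx = np.arange(p)
    cov = spec.correlation ** np.abs(np.subtract.outer(idx, idx))
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((spec.n_samples, p)) @ chol.T
    labels = np.zeros(spec.n_samples, dtype=np.int64)
    labels[:n_cases] = 1
    x[:n_cases, : spec.n_informative] += spec.effect_size
    perm = rng.permutation(spec.n_samples)
    return LabeledTable(x[perm], labels[perm], name=spec.name)


# (n_samples, n_cases, n_features) of the ten clinical benchmark datasets.
# The HCV feature count is not published in the collection's running text;
# 12 (the standard UCI HCV laboratory panel) is used for the generator.
_PRESETS = {
    "wdbc": (569, 212, 30),
    "wpbc": (198, 47, 32),
    "haberman": (306, 81, 3),
    "ccrf": (761, 17, 7),
    "ccbr": (72, 21, 19),
    "fertility": (100, 12, 9),
    "heroin": (942, 97, 11),
    "hcv": (546, 20, 12),
    "nafld": (74, 22, 9),
    "ctg": (1831, 176, 22),
}


def benchmark_presets(effect_size: float = 1.0, correlation: float = 0.3,
                      seed: int = 0) -> list[SyntheticSpec]:
    """Ten presets emulating the clinical benchmark collection's shape.

    Each preset reproduces a dataset's (n_samples, case count, n_features)
    exactly; effect size and feature correlation default to mid-range
    difficulty (delta=1, rho=0.3).
    """
    specs = []
    for name, (n, n_cases, p) in _PRESETS.items():
        specs.append(
            SyntheticSpec(
                n_samples=n,
                n_features=p,
                case_fraction=n_cases / n,
                effect_size=effect_size,
                correlation=correlation,
                seed=seed,
                name=name,
            )
        )
    return specs


def preset(name: str, **overrides) -> SyntheticSpec:
    """One named preset, optionally with field overrides (e.g. seed)."""
    for spec in benchmark_presets():
        if spec.name == name:
            return replace(spec, **overrides) if overrides else spec
    raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")


def permute_labels(table: LabeledTable, seed: int = 0) -> LabeledTable:
    """Randomly permute labels against rows (null-calibration harness)."""
    rng = np.random.default_rng(seed)
    labels = table.labels[rng.permutation(table.n_samples)]
    return LabeledTable(table.features.copy(), labels, list(table.feature_names),
                        f"{table.name}_permuted")
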