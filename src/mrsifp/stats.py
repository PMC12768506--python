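"""Statistical battery for group comparisons of metabolic features.

Thin, uniformly-typed wrappers around the standard tests (Kruskal-Wallis,
Welch's t, Mann-Whitney U, Levene, Pearson) plus Cohen's d, all returning
:class:`TestResult` / :class:`EffectSize` records with sample sizes
attached. Group tests are intended to run on patient-level observations —
patients, not voxels, are the exchangeable units in a 12-patient cohort;
voxel-level testing pseudo-replicates. Both granularities are supported by
simply passing the corresponding samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "EffectSize",
    "kruskal_wallis",
    "welch_t",
    "mann_whitney",
    "levene",
    "pearson",
    "cohens_d",
    "benjamini_hochberg",
]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]


@dataclass
class EffectSize:
    cohens_d: float
    direction: str = "group1 - group2"


def _arrays(*groups):
    return [np.asarray(g, dtype=float) for g in groups]


def kruskal_wallis(*groups, names: tuple[str, ...] | None = None) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square p-value.

    Degenerate input (all values identical across groups) returns H=0, p=1.
    """
    gs = _arrays(*groups)
    if len(gs) < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*gs)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      names or tuple(f"g{i+1}" for i in range(len(gs))),
                      tuple(len(g) for g in gs))


def welch_t(a, b, names: tuple[str, str] = ("a", "b")) -> TestResult:
    """Welch's t-test (unequal variances, Satterthwaite df), two-sided."""
    a, b = _arrays(a, b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test needs n >= 2 per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: decide by mean equality
        equal = math.isclose(a.mean(), b.mean())
        return TestResult("welch_t", 0.0 if equal else math.inf,
                          1.0 if equal else 0.0, names, (len(a), len(b)))
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("welch_t", float(stat), float(p), names, (len(a), len(b)))


def mann_whitney(a, b, names: tuple[str, str] = ("a", "b")) -> TestResult:
    """Mann-Whitney U with midrank ties and normal approximation."""
    a, b = _arrays(a, b)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("Mann-Whitney needs non-empty groups")
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("mann_whitney", float(stat), float(p), names,
                      (len(a), len(b)))


def levene(*groups, center: str = "mean",
           names: tuple[str, ...] | None = None) -> TestResult:
    """Levene's test of variance homogeneity.

    ``center="median"`` gives the Brown-Forsythe variant.
    """
    gs = _arrays(*groups)
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("Levene's test needs >= 2 groups with n >= 2")
    stat, p = sps.levene(*gs, center=center)
    return TestResult("levene", float(stat), float(p),
                      names or tuple(f"g{i+1}" for i in range(len(gs))),
                      tuple(len(g) for g in gs))


def pearson(x, y) -> TestResult:
    """Pearson correlation with t-distribution p-value; NaN for constant input."""
    x, y = _arrays(x, y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("Pearson correlation needs paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input to Pearson correlation; r undefined")
        return TestResult("pearson", float("nan"), float("nan"), ("x", "y"),
                          (len(x), len(y)))
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson", float(r), float(p), ("x", "y"), (len(x), len(y)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (FDR). Off by default in the pipeline,
    which reports raw p-values; available for users who test many sources."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def cohens_d(a, b) -> EffectSize:
    """Cohen's d with pooled (n-1)-weighted standard deviation.

    Antisymmetric under group swap and invariant to common affine
    transforms. Zero pooled SD yields NaN with a warning.
    """
    a, b = _arrays(a, b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Cohen's d needs n >= 2 per group")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        logger.warning("zero pooled SD; Cohen's d undefined")
        return EffectSize(float("nan"))
    return EffectSize(float((a.mean() - b.mean()) / math.sqrt(pooled_var)))
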