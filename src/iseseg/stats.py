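"""Replicated G-tests of goodness-of-fit and count reconstruction.

Flow cytometry yields class *proportions* per sample; the underlying
number of males per sample is known, so integer class counts are
reconstructed before testing.  Transmission bias in a two-class clone is
then a goodness-of-fit question — does the proportion of the ISE-free
class deviate from the unbiased expectation of 0.5? — answered with the
replicated G-test: per-replicate G statistics sum to a *total* G, the
G-test on the summed counts gives the *pooled* G (the shared deviation),
and the difference is the *heterogeneity* G (among-replicate
disagreement).  The decomposition total = pooled + heterogeneity is an
exact identity, for degrees of freedom too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ClassCounts",
    "GTestResult",
    "reconstruct_counts",
    "g_test",
    "repeated_g_test",
]


@dataclass(frozen=True)
class ClassCounts:
    """Integer male counts per GS class for one sample."""

    counts: np.ndarray
    stage: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("counts must be a non-empty 1-D integer vector")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if c.sum() < 1:
            raise ValueError("counts must sum to at least 1")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float
    kind: str  # individual | total | pooled | heterogeneity


def reconstruct_counts(
    n_total: int,
    proportions: Sequence[float],
    stage: str = "",
    replicate_id: str = "",
) -> ClassCounts:
    """Integer class counts from a sample's size and class proportions.

    Uses largest-remainder (Hamilton) rounding so the counts sum to
    ``n_total`` exactly; remainder ties go to the lower class index.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be nonnegative and sum to 1")
    exact = n_total * p / p.sum()
    base = np.floor(exact).astype(np.int64)
    short = n_total - int(base.sum())
    if short > 0:
        # stable sort => ties resolved toward the lower class index
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    return ClassCounts(counts=base, stage=stage, replicate_id=replicate_id)


def _g_statistic(counts: np.ndarray, expected: np.ndarray) -> float:
    obs = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
    return float(2.0 * terms.sum())


def g_test(
    observed: ClassCounts,
    expected_probs: Sequence[float],
    williams: bool = False,
) -> GTestResult:
    """Log-likelihood-ratio (G) goodness-of-fit test.

    G = 2 * sum_k O_k * ln(O_k / E_k) with E_k = n * p_k and the
    convention 0 * ln 0 = 0; df = classes - 1, p from the chi-square
    upper tail.  ``williams=True`` applies the Williams small-sample
    correction G/q with q = 1 + (a^2 - 1) / (6 n (a - 1)) for a classes.
    """
    p = np.asarray(expected_probs, dtype=float)
    if p.shape != observed.counts.shape:
        raise ValueError("expected_probs length must match the class count")
    if np.any(p <= 0):
        raise ValueError("all expected probabilities must be positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    n = observed.total
    g = _g_statistic(observed.counts, n * p)
    a = observed.counts.size
    if williams and a > 1:
        q = 1.0 + (a * a - 1.0) / (6.0 * n * (a - 1.0))
        g /= q
    df = a - 1
    return GTestResult(G=g, df=df, p=float(sps.chi2.sf(g, df)), kind="individual")


def repeated_g_test(
    replicates: Sequence[ClassCounts],
    expected_probs: Sequence[float],
) -> tuple[GTestResult, GTestResult, GTestResult]:
    """Replicated goodness-of-fit G-tests: (total, pooled, heterogeneity).

    total
        Sum of the per-replicate G statistics (df summed likewise);
        significant if replicates deviate from expectation in any way.
    pooled
        G-test on the class counts summed over replicates; the shared,
        directional deviation.
    heterogeneity
        total - pooled (df likewise): do the replicates disagree with
        one another?  With r replicates of a classes its df is
        (r - 1) * (a - 1).

    The decomposition is an exact algebraic identity, not an
    approximation, and is returned without re-fitting.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    shape = replicates[0].counts.shape
    for r in replicates:
        if r.counts.shape != shape:
            raise ValueError("replicates must share the class structure")
    individual = [g_test(r, expected_probs) for r in replicates]
    total_g = sum(r.G for r in individual)
    total_df = sum(r.df for r in individual)
    total = GTestResult(
        G=total_g, df=total_df, p=float(sps.chi2.sf(total_g, total_df)), kind="total"
    )
    summed = ClassCounts(
        counts=np.sum([r.counts for r in replicates], axis=0)
    )
    pooled_ind = g_test(summed, expected_probs)
    pooled = GTestResult(
        G=pooled_ind.G, df=pooled_ind.df, p=pooled_ind.p, kind="pooled"
    )
    het_g = total.G - pooled.G
    het_df = total.df - pooled.df
    het = GTestResult(
        G=het_g, df=het_df, p=float(sps.chi2.sf(het_g, het_df)), kind="heterogeneity"
    )
    return total, pooled, het
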