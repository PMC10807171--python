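"""Group comparison and expression-matrix regression.

Two small statistical utilities used throughout the assays: the
Mann–Whitney U test (the nonparametric two-group comparison applied to
every per-cell metric) and ordinary least-squares regression between
z-scored expression rows of a genes × samples matrix (e.g. PLEC versus
GFAP or AQP4 z-scores across patient cohorts). Group summaries are given
as median ± bootstrap standard error of the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExpressionMatrix",
    "RegressionResult",
    "MannWhitneyResult",
    "zscore_rows",
    "regress_pair",
    "mann_whitney",
    "median_bootstrap_se",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with a z-scored flag."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    zscored: bool = False
    flagged_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    p: float  # two-sided, for the slope


@dataclass
class MannWhitneyResult:
    u: float  # min(U_a, U_b)
    p: float  # two-sided
    method: str  # 'exact' or 'asymptotic'


def zscore_rows(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization: (x − mean) / SD with sample SD (ddof=1).

    Zero-variance rows cannot be standardized; they are dropped and listed
    in ``flagged_genes``.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-score")
    sd = df.std(axis=1, ddof=1)
    flagged = list(df.index[sd == 0])
    keep = df.loc[sd > 0]
    z = keep.sub(keep.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return ExpressionMatrix(values=z, zscored=True, flagged_genes=flagged)


def regress_pair(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with R² and a two-sided p-value for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
        p=float(res.pvalue),
    )


def mann_whitney(a: np.ndarray, b: np.ndarray, exact_max_n: int = 12) -> MannWhitneyResult:
    """Mann–Whitney U test, two-sided.

    Reports U = min(U_a, U_b). The p-value is exact (full null distribution
    of U) for tie-free samples with n_a + n_b ≤ ``exact_max_n``; otherwise
    the normal approximation with midrank tie correction and continuity
    correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and a.size + b.size <= exact_max_n) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return MannWhitneyResult(u=u, p=float(min(res.pvalue, 1.0)), method=method)


def median_bootstrap_se(
    x: np.ndarray, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Median and its bootstrap standard error (seeded)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    return float(np.median(x)), float(meds.std(ddof=1))
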