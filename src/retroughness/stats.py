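"""Cohort-level inference for layer-roughness studies.

Group comparisons (exact Mann-Whitney rank sum, paired and independent t),
distributional checks (Shapiro-Wilk, Fisher variance ratio, two-sample
Kolmogorov-Smirnov, proportions z) and the one-sided Pearson correlation
matrix linking layer fractal dimensions to disease-related covariates.

Directional hypotheses are fixed a priori in ``ONE_SIDED_DIRECTIONS``:
roughness is predicted higher in the disease group, positively correlated
with age, negatively with cognitive score (MMSE) and visual acuity, and
positively among layers.  No multiple-testing correction is applied;
significance flags mark raw p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05

#: predicted sign of the correlation of layer FD with each covariate
ONE_SIDED_DIRECTIONS = {"mmse": "less", "visual_acuity": "less", "age": "greater"}


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    sidedness: str = "two-sided"
    extra: dict | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney / Wilcoxon rank sum, exact
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of labelings with each U value under the null (no ties).

    Dynamic program over the choice of which n1 of the n1+n2 ranks belong
    to the first sample; counts[u] is the number of subsets whose U
    statistic equals u, for u = 0 .. n1*n2.
    """
    u_max = n1 * n2
    # ways[k][u]: subsets of size k of ranks seen so far with U-contribution u
    ways = np.zeros((n1 + 1, u_max + 1), dtype=float)
    ways[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        # adding rank i to the first sample contributes (i - k) to U once the
        # subset has k-1 smaller members... iterate k downward to reuse rows
        for k in range(min(i, n1), 0, -1):
            contrib = i - k  # number of second-sample ranks below rank i
            if contrib > u_max:
                continue
            ways[k, contrib:] += ways[k - 1, : u_max + 1 - contrib]
    return ways[n1]


def _exact_u_sf(u: float, n1: int, n2: int) -> float:
    """P(U >= u) under the exact null distribution (no ties)."""
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    lo = int(math.ceil(u - 1e-9))
    return float(counts[lo:].sum() / total)


def mann_whitney_exact(
    x,
    y,
    alternative: str = "two-sided",
    max_exact_n: int = 50,
    n_permutations: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Exact Mann-Whitney rank-sum test.

    Reports both conventions: U (0 .. n1*n2, counting pairs where x exceeds
    y, with half-credit for ties) and the first-sample rank sum
    W = U + n1*(n1+1)/2.  Without ties and for combined n <= ``max_exact_n``
    the p-value comes from full enumeration of the null U distribution via
    a counting recursion; with ties mid-ranks are used and the p-value
    degrades to a permutation test (exhaustive when feasible, otherwise
    seeded Monte Carlo of ``n_permutations`` draws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    def p_of(u_obs: float, sf) -> float:
        if alternative == "greater":
            return sf(u_obs)
        if alternative == "less":
            return sf(n1 * n2 - u_obs)  # by symmetry U' = n1*n2 - U
        return min(1.0, 2.0 * min(sf(u_obs), sf(n1 * n2 - u_obs)))

    if not has_ties and n1 + n2 <= max_exact_n:
        p = p_of(u, lambda v: _exact_u_sf(v, n1, n2))
        method = "exact enumeration"
    else:
        # permutation on the mid-rank U statistic
        n_total = n1 + n2
        n_comb = math.comb(n_total, n1)
        if n_comb <= 200_000:
            us = np.array(
                [
                    ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
                    for idx in itertools.combinations(range(n_total), n1)
                ]
            )
            method = "exhaustive permutation (ties)"
        else:
            rng = np.random.default_rng(seed)
            us = np.empty(n_permutations)
            for i in range(n_permutations):
                idx = rng.choice(n_total, size=n1, replace=False)
                us[i] = ranks[idx].sum() - n1 * (n1 + 1) / 2.0
            method = "Monte Carlo permutation (ties)"

        def sf(v):
            return float((us >= v - 1e-9).mean())

        p = p_of(u, sf)
    return TestResult(
        name="Mann-Whitney rank sum",
        statistic=w,
        p_value=p,
        sidedness=alternative,
        extra={"U": u, "W": w, "n1": n1, "n2": n2, "method": method},
    )


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def paired_t(x, y, alternative: str = "two-sided") -> TestResult:
    """Student's t for paired samples on the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero variance of paired differences")
    res = sps.ttest_rel(x, y, alternative=alternative)
    return TestResult(
        name="paired t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(x.size - 1),
        sidedness=alternative,
    )


def independent_t(x, y, alternative: str = "two-sided") -> TestResult:
    """Student's t for two independent samples (pooled variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(x, y, alternative=alternative)
    return TestResult(
        name="independent t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(x.size + y.size - 2),
        sidedness=alternative,
    )


# ---------------------------------------------------------------------------
# distributional checks
# ---------------------------------------------------------------------------

def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (Royston's approximation), 3 <= n <= 50."""
    x = np.asarray(x, dtype=float)
    if not (3 <= x.size <= 50):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 50")
    res = sps.shapiro(x)
    return TestResult(
        name="Shapiro-Wilk", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def fisher_variance_ratio(x, y, alternative: str = "two-sided") -> TestResult:
    """Fisher's F test of equal variances: F = var(x)/var(y), df (n1-1, n2-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("need at least 2 observations per group")
    f = float(x.var(ddof=1) / y.var(ddof=1))
    d1, d2 = x.size - 1, y.size - 1
    dist = sps.f(d1, d2)
    if alternative == "greater":
        p = float(dist.sf(f))
    elif alternative == "less":
        p = float(dist.cdf(f))
    else:
        p = float(min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f))))
    return TestResult(
        name="Fisher variance ratio", statistic=f, p_value=p, df=(d1, d2),
        sidedness=alternative,
    )


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov; reports the Z-normalized statistic."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ks_2samp(x, y)
    n1, n2 = x.size, y.size
    z = float(res.statistic * math.sqrt(n1 * n2 / (n1 + n2)))
    return TestResult(
        name="Kolmogorov-Smirnov Z", statistic=z, p_value=float(res.pvalue),
        extra={"D": float(res.statistic)},
    )


def proportions_z(count1: int, n1: int, count2: int, n2: int) -> TestResult:
    """Two-sided two-proportion z-test with pooled standard error."""
    if min(n1, n2) < 1:
        raise ValueError("empty group")
    p1, p2 = count1 / n1, count2 / n2
    p_pool = (count1 + count2) / (n1 + n2)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
    z = 0.0 if se == 0 else (p1 - p2) / se
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(name="proportions z", statistic=float(z), p_value=p)


# ---------------------------------------------------------------------------
# correlation matrix
# ---------------------------------------------------------------------------

def pearson_one_sided(x, y, alternative: str) -> tuple[float, float]:
    """Pearson r with a one- or two-sided p from the exact t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    dist = sps.t(n - 2)
    if alternative == "greater":
        p = float(dist.sf(t))
    elif alternative == "less":
        p = float(dist.cdf(t))
    else:
        p = float(2.0 * dist.sf(abs(t)))
    return r, p


@dataclass
class CorrelationMatrixResult:
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    subset: str
    n: int


def correlation_matrix(
    table: pd.DataFrame, subset: str = "all", alpha: float = ALPHA
) -> CorrelationMatrixResult:
    """Pearson correlations of layer FDs with one another and with covariates.

    ``table`` is a cohort table with ``fd_layer_1 .. fd_layer_10`` columns,
    optionally ``fd_total_retina``, a ``group`` column, and the covariates
    ``mmse``, ``visual_acuity``, ``age``.  Layer-layer (and layer-total)
    pairs are tested one-sided for positive correlation; layer-covariate
    pairs one-sided in the predicted direction; covariate-covariate pairs
    two-sided.  ``subset`` restricts to the disease group ("AD") or keeps
    the whole sample ("all").
    """
    if subset == "AD":
        table = table[table["group"] == "AD"]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    fd_cols = [c for c in table.columns if c.startswith("fd_layer_")]
    if "fd_total_retina" in table.columns:
        fd_cols = fd_cols + ["fd_total_retina"]
    cov_cols = [c for c in ONE_SIDED_DIRECTIONS if c in table.columns]
    cols = fd_cols + cov_cols
    sub = table[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")

    r_mat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p_mat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    np.fill_diagonal(p_mat.values, np.nan)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            a_fd, b_fd = a in fd_cols, b in fd_cols
            if a_fd and b_fd:
                alt = "greater"
            elif a_fd != b_fd:
                cov = b if a_fd else a
                alt = ONE_SIDED_DIRECTIONS[cov]
            else:
                alt = "two-sided"
            r, p = pearson_one_sided(sub[a], sub[b], alt)
            r_mat.loc[a, b] = r_mat.loc[b, a] = r
            p_mat.loc[a, b] = p_mat.loc[b, a] = p
    sig = p_mat < alpha
    return CorrelationMatrixResult(
        r=r_mat, p=p_mat, significant=sig, subset=subset, n=len(sub)
    )


def group_comparison(
    table: pd.DataFrame, column: str = "mean_fd_10", alternative: str = "greater"
) -> TestResult:
    """Disease-vs-control comparison of one per-subject summary column.

    One-sided exact Mann-Whitney with the disease group as the first
    sample, matching the a-priori prediction of higher roughness.
    """
    x = table.loc[table["group"] == "AD", column].dropna().to_numpy()
    y = table.loc[table["group"] == "CTL", column].dropna().to_numpy()
    return mann_whitney_exact(x, y, alternative=alternative)
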