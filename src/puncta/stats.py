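"""Statistical layer for per-cell metrics.

Implements the tests the quantifications are reported with: the two-tailed
unpaired t test with Welch's correction, the Mann-Whitney test, one-way
ANOVA with Dunnett's T3 correction for unequal-variance multiple
comparisons, ROUT outlier removal at rate Q, and Tukey box-and-whisker
summaries.

Dunnett's T3 adjusts each pairwise Welch-type statistic against the
studentized maximum modulus (SMM) distribution: the maximum of k independent
|N(0, 1)| variables studentized by a common chi estimate with that pair's
Welch-Satterthwaite degrees of freedom. The SMM tail probability is
estimated by seeded Monte Carlo over the chi denominator s, with the
max-modulus handled in closed form,

    P(SMM(k, nu) > t) = 1 - E_s[(2*Phi(t*s) - 1)^k],   s = sqrt(chi2_nu/nu),

which keeps the Monte-Carlo noise orders of magnitude below the naive
max-of-draws estimator at the same number of draws. With k = 1 the SMM is
|t_nu| and the adjusted p is computed exactly. The Sidak bound
1 - (1 - p_raw)^k is reported alongside as a cross-check.

ROUT (robust regression and outlier removal) is published for nonlinear
fits; applied to a univariate data column it reduces to a constant model:
a robust center is fit by iteratively reweighted least squares with
Lorentzian weights, the robust SD of the residuals (RSDR) is the 68.27th
percentile of the absolute residuals times n/(n-1), each point gets a
t-like score |residual|/RSDR with n-1 df, and outliers are declared by a
false-discovery-rate step-up rule at rate Q testing from the largest
residual inward.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import StatsError


@dataclass
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    method: str
    n_per_group: tuple[int, ...]


@dataclass
class ComparisonTable:
    """All pairwise Welch-type comparisons with T3-adjusted p-values."""

    comparisons: list[dict] = field(default_factory=list)
    family_alpha: float = 0.05
    mc_reps: int = 100_000
    seed: int = 0
    anova_f: float = float("nan")
    anova_p: float = float("nan")


@dataclass
class OutlierResult:
    kept: list[float]
    flagged: list[float]
    Q: float
    center_estimate: float
    rsdr: float


@dataclass
class BoxSummary:
    """Tukey five-number summary; quartiles use linear interpolation of the
    empirical CDF (the type-7 rule), whiskers reach the most extreme points
    within 1.5 IQR of the quartiles."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def _as_array(values, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(list(values), dtype=float)
    if arr.ndim != 1 or len(arr) < min_n:
        raise StatsError(f"{name}: need at least {min_n} values, got {arr.size}")
    return arr


def _welch_components(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(t, df) of the unequal-variance t statistic. Degenerate cases
    (zero pooled standard error) are handled by the caller."""
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return math.inf if a.mean() != b.mean() else 0.0, float(na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def welch_t_test(a, b) -> TestResult:
    """Two-tailed unpaired t test with Welch's correction.

    Both groups having zero variance is degenerate: equal means give
    t = 0, p = 1; unequal means give p = 0 with a warning.
    """
    a = _as_array(a, "a", 2)
    b = _as_array(b, "b", 2)
    t, df = _welch_components(a, b)
    if math.isinf(t):
        warnings.warn("both groups have zero variance with unequal means", stacklevel=2)
        t = math.copysign(math.inf, a.mean() - b.mean())
        p = 0.0
    elif t == 0.0 and a.var(ddof=1) + b.var(ddof=1) == 0.0:
        p = 1.0
    else:
        p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t), df=float(df), p_value=float(p),
        method="welch_t", n_per_group=(len(a), len(b)),
    )


def mann_whitney_test(a, b) -> TestResult:
    """Two-tailed Mann-Whitney U test.

    Exact p by enumeration when n_a + n_b <= 12 with no ties, otherwise the
    normal approximation with tie correction; the method label records
    which path was taken.
    """
    a = _as_array(a, "a", 1)
    b = _as_array(b, "b", 1)
    pooled = np.concatenate([a, b])
    exact = len(pooled) <= 12 and len(np.unique(pooled)) == len(pooled)
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic), df=None, p_value=float(res.pvalue),
        method="mann_whitney_exact" if exact else "mann_whitney_normal_approx",
        n_per_group=(len(a), len(b)),
    )


def smm_sf(t: float, k: int, df: float, rng: np.random.Generator, mc_reps: int) -> float:
    """P(SMM(k, df) > t) by seeded Monte Carlo over the chi denominator."""
    if not math.isfinite(t):
        return 0.0 if t > 0 else 1.0
    if k == 1:
        return float(2.0 * sps.t.sf(abs(t), df))
    s = np.sqrt(rng.chisquare(df, mc_reps) / df)
    inner = 2.0 * sps.norm.cdf(abs(t) * s) - 1.0
    return float(1.0 - np.mean(inner**k))


def dunnett_t3(groups: dict, mc_reps: int = 100_000, seed: int = 0) -> ComparisonTable:
    """All pairwise unequal-variance comparisons with Dunnett T3 adjustment.

    Each pair gets a Welch statistic and Welch-Satterthwaite df; the
    adjusted p is the SMM tail probability at that pair's df for k = number
    of pairs. The one-way ANOVA omnibus F is reported but gates nothing.
    """
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    arrays = {label: _as_array(v, str(label), 2) for label, v in groups.items()}
    labels = list(arrays)
    pairs = list(combinations(labels, 2))
    k = len(pairs)
    rng = np.random.default_rng(seed)
    f_stat, f_p = sps.f_oneway(*arrays.values())
    comparisons = []
    for la, lb in pairs:
        a, b = arrays[la], arrays[lb]
        t, df = _welch_components(a, b)
        if math.isinf(t):
            p_raw = 0.0
        else:
            p_raw = float(2.0 * sps.t.sf(abs(t), df)) if (a.var(ddof=1) + b.var(ddof=1)) else 1.0
        p_adj = smm_sf(t, k, df, rng, mc_reps)
        p_adj = min(1.0, max(p_adj, p_raw))  # adjustment never helps
        comparisons.append(
            {
                "group_a": la, "group_b": lb,
                "t": float(t), "df": float(df),
                "p_raw": p_raw, "p_adjusted": p_adj,
                "p_sidak": float(1.0 - (1.0 - p_raw) ** k),
            }
        )
    return ComparisonTable(
        comparisons=comparisons, mc_reps=mc_reps, seed=seed,
        anova_f=float(f_stat), anova_p=float(f_p),
    )


def rout_outliers(values, Q: float = 1.0, max_iter: int = 100) -> OutlierResult:
    """ROUT outlier detection on a univariate sample at FDR rate ``Q`` (%).

    See the module docstring for the constant-model adaptation. Constant
    data have zero residuals and yield no outliers.
    """
    x = _as_array(values, "values", 3)
    if not (0.0 < Q < 100.0):
        raise StatsError("Q must be in (0, 100), as a percentage")
    n = len(x)
    scale = max(np.ptp(x), 1.0)

    center = float(np.median(x))
    for _ in range(max_iter):
        resid = x - center
        rsdr = _rsdr(resid, n)
        if rsdr == 0.0:
            break
        w = 1.0 / (1.0 + (resid / rsdr) ** 2)  # Lorentzian weights
        new_center = float(np.sum(w * x) / np.sum(w))
        if abs(new_center - center) < 1e-12 * scale:
            center = new_center
            break
        center = new_center

    resid = x - center
    rsdr = _rsdr(resid, n)
    flagged_idx: set[int] = set()
    if np.abs(resid).max() > 0.0:
        with np.errstate(divide="ignore"):
            t_scores = np.abs(resid) / rsdr if rsdr > 0 else np.full(n, np.inf)
            t_scores[np.abs(resid) == 0] = 0.0
        pvals = 2.0 * sps.t.sf(t_scores, n - 1)
        # FDR step-up at rate Q, testing from the largest residual inward:
        # the i-th largest residual is compared against (Q/100) * i / n, the
        # Benjamini-Hochberg ladder (so the single largest faces Q/n).
        order = np.argsort(-np.abs(resid))
        q = Q / 100.0
        cutoff = 0
        for i in range(n, 0, -1):  # step-up: find the deepest passing rank
            if pvals[order[i - 1]] <= q * i / n:
                cutoff = i
                break
        flagged_idx = {int(idx) for idx in order[:cutoff]}
    kept = [float(v) for i, v in enumerate(x) if i not in flagged_idx]
    flagged = [float(v) for i, v in enumerate(x) if i in flagged_idx]
    return OutlierResult(kept=kept, flagged=flagged, Q=Q, center_estimate=center, rsdr=rsdr)


def _rsdr(resid: np.ndarray, n: int) -> float:
    """Robust SD of residuals: 68.27th percentile of |residuals| x n/(n-1)."""
    return float(np.percentile(np.abs(resid), 68.27) * n / (n - 1))


def tukey_box_summary(values) -> BoxSummary:
    """Median, type-7 quartiles, 1.5-IQR whiskers, and outliers beyond them."""
    x = _as_array(values, "values", 1)
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = sorted(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxSummary(
        n=len(x), median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )
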