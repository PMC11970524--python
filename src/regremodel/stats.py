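"""Statistical primitives shared by every pipeline stage.

Thin, validated wrappers around scipy/statsmodels with explicit degenerate-input
contracts, so that every downstream verdict (specialization call, enrichment,
program shift, lipid discriminant) rests on the same small, well-tested surface.

Conventions
-----------
* Two-sided alternatives by default.
* A Pearson chi-square on a 2x2 table carries no continuity correction:
  genomic contingency tables here have large margins, where the correction is
  conservative and uncommon.
* Mann-Whitney switches from exact enumeration to the tie-corrected normal
  approximation once the combined sample size exceeds ``exact_limit``.
* Spearman p-values come from the t-approximation for n >= 10 and from full
  permutation enumeration below that.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "welch_t_test",
    "bh_adjust",
    "spearman_correlation",
    "binomial_test",
    "chi_square_2x2",
    "mann_whitney_u",
    "two_way_anova",
]

_ALTERNATIVES = ("two_sided", "greater", "less")


def _scipy_alt(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}")
    return "two-sided" if alternative == "two_sided" else alternative


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``degrees_of_freedom`` is ``None`` where the test has no df concept
    (exact binomial, U statistic). ``degenerate`` flags inputs on which the
    statistic is undefined and the reported values follow the documented
    degenerate contract rather than the usual formula.
    """

    statistic: float
    p_value: float
    alternative: str = "two_sided"
    degrees_of_freedom: float | None = None
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class AdjustedPValues:
    raw: tuple
    adjusted: tuple
    method: str = "benjamini_hochberg"


def welch_t_test(x, y, alternative: str = "two_sided") -> TestResult:
    """Welch's unequal-variance t-test.

    Degenerate contract: if both samples have zero variance, returns
    statistic 0 / p 1 for equal means and +/-inf / p 0 for unequal means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t_test requires at least 2 values per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, alternative, None, degenerate=True)
        sign = math.copysign(1.0, x.mean() - y.mean())
        if alternative == "two_sided":
            p = 0.0
        elif alternative == "greater":
            p = 0.0 if sign > 0 else 1.0
        else:
            p = 0.0 if sign < 0 else 1.0
        return TestResult(sign * math.inf, p, alternative, None, degenerate=True)
    res = sps.ttest_ind(x, y, equal_var=False, alternative=_scipy_alt(alternative))
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      degrees_of_freedom=float(res.df))


def welch_t_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch tests for two (rows x replicates) arrays.

    Returns (mean difference, two-sided p). Zero-variance rows follow the
    scalar degenerate contract: identical rows give p 1, separated
    zero-variance rows give p 0.
    """
    import warnings

    diff = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.atleast_1d(np.asarray(p, dtype=float)).copy()
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    bad = ~np.isfinite(p) | degenerate
    if bad.any():
        p[bad & (diff == 0)] = 1.0
        p[bad & (diff != 0)] = 0.0
    return diff, p


def bh_adjust(p) -> AdjustedPValues:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return AdjustedPValues((), ())
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("all p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return AdjustedPValues(tuple(p), tuple(out))


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho: float, alternative: str) -> float:
    """Permutation p by full enumeration of y-rank orders (n < 10 only)."""
    n = rx.size
    rx_c = rx - rx.mean()
    denom = math.sqrt(float((rx_c ** 2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    obs = rho
    count_ge = count_le = count_abs = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float((rx_c * (ry[list(perm)] - ry.mean())).sum()) / denom
        total += 1
        if r >= obs - 1e-12:
            count_ge += 1
        if r <= obs + 1e-12:
            count_le += 1
        if abs(r) >= abs(obs) - 1e-12:
            count_abs += 1
    if alternative == "greater":
        return count_ge / total
    if alternative == "less":
        return count_le / total
    return count_abs / total


def spearman_correlation(x, y, alternative: str = "two_sided",
                         exact_below: int = 10) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    The statistic field carries rho. p-values use the t-approximation for
    n >= ``exact_below`` and full permutation enumeration below that.
    Constant input in either vector yields a degenerate result (rho nan, p 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_correlation requires >= 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(math.nan, 1.0, alternative, None, degenerate=True)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n < exact_below:
        p = _spearman_exact_p(rx, ry, rho, alternative)
        return TestResult(rho, p, alternative, None, extra={"n": n, "method": "exact"})
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1 - rho ** 2))
        if alternative == "two_sided":
            p = 2 * sps.t.sf(abs(t), n - 2)
        elif alternative == "greater":
            p = sps.t.sf(t, n - 2)
        else:
            p = sps.t.cdf(t, n - 2)
    return TestResult(rho, float(min(p, 1.0)), alternative, float(n - 2),
                      extra={"n": n, "method": "t_approximation"})


def binomial_test(k: int, n: int, p0: float, alternative: str = "two_sided") -> TestResult:
    """Exact binomial tail test. ``p0`` must lie strictly inside (0, 1)."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly in (0, 1); floor/cap upstream")
    res = sps.binomtest(int(k), int(n), p0, alternative=_scipy_alt(alternative))
    return TestResult(float(k), float(res.pvalue), alternative,
                      extra={"n": int(n), "p0": float(p0)})


def chi_square_2x2(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    total = t.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("chi-square undefined: zero margin")
    expected = np.outer(rows, cols) / total
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    return TestResult(stat, float(sps.chi2.sf(stat, 1)), "two_sided", 1.0)


def mann_whitney_u(x, y, alternative: str = "two_sided", exact_limit: int = 20) -> TestResult:
    """Mann-Whitney U test.

    Exact null enumeration (scipy) when the combined n is <= ``exact_limit``
    and the data are tie-free; otherwise the normal approximation with tie
    correction. All-tied degenerate input returns p 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(float(x.size * y.size / 2), 1.0, alternative, None, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=_scipy_alt(alternative), method=method)
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      extra={"method": method})


def two_way_anova(values, factor_a, factor_b) -> dict:
    """Two-way crossed ANOVA with type-II sums of squares.

    Returns ``{"factor_a": TestResult, "factor_b": TestResult,
    "interaction": TestResult}``. If any cell of the design is empty the
    interaction term is undefined: an additive model is fitted instead and
    the interaction result is flagged degenerate with p nan.
    """
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "fa": np.asarray(factor_a, dtype=object),
                       "fb": np.asarray(factor_b, dtype=object)})
    if df["fa"].nunique() < 2 or df["fb"].nunique() < 2:
        raise ValueError("two_way_anova needs >= 2 levels per factor")
    cells = df.groupby(["fa", "fb"], observed=True).size()
    full_grid = df["fa"].nunique() * df["fb"].nunique()
    has_all_cells = len(cells) == full_grid

    if float(df["value"].var(ddof=1)) == 0.0:
        zero = TestResult(0.0, 1.0, "two_sided", degenerate=True)
        return {"factor_a": zero, "factor_b": zero, "interaction": zero}

    formula = "value ~ C(fa) * C(fb)" if has_all_cells else "value ~ C(fa) + C(fb)"
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def _row(name):
        if name not in table.index:
            return TestResult(math.nan, math.nan, "two_sided", None, degenerate=True)
        r = table.loc[name]
        f = float(r["F"])
        p = float(r["PR(>F)"])
        if not math.isfinite(f):  # saturated fit: residual SS ~ 0
            return TestResult(math.inf, 0.0, "two_sided", float(r["df"]), degenerate=True)
        return TestResult(f, p, "two_sided", float(r["df"]))

    out = {"factor_a": _row("C(fa)"), "factor_b": _row("C(fb)"),
           "interaction": _row("C(fa):C(fb)")}
    if not has_all_cells:
        out["interaction"] = TestResult(math.nan, math.nan, "two_sided", None, degenerate=True)
    return out
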