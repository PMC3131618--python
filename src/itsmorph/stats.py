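"""Group statistics for per-subject metric tables.

The battery used on plate/rod morphology and elastic moduli: two-tailed
Mann-Whitney U group comparison, product-moment correlation with
significance flags, first-order partial correlation (removing the effect
of bone volume fraction), forward stepwise multiple linear regression, and
rounded percent differences between group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import erf, sqrt

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "correlation_matrix",
    "partial_correlation",
    "forward_stepwise",
    "group_percent_difference",
    "StepwiseResult",
]


def _rank_sum_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of the rank sum of the first sample.

    Dynamic program: ``ways[k][s]`` = number of k-subsets of the ranks
    ``1..n1+n2`` summing to s. Index i of the returned array corresponds
    to rank-sum ``n1(n1+1)/2 + i`` (i.e. to U = i).
    """
    n = n1 + n2
    min_sum = n1 * (n1 + 1) // 2
    max_sum = sum(range(n2 + 1, n + 1))
    ways = np.zeros((n1 + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    return ways[n1, min_sum : max_sum + 1]


def mann_whitney_u(
    sample_a,
    sample_b,
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns ``(U, p)``.

    Uses the exact permutation distribution when the pooled sample has at
    most ``exact_max_n`` observations and no ties (two-tailed p = twice the
    smaller one-tailed tail, capped at 1); otherwise the normal
    approximation with tie correction. The method used is recorded on the
    function's ``last_method`` attribute.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate pooled sample: zero variance")
    n1, n2 = a.size, b.size
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    U = r1 - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    if n1 + n2 <= exact_max_n and not has_ties:
        dist = _rank_sum_distribution(n1, n2)
        total = dist.sum()
        u_int = int(round(U))
        lo = dist[: u_int + 1].sum() / total  # P(U <= u)
        hi = dist[u_int:].sum() / total  # P(U >= u)
        p = min(1.0, 2.0 * min(lo, hi))
        mann_whitney_u.last_method = "exact"
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = float((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise ValueError("degenerate pooled sample: zero rank variance")
        z = (U - mu) / sqrt(var)
        p = min(1.0, 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0)))))
        mann_whitney_u.last_method = "normal-tie-corrected"
    return float(U), float(p)


def _p_flag(p: float) -> str:
    if p < 0.001:
        return "<.001"
    if p < 0.01:
        return "<.01"
    if p < 0.05:
        return "<.05"
    return "NS"


def correlation_matrix(
    table: pd.DataFrame,
    targets: list[str],
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """Pearson r of every predictor against every target, with flags.

    Returns a long-format frame (predictor, target, r, p, flag); flags at
    p < .001 / .01 / .05 as customary in correlation tables. Raises on a
    constant column or fewer than 3 complete rows.
    """
    predictors = predictors or [c for c in table.columns if c not in targets]
    rows = []
    for x in predictors:
        for y in targets:
            sub = table[[x, y]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete rows for ({x}, {y})")
            if sub[x].nunique() == 1 or sub[y].nunique() == 1:
                raise ValueError(f"constant column in ({x}, {y})")
            r, p = sps.pearsonr(sub[x], sub[y])
            rows.append({"predictor": x, "target": y, "r": r, "p": p, "flag": _p_flag(p)})
    return pd.DataFrame(rows)


def partial_correlation(x, y, control) -> float:
    """First-order partial correlation of x and y given one control.

    Standard identity
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``; identical to
    the correlation of the residuals of x and y each regressed on the
    control. Raises when the control is collinear with x or y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(control, float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("control variable is collinear with x or y")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


@dataclass
class StepwiseResult:
    """Entry-ordered forward stepwise regression result."""

    predictors: list[str]  # in entry order
    p_values: list[float]  # partial-F p at entry
    adjusted_r2: float
    adjusted_r: float
    coefficients: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.predictors)


def forward_stepwise(
    X: pd.DataFrame,
    y,
    alpha_enter: float = 0.05,
) -> StepwiseResult:
    """Forward stepwise OLS: greedily enter the candidate with the smallest
    partial-F p-value while it is below ``alpha_enter``.

    For adding a single variable the partial F test equals the squared t
    test of its coefficient, which is what is evaluated. Reports entry
    order and the adjusted correlation coefficient sqrt(max(adj R^2, 0)).
    """
    y = np.asarray(y, float)
    if len(X) <= 1:
        raise ValueError("need more rows than predictors entered")
    entered: list[str] = []
    p_at_entry: list[float] = []
    remaining = list(X.columns)
    while remaining:
        best_p, best_c = None, None
        for c in remaining:
            cols = entered + [c]
            design = sm.add_constant(X[cols].to_numpy(float))
            if np.linalg.matrix_rank(design) < design.shape[1]:
                continue  # collinear candidate
            fit = sm.OLS(y, design).fit()
            p = float(fit.pvalues[-1])
            if best_p is None or p < best_p:
                best_p, best_c = p, c
        if best_c is None or not (best_p < alpha_enter):
            break
        entered.append(best_c)
        p_at_entry.append(best_p)
        remaining.remove(best_c)
    if entered:
        design = sm.add_constant(X[entered].to_numpy(float))
        fit = sm.OLS(y, design).fit()
        adj = float(fit.rsquared_adj)
        coefs = dict(zip(["const"] + entered, [float(v) for v in fit.params]))
    else:
        adj = 0.0
        coefs = {}
    return StepwiseResult(
        predictors=entered,
        p_values=p_at_entry,
        adjusted_r2=adj,
        adjusted_r=float(np.sqrt(max(adj, 0.0))),
        coefficients=coefs,
    )


def group_percent_difference(
    mean_control: float, mean_iop: float, direction: str = "lower"
) -> int:
    """Rounded percent difference between group means.

    ``lower``: 100 (control - iop) / control; ``higher``:
    100 (iop - control) / control. Rounded half away from zero, as in
    everyday reporting (banker's rounding would print 42.5% as 42).
    """
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    if direction == "lower":
        pct = 100.0 * (mean_control - mean_iop) / mean_control
    elif direction == "higher":
        pct = 100.0 * (mean_iop - mean_control) / mean_control
    else:
        raise ValueError("direction must be 'lower' or 'higher'")
    return int(np.sign(pct) * np.floor(abs(pct) + 0.5))
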