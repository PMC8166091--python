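"""Two-sample t-tests shared by the expression and density-comparison stages.

The pooled-variance (Student's) test is the default everywhere because the
study design reports Student's t-test P-values; Welch's unequal-variance
variant is available behind a flag. Degenerate inputs are handled
explicitly rather than left to produce NaN: zero pooled variance with
equal means gives t=0, p=1; zero pooled variance with unequal means gives
an infinite t and p=0 (flagged by the caller).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError


def pooled_ttest(
    x, y, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test of x vs y. Returns (t, p, df)."""
    t, p, df = matrix_ttest(
        np.asarray(x, dtype=float)[None, :],
        np.asarray(y, dtype=float)[None, :],
        equal_var=equal_var,
    )
    return float(t[0]), float(p[0]), float(df[0])


def matrix_ttest(
    X: np.ndarray, Y: np.ndarray, equal_var: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise two-sided t-tests of X (g x n1) against Y (g x n2).

    Returns arrays (t, p, df) of length g. With ``equal_var`` the classic
    pooled estimator is used, df = n1 + n2 - 2; otherwise Welch's statistic
    with Satterthwaite df.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n1, n2 = X.shape[1], Y.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"t-test needs >=2 values per group, got {n1} and {n2}"
        )
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    diff = m1 - m2
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = np.full(diff.shape, float(n1 + n2 - 2))
    else:
        a, b = v1 / n1, v2 / n2
        se = np.sqrt(a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
        df = np.where(np.isfinite(df), df, float(n1 + n2 - 2))

    t = np.empty_like(diff)
    p = np.empty_like(diff)
    zero_se = se == 0
    ok = ~zero_se
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = diff[ok] / se[ok]
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df[ok])
    # degenerate: no within-group variability at all
    eq = zero_se & (diff == 0)
    ne = zero_se & (diff != 0)
    t[eq], p[eq] = 0.0, 1.0
    t[ne] = np.sign(diff[ne]) * np.inf
    p[ne] = 0.0
    return t, p, df


def hypergeom_overlap_pvalue(
    overlap: int, n_a: int, n_b: int, universe: int
) -> float:
    """P(overlap >= observed) for two sets of sizes n_a, n_b drawn from a
    shared universe — the optional enrichment check on an intersection."""
    if universe <= 0:
        raise ValidationError("empty universe for overlap test")
    return float(sps.hypergeom.sf(overlap - 1, universe, n_a, n_b))
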