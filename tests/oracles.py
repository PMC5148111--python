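"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (loops, enumeration, a second library)
so it shares no code path with the implementation it validates.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def pcit_oracle(corr: np.ndarray, clamp: float = 1.0 - 1e-12, tol: float = 1e-12) -> np.ndarray:
    """Exhaustive O(n^3) trio test, scalar arithmetic throughout."""

    def partial(rxy, rxz, ryz):
        return (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))

    c = corr.copy().astype(float)
    n = c.shape[0]
    off = ~np.eye(n, dtype=bool)
    c[off] = np.clip(c[off], -clamp, clamp)
    mask = off.copy()
    for x in range(n):
        for y in range(x + 1, n):
            for z in range(n):
                if z in (x, y):
                    continue
                pxy = partial(c[x, y], c[x, z], c[y, z])
                pxz = partial(c[x, z], c[x, y], c[y, z])
                pyz = partial(c[y, z], c[x, y], c[x, z])
                terms = [
                    num / den
                    for num, den in ((pxy, c[x, y]), (pxz, c[x, z]), (pyz, c[y, z]))
                    if abs(den) >= tol
                ]
                if not terms:
                    continue
                eps = sum(terms) / len(terms)
                if abs(c[x, y]) < abs(eps * c[x, z]) and abs(c[x, y]) < abs(eps * c[y, z]):
                    mask[x, y] = mask[y, x] = False
    return mask


def anova_oracle(y: np.ndarray, design: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Type-II two-way ANOVA for a single response via statsmodels OLS."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {"y": y, "breed": design["breed"].to_numpy(), "alt": design["altitude"].to_numpy()}
    )
    fit = smf.ols("y ~ C(breed) * C(alt)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return {
        "breed": (tab.loc["C(breed)", "F"], tab.loc["C(breed)", "PR(>F)"]),
        "altitude": (tab.loc["C(alt)", "F"], tab.loc["C(alt)", "PR(>F)"]),
        "interaction": (tab.loc["C(breed):C(alt)", "F"], tab.loc["C(breed):C(alt)", "PR(>F)"]),
    }


def bh_oracle(pvalues) -> np.ndarray:
    """Step-up rule written out directly: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def hypergeom_tail_oracle(count: int, n_total: int, ref: int, n_list: int) -> float:
    """P(X >= count) for X hypergeometric, by direct enumeration (math.comb)."""
    denom = math.comb(n_total, n_list)
    upper = min(ref, n_list)
    return sum(
        math.comb(ref, k) * math.comb(n_total - ref, n_list - k) for k in range(count, upper + 1)
    ) / denom


def quantile_normalize_oracle(x: np.ndarray) -> np.ndarray:
    """Naive quantile normalization with explicit tie averaging."""
    n, m = x.shape
    ref = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(m):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            assigned[i : k + 1] = ref[i : k + 1].mean()
            i = k + 1
        out[order, j] = assigned
    return out
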