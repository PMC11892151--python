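"""Independent reference implementations used to check the package.

Everything here is deliberately written from the mathematical definitions,
without reusing the package's vectorized internals, so agreement between the
two is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def ols_window(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of one window by the plain textbook formulas."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.max() == y.min():
        return 0.0, float(y[0]), 1.0
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * tm
    r2 = max(0.0, min(1.0, 1.0 - max(syy - sxy * sxy / sxx, 0.0) / syy))
    return slope, intercept, r2


def exhaustive_linear_window(
    t: np.ndarray, y: np.ndarray, r2_min: float, min_points: int
) -> tuple[int, int, float, str]:
    """Longest-then-earliest window with R² >= r2_min, by brute force.

    Returns (start, end, slope, qc) with the same qc conventions as
    ``laccscreen.kinetics.trim_to_linear``: ``flat`` for a qualifying window
    with constant response, ``no_linear_window`` (best min_points window by
    R²) when nothing qualifies.
    """
    n = len(t)
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            end = start + length - 1
            w = slice(start, end + 1)
            slope, _, r2 = ols_window(t[w], y[w])
            if r2 >= r2_min:
                flat = y[w].max() == y[w].min()
                return start, end, slope, ("flat" if flat else "ok")
    best = None
    for start in range(0, n - min_points + 1):
        end = start + min_points - 1
        w = slice(start, end + 1)
        slope, _, r2 = ols_window(t[w], y[w])
        if best is None or r2 > best[3]:
            best = (start, end, slope, r2)
    return best[0], best[1], best[2], "no_linear_window"


def fisher_two_sided_float(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by float hypergeometric enumeration (R convention).

    Sums hypergeometric pmf values not exceeding the observed one, with the
    customary (1 + 1e-7) relative tolerance for float ties.
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())


def variable_orfs_bruteforce(presence, reference: str, hits: list[str]) -> list[str]:
    """ORFs differing between reference and at least one hit, by plain loops."""
    out = []
    for orf in presence.columns:
        ref_val = bool(presence.loc[reference, orf])
        if any(bool(presence.loc[h, orf]) != ref_val for h in hits):
            out.append(orf)
    return out


def tip_distances(tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths of an skbio TreeNode as a plain dict."""
    dm = tree.tip_tip_distances()
    ids = list(dm.ids)
    return {
        tuple(sorted((a, b))): float(dm[ids.index(a), ids.index(b)])
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
    }
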