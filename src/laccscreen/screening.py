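"""Hit calling for producer-strain screens.

The primary screen flags strains whose activity exceeds the library median by
at least ``k`` median absolute deviations (MAD); the secondary screen confirms
hits against the reference strain with replicate Welch t-tests; dual-enzyme
screens are combined with per-strain flags and a Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreenParams",
    "mad",
    "call_primary_hits",
    "secondary_screen",
    "combine_dual_screen",
]

#: Scale factor making the MAD a consistent estimator of the standard
#: deviation under normality (1 / Phi^-1(3/4)).
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class ScreenParams:
    mad_k: float = 3.0
    mad_constant: float = MAD_CONSTANT
    alpha: float = 0.05
    alternative: str = "greater"  # or "two-sided"
    correct: str = "none"  # or "BH"

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.alternative not in ("greater", "two-sided"):
            raise ValueError("alternative must be 'greater' or 'two-sided'")
        if self.correct not in ("none", "BH"):
            raise ValueError("correct must be 'none' or 'BH'")


def mad(values, constant: float = MAD_CONSTANT) -> float:
    """Median absolute deviation: ``constant * median(|x_i - median(x)|)``.

    Even-length medians use the midpoint convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty sequence")
    if not np.all(np.isfinite(x)):
        raise ValueError("mad requires finite values")
    med = np.median(x)
    return float(constant * np.median(np.abs(x - med)))


def call_primary_hits(activities: pd.Series, params: ScreenParams = ScreenParams()) -> pd.DataFrame:
    """Flag strains whose activity strictly exceeds median + k * MAD.

    The threshold is computed over all screened strains (reference included).

    Parameters
    ----------
    activities : Series indexed by strain_id (one activity per strain, Units).

    Returns
    -------
    DataFrame with columns ``strain_id, activity_U, threshold_U, is_hit``.
    """
    if activities.index.duplicated().any():
        dup = sorted(set(activities.index[activities.index.duplicated()]))
        raise ValueError(f"multiple activities per strain: {dup}")
    bad = activities.index[~np.isfinite(activities.to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"non-finite activity for strains: {sorted(bad)}")
    x = activities.to_numpy(dtype=float)
    threshold = float(np.median(x) + params.mad_k * mad(x, params.mad_constant))
    return pd.DataFrame(
        {
            "strain_id": activities.index,
            "activity_U": x,
            "threshold_U": threshold,
            "is_hit": x > threshold,
        }
    ).reset_index(drop=True)


def secondary_screen(
    replicates: pd.DataFrame,
    reference_id: str,
    params: ScreenParams = ScreenParams(),
    enzyme: Optional[str] = None,
) -> pd.DataFrame:
    """Confirm candidate strains against the reference by Welch's t-test.

    Parameters
    ----------
    replicates : long DataFrame with columns ``strain_id, activity_U``
        (one row per biological replicate).
    reference_id : the control strain every other strain is tested against.
    params : test sidedness (default one-sided, greater), alpha, optional BH.
    enzyme : optional label copied into the output.

    Returns
    -------
    DataFrame ``strain_id, enzyme, mean_U, n, p, q, significant`` with one
    row per non-reference strain.  ``significant`` requires the strain mean
    to exceed the reference mean and p (or q under BH) < alpha.
    """
    for col in ("strain_id", "activity_U"):
        if col not in replicates.columns:
            raise ValueError(f"replicates table lacks column {col!r}")
    groups = {s: g["activity_U"].to_numpy(dtype=float) for s, g in replicates.groupby("strain_id")}
    if reference_id not in groups:
        raise ValueError(f"reference strain {reference_id!r} absent from replicate table")
    ref = groups.pop(reference_id)
    if ref.size < 2:
        raise ValueError("reference strain needs at least 2 replicates")
    rows = []
    for strain in sorted(groups):
        x = groups[strain]
        if x.size < 2:
            raise ValueError(f"strain {strain!r} needs at least 2 replicates")
        alt = "greater" if params.alternative == "greater" else "two-sided"
        res = stats.ttest_ind(x, ref, equal_var=False, alternative=alt)
        p = float(res.pvalue)
        if not np.isfinite(p):  # both groups constant and equal
            p = 1.0
        rows.append(
            {
                "strain_id": strain,
                "enzyme": enzyme,
                "mean_U": float(x.mean()),
                "n": int(x.size),
                "p": p,
                "ref_mean_U": float(ref.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if params.correct == "BH":
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        crit = out["q"]
    else:
        out["q"] = np.nan
        crit = out["p"]
    out["significant"] = (out["mean_U"] > out["ref_mean_U"]) & (crit < params.alpha)
    return out


def combine_dual_screen(res_a: pd.DataFrame, res_b: pd.DataFrame) -> tuple[pd.DataFrame, float, float]:
    """Combine two secondary screens run on the same strains.

    Returns (per-strain table with flag in {a_only, b_only, both, neither},
    Pearson r of the mean activities across all assessed strains, its
    two-sided p-value from the standard t transform).
    """
    set_a, set_b = set(res_a["strain_id"]), set(res_b["strain_id"])
    if set_a != set_b:
        raise ValueError(f"strain sets differ; symmetric difference: {sorted(set_a ^ set_b)}")
    a = res_a.set_index("strain_id").sort_index()
    b = res_b.set_index("strain_id").sort_index()
    flags = np.select(
        [
            a["significant"] & b["significant"],
            a["significant"] & ~b["significant"],
            ~a["significant"] & b["significant"],
        ],
        ["both", "a_only", "b_only"],
        default="neither",
    )
    combined = pd.DataFrame(
        {
            "strain_id": a.index,
            "mean_U_a": a["mean_U"].to_numpy(),
            "mean_U_b": b["mean_U"].to_numpy(),
            "significant_a": a["significant"].to_numpy(),
            "significant_b": b["significant"].to_numpy(),
            "flag": flags,
        }
    ).reset_index(drop=True)
    r, p = stats.pearsonr(combined["mean_U_a"], combined["mean_U_b"])
    return combined, float(r), float(p)
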