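"""Relative mRNA quantification by the comparative Ct method.

Technical replicates are averaged on the Ct scale; ΔCt = Ct(target) −
Ct(reference gene) per strain, ΔΔCt = ΔCt(strain) − ΔCt(calibrator strain),
and the relative level is efficiency^(−ΔΔCt) (2^−ΔΔCt at perfect
efficiency).  Also normalizes enzyme activity per unit mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrParams", "relative_expression", "activity_per_mrna"]


@dataclass(frozen=True)
class QpcrParams:
    target_gene: str = "ttLCC1"
    reference_gene: str = "UBC6"
    calibrator_strain: str = "BY4741"
    efficiency: float = 2.0  # amplification factor per cycle

    def __post_init__(self) -> None:
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError("efficiency must be in (1, 2]")


def relative_expression(ct: pd.DataFrame, params: QpcrParams = QpcrParams()) -> pd.Series:
    """Relative target-gene mRNA level per strain (calibrator = 1 exactly).

    Parameters
    ----------
    ct : DataFrame with columns ``strain_id, gene, technical_replicate, ct``.

    Returns
    -------
    Series indexed by strain_id.
    """
    for col in ("strain_id", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
    if not np.all(np.isfinite(ct["ct"].to_numpy(dtype=float))):
        raise ValueError("non-finite Ct values")
    mean_ct = ct.groupby(["strain_id", "gene"])["ct"].mean().unstack("gene")
    for gene in (params.target_gene, params.reference_gene):
        if gene not in mean_ct.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
        missing = mean_ct.index[mean_ct[gene].isna()]
        if len(missing):
            raise ValueError(f"strains lacking Ct for {gene!r}: {sorted(missing)}")
    if params.calibrator_strain not in mean_ct.index:
        raise ValueError(f"calibrator strain {params.calibrator_strain!r} absent from Ct table")
    delta_ct = mean_ct[params.target_gene] - mean_ct[params.reference_gene]
    ddct = delta_ct - delta_ct[params.calibrator_strain]
    level = params.efficiency ** (-ddct)
    level[params.calibrator_strain] = 1.0
    level.name = "relative_level"
    return level


def activity_per_mrna(activity: pd.Series, levels: pd.Series, calibrator: str) -> pd.Series:
    """Enzyme activity per unit relative mRNA, rescaled so the calibrator is 1.

    Invariant to a common rescaling of all activities (e.g. a change of
    units), since the calibrator rescales identically.
    """
    strains = set(activity.index)
    if strains != set(levels.index):
        raise ValueError(f"strain sets differ: {sorted(strains ^ set(levels.index))}")
    if calibrator not in strains:
        raise ValueError(f"calibrator {calibrator!r} not in tables")
    lv = levels.astype(float)
    if (lv <= 0).any():
        bad = sorted(lv.index[lv <= 0])
        raise ValueError(f"non-positive relative levels for strains: {bad}")
    ratio = activity.astype(float) / lv
    out = ratio / ratio[calibrator]
    out.name = "activity_per_mrna"
    return out
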