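"""Post-quantification analysis of DIA proteome intensity matrices.

Stages, in enforced order: replicate quality control (pairwise R² on log
intensities), cross-run median-scaling normalization, left-censored
imputation from each sample's low-intensity tail, per-strain differential
abundance against the reference strain (Welch t-tests on log2 intensities
with Benjamini-Hochberg q-values), and a recurrence filter over strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityMatrix",
    "ProteomicsParams",
    "replicate_qc",
    "median_normalize",
    "impute_minprob",
    "differential_abundance",
    "recurrence_filter",
    "cv_profile",
    "pca_samples",
]

DIR_UP = "up"
DIR_DOWN = "down"
DIR_NS = "ns"

REPLICATE_TYPES = ("technical", "biological")


@dataclass(frozen=True)
class IntensityMatrix:
    """Proteins x samples positive intensities (NaN = missing) plus sample metadata.

    ``metadata`` is indexed by sample id with columns ``strain_id,
    replicate_id, replicate_type``.
    """

    intensity: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        m, meta = self.intensity, self.metadata
        if list(m.columns) != list(meta.index):
            raise ValueError("intensity columns and metadata index must match (same order)")
        for col in ("strain_id", "replicate_id", "replicate_type"):
            if col not in meta.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        bad = set(meta["replicate_type"]) - set(REPLICATE_TYPES)
        if bad:
            raise ValueError(f"unknown replicate types {sorted(bad)}")
        vals = m.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("observed intensities must be positive")

    @property
    def n_missing(self) -> int:
        return int(self.intensity.isna().to_numpy().sum())

    def samples_of(self, strain: str, replicate_type: Optional[str] = None) -> list[str]:
        meta = self.metadata
        mask = meta["strain_id"] == strain
        if replicate_type is not None:
            mask &= meta["replicate_type"] == replicate_type
        return list(meta.index[mask])


@dataclass(frozen=True)
class ProteomicsParams:
    r2_exclude: float = 0.85
    impute_quantile: float = 0.05
    fc_min: float = 2.0
    alpha: float = 0.05
    correction: str = "BH"  # q-values reported; direction filter uses raw p unless strict_bh
    strict_bh: bool = False
    recurrence_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r2_exclude < 1):
            raise ValueError("r2_exclude must be in (0, 1)")
        if not (0 < self.impute_quantile < 1):
            raise ValueError("impute_quantile must be in (0, 1)")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.recurrence_fraction <= 1):
            raise ValueError("recurrence_fraction must be in (0, 1]")


def _pairwise_r2(m: pd.DataFrame, s1: str, s2: str) -> float:
    """Squared Pearson correlation of log10 intensities on mutually observed proteins."""
    x, y = m[s1], m[s2]
    mask = x.notna() & y.notna()
    if mask.sum() < 3:
        return np.nan
    lx, ly = np.log10(x[mask]), np.log10(y[mask])
    if lx.std() == 0 or ly.std() == 0:
        return 1.0 if np.allclose(lx, ly) else 0.0
    return float(np.corrcoef(lx, ly)[0, 1] ** 2)


def replicate_qc(m: IntensityMatrix, params: ProteomicsParams = ProteomicsParams()) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Drop samples uncorrelated with every other replicate of their strain.

    A sample is excluded iff its pairwise R² (log intensities, mutually
    observed proteins) is below ``r2_exclude`` against *every* other
    replicate of the same strain.  When exactly two replicates are mutually
    discordant, only the one with the lower median R² against all other
    samples in the dataset is excluded, so a strain is never emptied.

    Returns the filtered matrix and a QC report (one row per sample with its
    best within-strain R² and exclusion status).
    """
    meta = m.metadata
    excluded: list[str] = []
    report_rows = []
    for strain, group in meta.groupby("strain_id", sort=True):
        samples = list(group.index)
        if len(samples) < 2:
            warnings.warn(f"strain {strain!r} has a single sample; retained without QC")
            for s in samples:
                report_rows.append({"sample_id": s, "strain_id": strain, "best_r2": np.nan, "excluded": False})
            continue
        best = {}
        for s in samples:
            r2s = [_pairwise_r2(m.intensity, s, o) for o in samples if o != s]
            best[s] = np.nanmax(r2s) if not np.all(np.isnan(r2s)) else np.nan
        failing = [s for s in samples if not np.isnan(best[s]) and best[s] < params.r2_exclude]
        if len(failing) == len(samples) == 2:
            # mutual discord between the only two replicates: keep the one
            # better anchored to the rest of the dataset
            med = {}
            for s in samples:
                others = [o for o in m.intensity.columns if o != s]
                med[s] = np.nanmedian([_pairwise_r2(m.intensity, s, o) for o in others])
            failing = [min(samples, key=lambda s: (med[s], s))]
        excluded.extend(failing)
        for s in samples:
            report_rows.append(
                {"sample_id": s, "strain_id": strain, "best_r2": best[s], "excluded": s in failing}
            )
    keep = [s for s in m.intensity.columns if s not in excluded]
    filtered = IntensityMatrix(m.intensity[keep], meta.loc[keep])
    return filtered, pd.DataFrame(report_rows)


def median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Median-scaling normalization across samples.

    Each sample is divided by its own observed-value median and multiplied
    by the mean of the per-sample medians, so after normalization every
    sample's median equals that common value.  Idempotent; missing cells are
    untouched.
    """
    medians = m.intensity.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = sorted(medians.index[medians.isna()])
        raise ValueError(f"samples with no observed intensities: {bad}")
    target = float(medians.mean())
    out = m.intensity * (target / medians)
    return IntensityMatrix(out, m.metadata)


def impute_minprob(
    m: IntensityMatrix,
    params: ProteomicsParams = ProteomicsParams(),
    rng: Optional[np.random.Generator] = None,
) -> IntensityMatrix:
    """Impute missing intensities from each sample's low-abundance tail.

    Missing entries of a sample are drawn from Normal(mu, sigma) where mu is
    the sample's ``impute_quantile`` quantile of observed values and sigma
    starts at the standard deviation of the bottom decile and is halved
    until every draw for that sample is positive.  Samples with fewer than
    20 observed values fall back to the global quantile with a warning.
    Seeded and reproducible; observed cells are never altered.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    out = m.intensity.copy()
    all_obs = m.intensity.to_numpy(dtype=float)
    all_obs = all_obs[~np.isnan(all_obs)]
    for s in out.columns:
        col = out[s]
        miss = col.isna()
        if not miss.any():
            continue
        obs = col[~miss].to_numpy(dtype=float)
        if obs.size < 20:
            warnings.warn(f"sample {s!r} has {obs.size} observed values; using global quantile")
            obs = all_obs
        mu = float(np.quantile(obs, params.impute_quantile))
        tail = obs[obs <= np.quantile(obs, 0.10)]
        sigma = float(np.std(tail))
        if sigma == 0.0:
            sigma = 0.01 * mu
        draws = rng.normal(mu, sigma, size=int(miss.sum()))
        while np.any(draws <= 0):
            sigma /= 2.0
            draws = rng.normal(mu, sigma, size=int(miss.sum()))
        out.loc[miss, s] = draws
    return IntensityMatrix(out, m.metadata)


def differential_abundance(
    m: IntensityMatrix,
    strain: str,
    reference: str,
    params: ProteomicsParams = ProteomicsParams(),
) -> pd.DataFrame:
    """Per-protein Welch t-test of a strain against the reference.

    Operates on log2 intensities of a complete (imputed) matrix.  Returns a
    DataFrame ``protein_id, strain_id, log2_fc, p_value, q_value, direction``
    where direction is ``up``/``down`` when |log2_fc| >= log2(fc_min) and
    the raw p (or the BH q under ``strict_bh``) is <= alpha.
    """
    if m.n_missing:
        raise ValueError("matrix has missing cells; run impute_minprob before testing")
    gs = m.samples_of(strain)
    gr = m.samples_of(reference)
    if len(gs) < 2 or len(gr) < 2:
        raise ValueError("both groups need at least 2 replicates")
    xs = np.log2(m.intensity[gs].to_numpy(dtype=float))
    xr = np.log2(m.intensity[gr].to_numpy(dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(xs, xr, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # constant in both groups
    lfc = xs.mean(axis=1) - xr.mean(axis=1)
    q = multipletests(p, method="fdr_bh")[1]
    crit = q if params.strict_bh else p
    lim = np.log2(params.fc_min)
    direction = np.select(
        [(lfc >= lim) & (crit <= params.alpha), (lfc <= -lim) & (crit <= params.alpha)],
        [DIR_UP, DIR_DOWN],
        default=DIR_NS,
    )
    return pd.DataFrame(
        {
            "protein_id": m.intensity.index,
            "strain_id": strain,
            "log2_fc": lfc,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    ).reset_index(drop=True)


def recurrence_filter(
    records: pd.DataFrame, params: ProteomicsParams = ProteomicsParams()
) -> tuple[set[str], set[str], set[str]]:
    """Proteins recurrently affected across strains.

    A protein is recurrently up (down) when called up (down) in at least
    ``ceil(recurrence_fraction * n_strains)`` of the strains covered by
    `records`.  A protein meeting both cut-offs in conflicting directions is
    excluded from both sets and returned in the third element.
    """
    n_strains = records["strain_id"].nunique()
    if n_strains == 0:
        raise ValueError("no strains in differential records")
    need = int(np.ceil(params.recurrence_fraction * n_strains))
    counts = (
        records[records["direction"] != DIR_NS]
        .groupby(["protein_id", "direction"])["strain_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    ups = set(counts.index[counts.get(DIR_UP, pd.Series(0, index=counts.index)) >= need])
    downs = set(counts.index[counts.get(DIR_DOWN, pd.Series(0, index=counts.index)) >= need])
    conflict = ups & downs
    if conflict:
        warnings.warn(f"{len(conflict)} proteins recurrent in both directions; excluded")
    return ups - conflict, downs - conflict, conflict


def cv_profile(m: IntensityMatrix, sample_ids: Iterable[str]) -> tuple[pd.Series, float]:
    """Per-protein coefficient of variation over a sample group, plus its median.

    CVs are computed on linear-scale intensities for proteins observed in at
    least two of the given samples.
    """
    samples = list(sample_ids)
    if len(samples) < 2:
        raise ValueError("CV needs a group of at least 2 samples")
    block = m.intensity[samples]
    n_obs = block.notna().sum(axis=1)
    block = block[n_obs >= 2]
    cv = block.std(axis=1, ddof=1, skipna=True) / block.mean(axis=1, skipna=True)
    cv.name = "cv"
    return cv, float(cv.median())


def pca_samples(m: IntensityMatrix, n_components: int = 2) -> pd.DataFrame:
    """PCA of sample proteomes (log2, per-protein mean-centred, complete-case proteins)."""
    from sklearn.decomposition import PCA

    complete = m.intensity.dropna(axis=0)
    if complete.shape[0] < n_components:
        raise ValueError("too few complete-case proteins for PCA")
    x = np.log2(complete.to_numpy(dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    pca = PCA(n_components=n_components, random_state=0)
    coords = pca.fit_transform(x.T)
    out = pd.DataFrame(
        coords, index=complete.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    out.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return out
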