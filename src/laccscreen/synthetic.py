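"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates the statistical structure of the corresponding real
data: saturating A420 progress curves with read noise, a ~600-strain
activity distribution with planted high producers, presence/absence matrices
with planted enriched/depleted/compensated ORFs, additive distances from a
known tree, log-normal protein intensities with distinct technical and
biological variability plus intensity-dependent missingness, and Ct tables
with known fold changes.  All randomness flows from one seed, fanned out to
per-stage substreams so stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .pangenome import ORFPresenceMatrix

__all__ = [
    "ScreenTruth",
    "PangenomeTruth",
    "ProteomeTruth",
    "stage_rng",
    "simulate_screen",
    "simulate_secondary",
    "default_pangenome_truth",
    "default_proteome_truth",
    "simulate_pangenome",
    "simulate_distances",
    "simulate_proteomes",
    "simulate_qpcr",
]

#: Fixed substream index per pipeline stage.
_STAGES = {"screen": 0, "pangenome": 1, "distances": 2, "proteomes": 3, "qpcr": 4, "secondary": 5}

WELLS_96 = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for a named stage, derived from the global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(_STAGES)}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# primary screen
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenTruth:
    strain_ids: list[str]
    true_activity: dict[str, float]  # Units per strain
    planted_hits: list[str]
    reference_id: str

    def __post_init__(self) -> None:
        if not set(self.planted_hits) <= set(self.strain_ids):
            raise ValueError("planted_hits must be a subset of strain_ids")
        if self.reference_id not in self.strain_ids:
            raise ValueError("reference_id must be a strain")
        if any(v < 0 for v in self.true_activity.values()):
            raise ValueError("true activities must be non-negative")


def _trace(
    rng: np.random.Generator,
    times: np.ndarray,
    activity_u: float,
    noise_sd: float,
    epsilon: float,
    path_length_cm: float,
    reaction_volume_ul: float,
    a_baseline: float,
    a_max: float,
    t_lag: float,
) -> np.ndarray:
    """Lag + exponential-saturation progress curve for a given activity.

    The initial post-lag slope (AU/min) corresponds to the strain's activity
    through the Beer-Lambert relation, so there is a genuine interior linear
    phase between the lag and saturation.
    """
    slope = activity_u * epsilon * path_length_cm / (reaction_volume_ul * 1e-6) / 1e6
    r = slope / a_max if a_max > 0 else 0.0
    t_eff = np.maximum(times - t_lag, 0.0)
    y = a_baseline + a_max * (1.0 - np.exp(-r * t_eff))
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=times.size)
    return y


def simulate_screen(
    n_strains: int = 600,
    n_hits: int = 30,
    effect_size: float = 2.0,
    noise_sd: float = 0.002,
    n_timepoints: int = 61,
    seed: int = 0,
    activity_cv: float = 0.15,
    base_activity_u: float = 2.0e-4,
    reference_id: str = "BY4741",
    dt_min: float = 1.0,
    epsilon: float = 36000.0,
    path_length_cm: float = 1.0,
    reaction_volume_ul: float = 200.0,
    substrate_mm: float = 1.0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, ScreenTruth]:
    """Simulate a one-replicate primary screen across 96-well plates.

    Strain activities are log-normal around ``base_activity_u`` with
    coefficient of variation ``activity_cv``; ``n_hits`` randomly chosen
    strains are multiplied by ``effect_size``.  Progress curves saturate at
    the absorbance equivalent of the available substrate (``substrate_mm``,
    the final chromogenic-substrate concentration in the well), so faster
    wells bend earlier.  Each plate carries one reference-strain well.
    Returns (plate kinetic tables keyed by plate id, layout table with
    plate/well/strain/role, truth).
    """
    if n_strains <= 0 or n_hits < 0 or n_hits >= n_strains:
        raise ValueError("need 0 <= n_hits < n_strains and n_strains > 0")
    if effect_size < 1:
        raise ValueError("effect_size must be >= 1")
    if noise_sd < 0 or activity_cv < 0:
        raise ValueError("noise_sd and activity_cv must be non-negative")
    if n_timepoints < 10:
        raise ValueError("n_timepoints must be >= 10")

    rng = stage_rng(seed, "screen")
    strains = [f"S{i:04d}" for i in range(1, n_strains + 1)]
    hits = sorted(rng.choice(strains, size=n_hits, replace=False).tolist())
    sigma = np.sqrt(np.log1p(activity_cv**2))
    z = rng.normal(0.0, 1.0, size=n_strains)
    acts = base_activity_u * np.exp(sigma * z)
    true_activity = dict(zip(strains, acts))
    for h in hits:
        true_activity[h] *= effect_size
    true_activity[reference_id] = base_activity_u

    times = np.arange(n_timepoints, dtype=float) * dt_min
    plates: dict[str, pd.DataFrame] = {}
    layout_rows = []
    per_plate = 95  # one well per plate reserved for the reference control
    n_plates = int(np.ceil(n_strains / per_plate))
    trace_kw = dict(
        epsilon=epsilon,
        path_length_cm=path_length_cm,
        reaction_volume_ul=reaction_volume_ul,
        a_baseline=0.05,
        # full conversion of the available substrate sets the plateau
        a_max=epsilon * path_length_cm * substrate_mm * 1e-3,
        t_lag=5.0,
    )
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        block = strains[p * per_plate : (p + 1) * per_plate]
        cols = {"time_min": times}
        # reference control always occupies A1
        cols["A1"] = _trace(rng, times, true_activity[reference_id], noise_sd, **trace_kw)
        layout_rows.append(
            {"plate": plate_id, "well": "A1", "strain_id": reference_id,
             "replicate_id": plate_id, "role": "reference"}
        )
        for w, strain in zip(WELLS_96[1:], block):
            cols[w] = _trace(rng, times, true_activity[strain], noise_sd, **trace_kw)
            layout_rows.append(
                {"plate": plate_id, "well": w, "strain_id": strain, "replicate_id": "r1", "role": "sample"}
            )
        plates[plate_id] = pd.DataFrame(cols)
    layout = pd.DataFrame(layout_rows)
    truth = ScreenTruth(
        strain_ids=strains + [reference_id],
        true_activity=true_activity,
        planted_hits=hits,
        reference_id=reference_id,
    )
    return plates, layout, truth


def simulate_secondary(
    truth: ScreenTruth,
    candidates: Sequence[str],
    n_reps: int = 4,
    replicate_cv: float = 0.22,
    enzyme_b_correlation: float = 0.25,
    n_hits_b: Optional[int] = None,
    effect_size_b: float = 2.0,
    strain_cv_b: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Replicate activity tables for a dual-enzyme confirmation screen.

    Enzyme A replicates scatter log-normally (CV ``replicate_cv``) around
    each candidate's true activity from the primary-screen truth.  Enzyme B
    gets its own planted producers (``n_hits_b``, default a third of the
    candidates, at ``effect_size_b``) plus a weak log-scale coupling
    (``enzyme_b_correlation``) to enzyme A, emulating that strains producing
    one enzyme well do not necessarily produce another.  Returns two long
    tables ``strain_id, replicate_id, activity_U`` and the list of planted
    enzyme-B producers.
    """
    rng = stage_rng(seed, "secondary")
    cand = list(candidates)
    if truth.reference_id in cand:
        cand = [s for s in cand if s != truth.reference_id]
    if n_hits_b is None:
        n_hits_b = len(cand) // 3
    hits_b = sorted(rng.choice(cand, size=n_hits_b, replace=False).tolist()) if n_hits_b else []
    base = truth.true_activity[truth.reference_id]
    sig_rep = float(np.sqrt(np.log1p(replicate_cv**2)))
    sig_b = float(np.sqrt(np.log1p(strain_cv_b**2)))
    rho = enzyme_b_correlation
    rows_a, rows_b = [], []
    for s in cand + [truth.reference_id]:
        la = np.log(truth.true_activity[s] / base)
        if s == truth.reference_id:
            lb = 0.0
        else:
            lb = (
                (np.log(effect_size_b) if s in hits_b else 0.0)
                + rho * la
                + rng.normal(0.0, sig_b)
            )
        for r in range(1, n_reps + 1):
            rows_a.append(
                {"strain_id": s, "replicate_id": f"r{r}",
                 "activity_U": base * np.exp(la + rng.normal(0.0, sig_rep))}
            )
            rows_b.append(
                {"strain_id": s, "replicate_id": f"r{r}",
                 "activity_U": base * np.exp(lb + rng.normal(0.0, sig_rep))}
            )
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b), hits_b


# ---------------------------------------------------------------------------
# pan-genome presence/absence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PangenomeTruth:
    planted_enriched: list[str]
    planted_depleted: list[str]
    planted_compensated_pairs: dict[str, str]  # depleted ORF -> enriched homolog
    background_presence_rate: float = 0.3
    enriched_rate_hits: float = 0.9
    enriched_rate_rest: float = 0.15
    depleted_rate_hits: float = 0.05
    depleted_rate_rest: float = 0.75
    identities: dict[str, float] = field(default_factory=dict)  # depleted ORF -> aa identity

    def __post_init__(self) -> None:
        enr, dep = set(self.planted_enriched), set(self.planted_depleted)
        comp_dep = set(self.planted_compensated_pairs)
        comp_enr = set(self.planted_compensated_pairs.values())
        if enr & dep:
            raise ValueError("an ORF cannot be both enriched and depleted")
        if comp_dep & enr or comp_enr & dep:
            raise ValueError("compensated pairs must link a depleted ORF to an enriched homolog")
        if not (0 < self.background_presence_rate < 1):
            raise ValueError("background presence rate must be in (0, 1)")

    @property
    def all_enriched(self) -> list[str]:
        return sorted(set(self.planted_enriched) | set(self.planted_compensated_pairs.values()))

    @property
    def all_depleted(self) -> list[str]:
        return sorted(set(self.planted_depleted) | set(self.planted_compensated_pairs))


def default_pangenome_truth(
    n_enriched: int = 15, n_depleted: int = 30, n_compensated: int = 10,
    background_presence_rate: float = 0.3,
) -> PangenomeTruth:
    """Planted classes named after their role, sized like a typical screen."""
    comp = {f"COMP{i:02d}": f"COMP{i:02d}-like" for i in range(1, n_compensated + 1)}
    return PangenomeTruth(
        planted_enriched=[f"ENR{i:02d}" for i in range(1, n_enriched + 1)],
        planted_depleted=[f"DEP{i:02d}" for i in range(1, n_depleted + 1)],
        planted_compensated_pairs=comp,
        background_presence_rate=background_presence_rate,
    )


def simulate_pangenome(
    n_strains: int,
    n_orfs: int,
    truth: PangenomeTruth,
    hit_set: Sequence[str],
    seed: int = 0,
    strain_ids: Optional[Sequence[str]] = None,
    reference_strain: str = "BY4741",
    core_fraction: float = 0.7,
) -> tuple[ORFPresenceMatrix, pd.DataFrame, PangenomeTruth]:
    """Simulate a strains x ORFs presence matrix with planted classes.

    Planted enriched ORFs (including compensated homologs) are absent from
    the reference strain and present at ``enriched_rate_hits`` in hit strains
    versus ``enriched_rate_rest`` elsewhere; planted depleted ORFs
    (including the depleted member of each compensated pair) are present in
    the reference and depleted among hits.  A ``core_fraction`` of the
    background ORFs is present in every strain (core genome) and is removed
    by the variable-ORF pre-filter; the remaining accessory background ORFs
    are i.i.d. Bernoulli at the background rate.  The homology map lists
    each compensated pair with an amino-acid identity drawn uniformly from
    [0.73, 0.99].
    """
    if not (0.0 <= core_fraction <= 1.0):
        raise ValueError(f"core_fraction must be in [0, 1], got {core_fraction}")
    hit_set = list(hit_set)
    if not hit_set:
        raise ValueError("hit_set must be nonempty")
    if strain_ids is None:
        strain_ids = [f"S{i:04d}" for i in range(1, n_strains + 1)]
        if reference_strain not in strain_ids:
            strain_ids = list(strain_ids[: n_strains - 1]) + [reference_strain]
    strain_ids = list(strain_ids)
    if len(strain_ids) != n_strains:
        raise ValueError("strain_ids length must equal n_strains")
    if not set(hit_set) <= set(strain_ids):
        raise ValueError("hit_set must be a subset of the strains")
    if len(hit_set) >= n_strains:
        raise ValueError("hit_set must be smaller than the strain set")

    planted = truth.all_enriched + truth.all_depleted
    if len(planted) > n_orfs:
        raise ValueError(f"{len(planted)} planted ORFs exceed n_orfs={n_orfs}")
    n_bg = n_orfs - len(planted)
    n_core = int(round(core_fraction * n_bg))
    orf_ids = planted + [f"ORF{i:04d}" for i in range(1, n_bg + 1)]
    core = set(orf_ids[len(planted) : len(planted) + n_core])

    rng = stage_rng(seed, "pangenome")
    is_hit = np.array([s in set(hit_set) for s in strain_ids])
    ref_idx = strain_ids.index(reference_strain)
    presence = np.zeros((n_strains, n_orfs), dtype=bool)
    for k, orf in enumerate(orf_ids):
        if orf in truth.all_enriched:
            rate = np.where(is_hit, truth.enriched_rate_hits, truth.enriched_rate_rest)
            col = rng.random(n_strains) < rate
            col[ref_idx] = False
        elif orf in truth.all_depleted:
            rate = np.where(is_hit, truth.depleted_rate_hits, truth.depleted_rate_rest)
            col = rng.random(n_strains) < rate
            col[ref_idx] = True
        elif orf in core:
            col = np.ones(n_strains, dtype=bool)
        else:
            col = rng.random(n_strains) < truth.background_presence_rate
        presence[:, k] = col

    matrix = ORFPresenceMatrix(
        pd.DataFrame(presence, index=strain_ids, columns=orf_ids), reference_strain
    )
    identities = {
        dep: float(rng.uniform(0.73, 0.99)) for dep in sorted(truth.planted_compensated_pairs)
    }
    homology = pd.DataFrame(
        [
            {"orf_id": dep, "homolog_id": truth.planted_compensated_pairs[dep], "identity": identities[dep]}
            for dep in sorted(truth.planted_compensated_pairs)
        ],
        columns=["orf_id", "homolog_id", "identity"],
    )
    truth_out = PangenomeTruth(
        planted_enriched=truth.planted_enriched,
        planted_depleted=truth.planted_depleted,
        planted_compensated_pairs=truth.planted_compensated_pairs,
        background_presence_rate=truth.background_presence_rate,
        enriched_rate_hits=truth.enriched_rate_hits,
        enriched_rate_rest=truth.enriched_rate_rest,
        depleted_rate_hits=truth.depleted_rate_hits,
        depleted_rate_rest=truth.depleted_rate_rest,
        identities=identities,
    )
    return matrix, homology, truth_out


# ---------------------------------------------------------------------------
# distances / phylogeny
# ---------------------------------------------------------------------------


def simulate_distances(
    n_taxa: int,
    branch_length_range: tuple[float, float] = (0.05, 1.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, TreeNode]:
    """Random binary tree with positive branch lengths and its additive distances.

    The returned matrix holds exact leaf-to-leaf path lengths, so it is
    symmetric with zero diagonal and satisfies the four-point condition;
    neighbour joining recovers the generating tree exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    lo, hi = branch_length_range
    if not (0 < lo <= hi):
        raise ValueError("branch lengths must be positive with lo <= hi")
    rng = stage_rng(seed, "distances")
    nodes = [TreeNode(name=f"T{i:02d}") for i in range(1, n_taxa + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(lo, hi))
        b.length = float(rng.uniform(lo, hi))
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = nodes[0]
    dm = tree.tip_tip_distances()
    taxa = list(dm.ids)
    frame = pd.DataFrame(dm.data, index=taxa, columns=taxa)
    order = sorted(taxa)
    return frame.loc[order, order], tree


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteomeTruth:
    planted_fold_changes: dict[str, dict[str, float]]  # protein -> strain -> log2 effect
    cv_technical: float = 0.08
    cv_biological: float = 0.22
    missing_midpoint_log2: Optional[float] = None  # None -> derived from base mean - 2.3 sd
    missing_slope_log2: float = 1.0
    censoring: bool = True

    def __post_init__(self) -> None:
        if self.cv_technical < 0 or self.cv_biological < 0:
            raise ValueError("CV parameters must be non-negative")
        if self.cv_technical > self.cv_biological:
            raise ValueError("technical CV must not exceed biological CV")


def default_proteome_truth(
    n_proteins: int,
    strains: Sequence[str],
    n_up: int = 40,
    n_down: int = 40,
    effect_log2: float = 1.5,
    fraction_strains: float = 0.6,
    cv_technical: float = 0.08,
    cv_biological: float = 0.22,
) -> ProteomeTruth:
    """Planted differential proteins shared by a fraction of the strains.

    The first ``n_up`` proteins go up and the next ``n_down`` go down by
    ``effect_log2`` in the first ``fraction_strains`` of the strains, so the
    recurrence filter has a planted recurrent set.
    """
    if n_up + n_down > n_proteins:
        raise ValueError("planted proteins exceed n_proteins")
    strains = list(strains)
    affected = strains[: int(np.ceil(fraction_strains * len(strains)))]
    fc: dict[str, dict[str, float]] = {}
    for i in range(n_up):
        fc[f"PROT{i + 1:05d}"] = {s: effect_log2 for s in affected}
    for i in range(n_down):
        fc[f"PROT{n_up + i + 1:05d}"] = {s: -effect_log2 for s in affected}
    return ProteomeTruth(fc, cv_technical=cv_technical, cv_biological=cv_biological)


def simulate_proteomes(
    n_proteins: int,
    strains: Sequence[str],
    truth: ProteomeTruth = ProteomeTruth({}),
    n_bio_reps: int = 4,
    seed: int = 0,
    reference: str = "BY4741",
    n_tech_reps_reference: int = 14,
    n_bio_reps_reference: int = 7,
    base_mean_log2: float = 20.0,
    base_sd_log2: float = 2.0,
) -> tuple["IntensityMatrix", ProteomeTruth]:
    """Simulate a proteins x samples intensity matrix.

    Base abundances are log-normal across proteins; every sample carries
    multiplicative technical noise at ``cv_technical`` and every biological
    replicate additionally biological noise at ``cv_biological``.  The
    reference strain is replicated more deeply than the test strains, as is
    usual for the internal control of a DIA experiment: it gets
    ``n_bio_reps_reference`` biological replicates and
    ``n_tech_reps_reference`` technical replicates sharing the biological
    draw of its first replicate.  Missingness is left-censored: the
    probability of a missing cell decreases logistically with log2 intensity.
    """
    from .proteomics import IntensityMatrix

    if n_bio_reps < 2:
        raise ValueError("n_bio_reps must be >= 2")
    strains = list(strains)
    if reference not in strains:
        strains = [reference] + strains
    rng = stage_rng(seed, "proteomes")
    proteins = [f"PROT{i:05d}" for i in range(1, n_proteins + 1)]
    base = rng.normal(base_mean_log2, base_sd_log2, size=n_proteins)

    sig_t = float(np.sqrt(np.log1p(truth.cv_technical**2)))
    sig_b = float(np.sqrt(np.log1p(truth.cv_biological**2)))

    fc = np.zeros((n_proteins, len(strains)))
    pidx = {p: i for i, p in enumerate(proteins)}
    sidx = {s: i for i, s in enumerate(strains)}
    for prot, per_strain in truth.planted_fold_changes.items():
        if prot not in pidx:
            raise ValueError(f"planted fold change for unknown protein {prot!r}")
        for s, eff in per_strain.items():
            fc[pidx[prot], sidx[s]] = eff

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    ln2 = np.log(2.0)
    for s in strains:
        n_bio = n_bio_reps_reference if s == reference else n_bio_reps
        bio_draws = rng.normal(0.0, sig_b, size=(n_proteins, n_bio))
        for b in range(n_bio):
            tech = rng.normal(0.0, sig_t, size=n_proteins)
            log2_int = base + fc[:, sidx[s]] + (bio_draws[:, b] + tech) / ln2
            sample = f"{s}_b{b + 1}"
            cols[sample] = 2.0**log2_int
            meta_rows.append(
                {"sample_id": sample, "strain_id": s, "replicate_id": f"b{b + 1}",
                 "replicate_type": "biological"}
            )
        if s == reference:
            for t in range(n_tech_reps_reference):
                tech = rng.normal(0.0, sig_t, size=n_proteins)
                log2_int = base + fc[:, sidx[s]] + (bio_draws[:, 0] + tech) / ln2
                sample = f"{s}_t{t + 1}"
                cols[sample] = 2.0**log2_int
                meta_rows.append(
                    {"sample_id": sample, "strain_id": s, "replicate_id": f"t{t + 1}",
                     "replicate_type": "technical"}
                )

    intensity = pd.DataFrame(cols, index=proteins)
    if truth.censoring:
        mid = (
            truth.missing_midpoint_log2
            if truth.missing_midpoint_log2 is not None
            else base_mean_log2 - 2.3 * base_sd_log2
        )
        x = np.log2(intensity.to_numpy(dtype=float))
        p_missing = 1.0 / (1.0 + np.exp((x - mid) / truth.missing_slope_log2))
        drop = rng.random(x.shape) < p_missing
        vals = intensity.to_numpy(dtype=float)
        vals[drop] = np.nan
        intensity = pd.DataFrame(vals, index=proteins, columns=intensity.columns)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return IntensityMatrix(intensity, meta), truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    strains: Sequence[str],
    true_rel_expression: Mapping[str, float],
    ct_noise_sd: float = 0.1,
    seed: int = 0,
    calibrator: str = "BY4741",
    target_gene: str = "ttLCC1",
    reference_gene: str = "UBC6",
    efficiency: float = 2.0,
    n_tech_reps: int = 3,
    ct_target_base: float = 22.0,
    ct_reference_base: float = 18.0,
) -> pd.DataFrame:
    """Simulate a Ct table with planted relative expression levels.

    Each strain gets a random RNA-input offset added to both genes (which
    the ΔCt cancels); the target-gene Ct is shifted by -log_E(expression).
    The calibrator's expression is fixed at 1.
    """
    strains = list(strains)
    if calibrator not in strains:
        strains = [calibrator] + strains
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    expr = {s: float(true_rel_expression.get(s, 1.0)) for s in strains}
    expr[calibrator] = 1.0
    if any(v <= 0 for v in expr.values()):
        raise ValueError("relative expression levels must be positive")
    rng = stage_rng(seed, "qpcr")
    rows = []
    log_e = np.log(efficiency)
    for s in strains:
        offset = float(rng.uniform(-1.0, 1.0))
        ct_t = ct_target_base + offset - np.log(expr[s]) / log_e
        ct_r = ct_reference_base + offset
        for rep in range(1, n_tech_reps + 1):
            for gene, ct0 in ((target_gene, ct_t), (reference_gene, ct_r)):
                noise = float(rng.normal(0.0, ct_noise_sd)) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {"strain_id": s, "gene": gene, "technical_replicate": rep, "ct": ct0 + noise}
                )
    return pd.DataFrame(rows)
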