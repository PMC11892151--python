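"""Pan-genome ORF presence/absence enrichment among hit strains.

ORFs whose presence differs between any hit strain and the reference are
tested for enrichment or depletion among the hits with a two-sided Fisher
exact test; depleted ORFs that have an enriched close homolog ("ORF-like"
pan-genome genes) are reclassified as compensated.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ORFPresenceMatrix",
    "HomologyPair",
    "fisher_exact_two_sided",
    "retain_variable_orfs",
    "fisher_enrichment",
    "classify_compensation",
    "CompensationSummary",
]

CLASS_ENRICHED = "enriched"
CLASS_DEPLETED = "depleted"
CLASS_COMPENSATED = "compensated"
CLASS_NS = "ns"


@dataclass(frozen=True)
class ORFPresenceMatrix:
    """Boolean strains x ORFs presence calls with a designated reference strain."""

    presence: pd.DataFrame  # index strain_id, columns orf_id, values bool
    reference_strain: str

    def __post_init__(self) -> None:
        df = self.presence
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("strain and ORF labels must be unique")
        if df.isna().any().any():
            raise ValueError("presence matrix has missing cells")
        if self.reference_strain not in df.index:
            raise ValueError(f"reference strain {self.reference_strain!r} not in matrix")
        object.__setattr__(self, "presence", df.astype(bool))

    @property
    def strain_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def orf_ids(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class HomologyPair:
    orf_id: str
    homolog_id: str
    identity: float

    def __post_init__(self) -> None:
        if self.orf_id == self.homolog_id:
            raise ValueError("a homology pair must link two distinct ORFs")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the probabilities of all tables with the same margins whose
    hypergeometric probability does not exceed that of the observed table.
    Computed in exact integer arithmetic (probabilities compared as their
    integer numerators over the common denominator C(n, a+c)), so ties at
    the observed probability are detected exactly.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1 = a + b  # first-row margin (e.g. hit strains)
    c1 = a + c  # first-column margin (e.g. ORF present)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    num_obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = 0
    for x in range(lo, hi + 1):
        num = comb(r1, x) * comb(n - r1, c1 - x)
        if num <= num_obs:
            total += num
    return float(total / comb(n, c1))


def retain_variable_orfs(matrix: ORFPresenceMatrix, hit_set: Iterable[str]) -> list[str]:
    """ORFs whose presence in at least one hit strain differs from the reference.

    This pre-filter restricts testing to ORFs actually variable between the
    hit strains and the reference genome.
    """
    hits = list(hit_set)
    if not hits:
        raise ValueError("hit_set is empty")
    unknown = [h for h in hits if h not in matrix.presence.index]
    if unknown:
        raise ValueError(f"hit strains not in matrix: {unknown}")
    ref = matrix.presence.loc[matrix.reference_strain]
    sub = matrix.presence.loc[hits]
    differs = (sub != ref).any(axis=0)
    return [orf for orf in matrix.orf_ids if differs[orf]]


def fisher_enrichment(
    matrix: ORFPresenceMatrix,
    hit_set: Iterable[str],
    orfs: Sequence[str] | None = None,
    alpha: float = 0.05,
    correct: str = "none",
) -> pd.DataFrame:
    """Per-ORF exact test of presence in hit strains vs the rest of the library.

    Returns a DataFrame with the 2x2 counts, odds ratio, p (and BH q when
    ``correct="BH"``), and class label: ``enriched`` when the hit presence
    proportion exceeds the rest and p < alpha, ``depleted`` for the converse,
    ``ns`` otherwise.  Classification uses raw p by default.
    """
    hits = sorted(set(hit_set))
    strains = set(matrix.strain_ids)
    if not set(hits) <= strains:
        raise ValueError(f"hit strains not in matrix: {sorted(set(hits) - strains)}")
    rest = sorted(strains - set(hits))
    if not rest:
        raise ValueError("hit_set covers the whole library; no remainder to compare against")
    if orfs is None:
        orfs = matrix.orf_ids
    unknown = [o for o in orfs if o not in matrix.presence.columns]
    if unknown:
        raise ValueError(f"ORFs not in matrix: {unknown}")

    hit_block = matrix.presence.loc[hits, list(orfs)].to_numpy()
    rest_block = matrix.presence.loc[rest, list(orfs)].to_numpy()
    ph = hit_block.sum(axis=0)
    pr = rest_block.sum(axis=0)
    n_hit, n_rest = len(hits), len(rest)

    rows = []
    for k, orf in enumerate(orfs):
        a, b = int(ph[k]), n_hit - int(ph[k])
        c, d = int(pr[k]), n_rest - int(pr[k])
        p = fisher_exact_two_sided(a, b, c, d)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        prop_hit, prop_rest = a / n_hit, c / n_rest
        rows.append(
            {
                "orf_id": orf,
                "present_in_hits": a,
                "absent_in_hits": b,
                "present_in_rest": c,
                "absent_in_rest": d,
                "odds_ratio": odds,
                "p_value": p,
                "prop_hit": prop_hit,
                "prop_rest": prop_rest,
            }
        )
    out = pd.DataFrame(rows)
    if correct == "BH":
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        crit = out["q_value"]
    else:
        out["q_value"] = np.nan
        crit = out["p_value"]
    out["class"] = np.select(
        [
            (crit < alpha) & (out["prop_hit"] > out["prop_rest"]),
            (crit < alpha) & (out["prop_hit"] < out["prop_rest"]),
        ],
        [CLASS_ENRICHED, CLASS_DEPLETED],
        default=CLASS_NS,
    )
    return out.drop(columns=["prop_hit", "prop_rest"])


@dataclass(frozen=True)
class CompensationSummary:
    n_enriched: int
    n_compensated: int
    n_depleted_remaining: int


def classify_compensation(
    records: pd.DataFrame,
    homology: Iterable[HomologyPair],
    min_identity: float = 0.73,
    known_orfs: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, CompensationSummary]:
    """Relabel depleted ORFs with an enriched close homolog as compensated.

    A depleted ORF linked by a homology pair with identity >= ``min_identity``
    to an ORF classified enriched becomes ``compensated``; when several
    enriched homologs qualify, the highest-identity link is recorded in the
    ``compensated_by`` column.  Pairs referencing ORFs outside the known ORF
    universe (``known_orfs``, defaulting to the tested records) raise; pairs
    whose ORFs are known but were filtered before testing are ignored.
    """
    pairs = list(homology)
    known = set(known_orfs) if known_orfs is not None else set(records["orf_id"])
    for p in pairs:
        if p.orf_id not in known or p.homolog_id not in known:
            raise ValueError(f"homology pair references unknown ORF: {p.orf_id!r} ~ {p.homolog_id!r}")
    out = records.copy()
    out["compensated_by"] = None
    out["homolog_identity"] = np.nan
    cls = out.set_index("orf_id")["class"]
    # symmetric lookup: a pair compensates in either direction
    links: dict[str, list[tuple[float, str]]] = {}
    for p in pairs:
        if p.identity >= min_identity:
            links.setdefault(p.orf_id, []).append((p.identity, p.homolog_id))
            links.setdefault(p.homolog_id, []).append((p.identity, p.orf_id))
    for i, row in out.iterrows():
        if row["class"] != CLASS_DEPLETED:
            continue
        enriched_links = [
            (ident, other)
            for ident, other in links.get(row["orf_id"], [])
            if cls.get(other) == CLASS_ENRICHED
        ]
        if enriched_links:
            ident, other = max(enriched_links)
            out.at[i, "class"] = CLASS_COMPENSATED
            out.at[i, "compensated_by"] = other
            out.at[i, "homolog_identity"] = ident
    summary = CompensationSummary(
        n_enriched=int((out["class"] == CLASS_ENRICHED).sum()),
        n_compensated=int((out["class"] == CLASS_COMPENSATED).sum()),
        n_depleted_remaining=int((out["class"] == CLASS_DEPLETED).sum()),
    )
    return out, summary
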