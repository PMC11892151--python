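"""Configuration, stage orchestration and run reporting.

Stages run in a fixed order (simulate → quantify → screen → enrich → tree →
qpcr → proteomics) over files in one output directory; a JSON run report
records parameters, the config hash, the seed, stage counts and warnings.
Reruns with the same config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import __version__
from .kinetics import KineticsParams, quantify_plate
from .pangenome import classify_compensation, fisher_enrichment, retain_variable_orfs
from .phylo import nj_tree, root_at_outgroup, write_newick
from .proteomics import (
    ProteomicsParams,
    cv_profile,
    differential_abundance,
    impute_minprob,
    median_normalize,
    recurrence_filter,
    replicate_qc,
)
from .qpcr import QpcrParams, activity_per_mrna, relative_expression
from .screening import ScreenParams, call_primary_hits, combine_dual_screen, secondary_screen
from . import synthetic

STAGE_ORDER = ("simulate", "quantify", "screen", "enrich", "tree", "qpcr", "proteomics")

#: file produced-by map used for dependency error messages
_PRODUCERS = {
    "layout.csv": "simulate",
    "activity.tsv": "quantify",
    "primary_hits.tsv": "screen",
    "presence.tsv": "simulate",
    "homology.tsv": "simulate",
    "distances.tsv": "simulate",
    "ct.csv": "simulate",
    "intensities.tsv": "simulate",
    "samples.tsv": "simulate",
    "secondary_a.tsv": "simulate",
    "secondary_b.tsv": "simulate",
}


@dataclass
class SimulateConfig:
    n_strains: int = 600
    n_hits: int = 30
    effect_size: float = 2.0
    noise_sd: float = 0.002
    n_timepoints: int = 61
    activity_cv: float = 0.15
    n_orfs: int = 500
    n_enriched: int = 15
    n_depleted: int = 30
    n_compensated: int = 10
    background_presence_rate: float = 0.3
    core_fraction: float = 0.7
    n_taxa: int = 24
    n_proteins: int = 2000
    n_bio_reps: int = 4
    n_proteome_strains: int = 20
    secondary_n_reps: int = 4
    secondary_cv: float = 0.22
    qpcr_noise_sd: float = 0.1


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    path_length_cm: float = 1.0
    outgroup: Optional[str] = None  # default: lexicographically first taxon
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    kinetics: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)
    enrich: dict = field(default_factory=dict)  # alpha, min_identity, correct
    qpcr: dict = field(default_factory=dict)
    proteomics: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = SimulateConfig(**raw.pop("simulate", {}))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def kinetics_params(self) -> KineticsParams:
        return KineticsParams(path_length_cm=self.path_length_cm, **self.kinetics)

    def screen_params(self) -> ScreenParams:
        return ScreenParams(**self.screen)

    def qpcr_params(self) -> QpcrParams:
        return QpcrParams(**self.qpcr)

    def proteomics_params(self) -> ProteomicsParams:
        prot = dict(self.proteomics)
        prot.setdefault("seed", self.seed)
        return ProteomicsParams(**prot)


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        producer = _PRODUCERS.get(name, "an earlier stage")
        raise FileNotFoundError(
            f"stage {stage!r} needs {name}, which is produced by stage {producer!r}; run it first"
        )
    return p


class PipelineRun:
    """Executes stages and accumulates the run report."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.header = lio.provenance_header(config.config_hash(), config.seed)
        self.report: dict = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "parameters": asdict(config),
            "stages": {},
            "warnings": [],
        }

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        cfg, seed = self.config.simulate, self.config.seed
        plates, layout, truth = synthetic.simulate_screen(
            n_strains=cfg.n_strains,
            n_hits=cfg.n_hits,
            effect_size=cfg.effect_size,
            noise_sd=cfg.noise_sd,
            n_timepoints=cfg.n_timepoints,
            activity_cv=cfg.activity_cv,
            seed=seed,
            path_length_cm=self.config.path_length_cm,
        )
        for pid, plate in plates.items():
            lio.write_kinetics_csv(plate, self.out / "plates" / f"{pid}.csv", header=self.header)
        lio.write_table(layout, self.out / "layout.csv", sep=",", header=self.header)
        lio.write_truth_json(truth, self.out / "screen_truth.json")

        sec_a, sec_b, hits_b = synthetic.simulate_secondary(
            truth, truth.planted_hits, n_reps=cfg.secondary_n_reps,
            replicate_cv=cfg.secondary_cv, seed=seed,
        )
        lio.write_table(sec_a, self.out / "secondary_a.tsv", header=self.header)
        lio.write_table(sec_b, self.out / "secondary_b.tsv", header=self.header)
        lio.write_truth_json({"planted_hits_b": hits_b}, self.out / "secondary_truth.json")

        pg_truth = synthetic.default_pangenome_truth(
            cfg.n_enriched, cfg.n_depleted, cfg.n_compensated, cfg.background_presence_rate
        )
        hit20 = truth.planted_hits[: cfg.n_proteome_strains]
        matrix, homology, pg_truth = synthetic.simulate_pangenome(
            n_strains=cfg.n_strains + 1,
            n_orfs=cfg.n_orfs,
            truth=pg_truth,
            hit_set=truth.planted_hits,
            seed=seed,
            strain_ids=truth.strain_ids,
            reference_strain=truth.reference_id,
            core_fraction=cfg.core_fraction,
        )
        lio.write_presence_tsv(matrix, self.out / "presence.tsv", header=self.header)
        lio.write_homology_tsv(homology, self.out / "homology.tsv", header=self.header)
        lio.write_truth_json(pg_truth, self.out / "pangenome_truth.json")

        dm, true_tree = synthetic.simulate_distances(cfg.n_taxa, seed=seed)
        lio.write_distance_tsv(dm, self.out / "distances.tsv")
        write_newick(true_tree, self.out / "true_tree.nwk")

        prot_truth = synthetic.default_proteome_truth(cfg.n_proteins, hit20)
        m, prot_truth = synthetic.simulate_proteomes(
            cfg.n_proteins,
            strains=hit20,
            truth=prot_truth,
            n_bio_reps=cfg.n_bio_reps,
            seed=seed,
            reference=truth.reference_id,
        )
        lio.write_intensity_tsv(m, self.out / "intensities.tsv", self.out / "samples.tsv", header=self.header)
        lio.write_truth_json(prot_truth, self.out / "proteome_truth.json")

        expr = {s: float(x) for s, x in zip(hit20[:8], [4.0, 2.0, 1.0, 0.5, 0.5, 0.25, 0.25, 0.125])}
        ct = synthetic.simulate_qpcr(
            hit20[:8] + [truth.reference_id], expr, ct_noise_sd=cfg.qpcr_noise_sd, seed=seed,
            calibrator=truth.reference_id,
        )
        lio.write_table(ct, self.out / "ct.csv", sep=",", header=self.header)
        lio.write_truth_json({"true_rel_expression": expr}, self.out / "qpcr_truth.json")
        self.report["stages"]["simulate"] = {
            "n_strains": cfg.n_strains,
            "n_planted_hits": len(truth.planted_hits),
            "n_plates": len(plates),
            "n_orfs": cfg.n_orfs,
            "n_taxa": cfg.n_taxa,
            "n_proteins": cfg.n_proteins,
        }

    def quantify(self) -> None:
        layout = lio.read_layout_csv(_require(self.out, "layout.csv", "quantify"))
        params = self.config.kinetics_params()
        tables = []
        for plate_id, sub in layout.groupby("plate", sort=True):
            traces = lio.read_kinetics_csv(_require(self.out, f"plates/{plate_id}.csv", "quantify"))
            tab = quantify_plate(traces, sub, params)
            tab.insert(0, "plate", plate_id)
            tables.append(tab)
        activity = pd.concat(tables, ignore_index=True)
        lio.write_table(activity, self.out / "activity.tsv", header=self.header)
        self.report["stages"]["quantify"] = {
            "n_wells": int(len(activity)),
            "n_qc_ok": int((activity["qc"] == "ok").sum()),
            "n_flat": int((activity["qc"] == "flat").sum()),
            "n_no_linear_window": int((activity["qc"] == "no_linear_window").sum()),
        }

    def screen(self) -> None:
        activity = lio.read_table(_require(self.out, "activity.tsv", "screen"))
        params = self.config.screen_params()
        per_strain = activity.dropna(subset=["activity_U"]).groupby("strain_id")["activity_U"].mean()
        hits = call_primary_hits(per_strain, params)
        lio.write_table(hits, self.out / "primary_hits.tsv", header=self.header)

        sec_a = lio.read_table(_require(self.out, "secondary_a.tsv", "screen"))
        sec_b = lio.read_table(_require(self.out, "secondary_b.tsv", "screen"))
        truth = lio.read_truth_json(self.out / "screen_truth.json")
        reference = truth["reference_id"]
        res_a = secondary_screen(sec_a, reference, params, enzyme="ttLcc1")
        res_b = secondary_screen(sec_b, reference, params, enzyme="mtLcc1")
        combined, r, p = combine_dual_screen(res_a, res_b)
        lio.write_table(pd.concat([res_a, res_b], ignore_index=True), self.out / "secondary.tsv", header=self.header)
        lio.write_table(combined, self.out / "dual_screen.tsv", header=self.header)
        self.report["stages"]["screen"] = {
            "threshold_U": float(hits["threshold_U"].iloc[0]),
            "n_primary_hits": int(hits["is_hit"].sum()),
            "n_secondary_a": int(res_a["significant"].sum()),
            "n_secondary_b": int(res_b["significant"].sum()),
            "n_both": int((combined["flag"] == "both").sum()),
            "n_union": int((combined["flag"] != "neither").sum()),
            "pearson_r": r,
            "pearson_p": p,
        }

    def enrich(self) -> None:
        matrix = lio.read_presence_tsv(_require(self.out, "presence.tsv", "enrich"))
        homology = lio.read_homology_tsv(_require(self.out, "homology.tsv", "enrich"))
        hits_tab = lio.read_table(_require(self.out, "primary_hits.tsv", "enrich"))
        cfg = self.config.enrich
        truth = lio.read_truth_json(self.out / "screen_truth.json")
        # the enrichment compares confirmed producer strains (union of both
        # enzymes' validated hits) to the rest of the library; when no
        # secondary screen ran, fall back to the primary hit calls
        dual = self.out / "dual_screen.tsv"
        if dual.exists():
            dual_tab = lio.read_table(dual)
            hit_set = sorted(dual_tab.loc[dual_tab["flag"] != "neither", "strain_id"])
        else:
            hit_set = sorted(
                s for s in hits_tab.loc[hits_tab["is_hit"], "strain_id"] if s != truth["reference_id"]
            )
        retained = retain_variable_orfs(matrix, hit_set)
        records = fisher_enrichment(
            matrix, hit_set, retained,
            alpha=float(cfg.get("alpha", 0.05)), correct=str(cfg.get("correct", "none")),
        )
        records, summary = classify_compensation(
            records, homology, min_identity=float(cfg.get("min_identity", 0.73)),
            known_orfs=matrix.orf_ids,
        )
        lio.write_table(records, self.out / "enrichment.tsv", header=self.header)
        self.report["stages"]["enrich"] = {
            "n_hit_strains": len(hit_set),
            "n_retained_orfs": len(retained),
            "n_enriched": summary.n_enriched,
            "n_compensated": summary.n_compensated,
            "n_depleted": summary.n_depleted_remaining,
        }

    def tree(self) -> None:
        dm = lio.read_distance_tsv(_require(self.out, "distances.tsv", "tree"))
        t = nj_tree(dm)
        outgroup = self.config.outgroup or sorted(str(x) for x in dm.index)[0]
        rooted = root_at_outgroup(t, outgroup)
        write_newick(rooted, self.out / "tree.nwk")
        self.report["stages"]["tree"] = {
            "n_taxa": int(len(dm)),
            "outgroup": outgroup,
            "total_branch_length": float(sum(n.length or 0.0 for n in rooted.traverse() if n.length)),
        }

    def qpcr(self) -> None:
        ct = lio.read_ct_csv(_require(self.out, "ct.csv", "qpcr"))
        params = self.config.qpcr_params()
        levels = relative_expression(ct, params)
        activity = lio.read_table(_require(self.out, "activity.tsv", "qpcr"))
        per_strain = activity.dropna(subset=["activity_U"]).groupby("strain_id")["activity_U"].mean()
        shared = [s for s in levels.index if s in per_strain.index]
        ratios = activity_per_mrna(per_strain[shared], levels[shared], params.calibrator_strain)
        out = pd.DataFrame(
            {"strain_id": levels.index, "relative_level": levels.to_numpy()}
        ).merge(
            pd.DataFrame({"strain_id": ratios.index, "activity_per_mrna": ratios.to_numpy()}),
            on="strain_id", how="left",
        )
        lio.write_table(out, self.out / "qpcr_levels.tsv", header=self.header)
        self.report["stages"]["qpcr"] = {"n_strains": int(len(levels))}

    def proteomics(self) -> None:
        m = lio.read_intensity_tsv(
            _require(self.out, "intensities.tsv", "proteomics"),
            _require(self.out, "samples.tsv", "proteomics"),
        )
        params = self.config.proteomics_params()
        truth = lio.read_truth_json(self.out / "screen_truth.json")
        reference = truth["reference_id"]
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            filtered, qc_report = replicate_qc(m, params)
            normalized = median_normalize(filtered)
            imputed = impute_minprob(normalized, params)
        self.report["warnings"].extend(str(w.message) for w in wlist)
        lio.write_table(qc_report, self.out / "qc_report.tsv", header=self.header)
        lio.write_intensity_tsv(normalized, self.out / "normalized.tsv", self.out / "normalized_samples.tsv", header=self.header)
        lio.write_intensity_tsv(imputed, self.out / "imputed.tsv", self.out / "imputed_samples.tsv", header=self.header)

        tech = imputed.samples_of(reference, "technical")
        cv_tech = cv_profile(m, tech)[1] if len(tech) >= 2 else np.nan
        bio = imputed.samples_of(reference, "biological")
        cv_bio = cv_profile(m, bio)[1] if len(bio) >= 2 else np.nan

        strains = sorted(set(imputed.metadata["strain_id"]) - {reference})
        all_records = []
        for s in strains:
            rec = differential_abundance(imputed, s, reference, params)
            lio.write_table(rec, self.out / f"differential_{s}.tsv", header=self.header)
            all_records.append(rec)
        records = pd.concat(all_records, ignore_index=True)
        ups, downs, conflicts = recurrence_filter(records, params)
        recurrent = pd.DataFrame(
            [{"protein_id": p, "direction": "up"} for p in sorted(ups)]
            + [{"protein_id": p, "direction": "down"} for p in sorted(downs)]
        , columns=["protein_id", "direction"])
        lio.write_table(recurrent, self.out / "recurrent.tsv", header=self.header)
        self.report["stages"]["proteomics"] = {
            "n_samples_in": int(m.intensity.shape[1]),
            "n_samples_excluded": int(qc_report["excluded"].sum()),
            "n_missing_before_impute": int(normalized.n_missing),
            "median_cv_technical": float(cv_tech),
            "median_cv_biological": float(cv_bio),
            "n_strains_tested": len(strains),
            "n_recurrent_up": len(ups),
            "n_recurrent_down": len(downs),
            "n_direction_conflicts": len(conflicts),
        }

    # -- driver ---------------------------------------------------------------

    def run(self, stages: Optional[Sequence[str]] = None) -> dict:
        requested = list(stages) if stages else list(STAGE_ORDER)
        unknown = set(requested) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}; known: {STAGE_ORDER}")
        for stage in STAGE_ORDER:
            if stage in requested:
                getattr(self, stage)()
        self.write_report()
        return self.report

    def write_report(self) -> None:
        with open(self.out / "run_report.json", "w") as fh:
            json.dump(self.report, fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: PipelineConfig, stages: Optional[Sequence[str]] = None) -> dict:
    """Run the requested stages (all by default) and return the run report."""
    return PipelineRun(config).run(stages)
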