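"""Readers and writers for the pipeline's plain-text formats.

All tabular outputs carry ``#``-prefixed provenance header lines (package
version, config hash, seed); readers skip them.  Newick files stay plain so
any parser can read them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .kinetics import KineticTrace
from .pangenome import HomologyPair, ORFPresenceMatrix
from .phylo import validate_distance_matrix
from .proteomics import IntensityMatrix

__all__ = [
    "provenance_header",
    "write_table",
    "read_table",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_layout_csv",
    "read_presence_tsv",
    "write_presence_tsv",
    "read_homology_tsv",
    "write_homology_tsv",
    "read_distance_tsv",
    "write_distance_tsv",
    "read_ct_csv",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "write_truth_json",
    "read_truth_json",
]


def provenance_header(config_hash: str = "none", seed: Optional[int] = None) -> str:
    from . import __version__

    return f"# laccscreen v{__version__} config={config_hash} seed={seed}"


def write_table(
    df: pd.DataFrame,
    path,
    sep: str = "\t",
    header: Optional[str] = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        df.to_csv(fh, sep=sep, index=index)


def read_table(path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col)


# -- kinetics ---------------------------------------------------------------


def write_kinetics_csv(plate: pd.DataFrame, path, header: Optional[str] = None) -> None:
    """Plate kinetic table: first column ``time_min``, one column per well."""
    if plate.columns[0] != "time_min":
        raise ValueError("first column of a kinetic table must be 'time_min'")
    write_table(plate, path, sep=",", header=header)


def read_kinetics_csv(path) -> dict[str, KineticTrace]:
    df = read_table(path, sep=",")
    if df.columns[0] != "time_min":
        raise ValueError(f"{path}: first column must be 'time_min', got {df.columns[0]!r}")
    times = df["time_min"].to_numpy(dtype=float)
    return {
        well: KineticTrace(well, times, df[well].to_numpy(dtype=float))
        for well in df.columns[1:]
    }


def read_layout_csv(path) -> pd.DataFrame:
    df = read_table(path, sep=",")
    required = {"well", "strain_id", "replicate_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: layout is missing columns {sorted(missing)}")
    return df


# -- pan-genome -------------------------------------------------------------


def write_presence_tsv(matrix: ORFPresenceMatrix, path, header: Optional[str] = None) -> None:
    df = matrix.presence.astype(int).copy()
    df.insert(0, "strain_id", df.index)
    extra = f"# reference_strain={matrix.reference_strain}"
    full = (header.rstrip("\n") + "\n" if header else "") + extra
    write_table(df, path, sep="\t", header=full)


def read_presence_tsv(path, reference_strain: Optional[str] = None) -> ORFPresenceMatrix:
    ref = reference_strain
    with open(path) as fh:
        for line in fh:
            if line.startswith("# reference_strain="):
                ref = ref or line.strip().split("=", 1)[1]
            if not line.startswith("#"):
                break
    if ref is None:
        raise ValueError(f"{path}: no reference strain given or recorded in the file header")
    df = read_table(path, sep="\t").set_index("strain_id")
    bad = df.to_numpy()
    if not np.isin(bad, (0, 1)).all():
        raise ValueError(f"{path}: presence cells must be 0/1")
    return ORFPresenceMatrix(df.astype(bool), ref)


def write_homology_tsv(pairs: pd.DataFrame, path, header: Optional[str] = None) -> None:
    write_table(pairs[["orf_id", "homolog_id", "identity"]], path, sep="\t", header=header)


def read_homology_tsv(path) -> list[HomologyPair]:
    df = read_table(path, sep="\t")
    return [
        HomologyPair(str(r.orf_id), str(r.homolog_id), float(r.identity))
        for r in df.itertuples(index=False)
    ]


# -- distances --------------------------------------------------------------


def write_distance_tsv(dm: pd.DataFrame, path) -> None:
    validate_distance_matrix(dm)
    write_table(dm, path, sep="\t", index=True)


def read_distance_tsv(path) -> pd.DataFrame:
    dm = read_table(path, sep="\t", index_col=0)
    dm.index = dm.index.astype(str)
    dm.columns = dm.columns.astype(str)
    return validate_distance_matrix(dm)


# -- qPCR -------------------------------------------------------------------


def read_ct_csv(path) -> pd.DataFrame:
    df = read_table(path, sep=",")
    required = {"strain_id", "gene", "technical_replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Ct table is missing columns {sorted(missing)}")
    return df


# -- proteomics -------------------------------------------------------------


def write_intensity_tsv(m: IntensityMatrix, path, meta_path, header: Optional[str] = None) -> None:
    df = m.intensity.copy()
    df.insert(0, "protein_id", df.index)
    write_table(df, path, sep="\t", header=header)
    meta = m.metadata.copy()
    meta.insert(0, "sample_id", meta.index)
    write_table(meta, meta_path, sep="\t", header=header)


def read_intensity_tsv(path, meta_path) -> IntensityMatrix:
    df = read_table(path, sep="\t").set_index("protein_id")
    meta = read_table(meta_path, sep="\t").set_index("sample_id")
    return IntensityMatrix(df[list(meta.index)], meta)


# -- truth objects ----------------------------------------------------------


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth_json(truth, path, provenance: Optional[dict] = None) -> None:
    payload = _to_jsonable(truth)
    if provenance:
        payload = {"_provenance": provenance, **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> dict:
    with open(path) as fh:
        data = json.load(fh)
    data.pop("_provenance", None)
    return data
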