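"""Readers and writers for the pipeline's delimited tables.

All tables are tab-separated with a header row and a ``parcel_id`` column
(where applicable). Loaders validate labels against the atlas, reorder rows to
atlas order, and fail loudly on unknown labels or non-numeric cells so that a
misaligned input can never propagate silently.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import (
    AtlasMetadata,
    ConnectivityBundle,
    DisorderEffectSet,
    ParcelMap,
    SquareMatrix,
    canonical_parcel_id,
)

SEP = "\t"
MAX_NA_FRACTION = 0.10  # maps with more missingness than this abort the run


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=SEP)
    if df.columns.size == 1 and SEP not in open(path).readline():
        raise ValueError(f"{path}: expected tab-separated table with header")
    return df


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def _atlas_row_order(labels, atlas: AtlasMetadata, path) -> np.ndarray:
    canon = [canonical_parcel_id(str(x)) for x in labels]
    if len(set(canon)) != len(canon):
        raise ValueError(f"{path}: duplicate parcel_id rows")
    pos = {p: i for i, p in enumerate(canon)}
    missing = [p for p in atlas.parcel_id if p not in pos]
    if missing:
        raise ValueError(f"{path}: missing parcel_id {missing[0]!r}")
    extra = [c for c in canon if c not in set(atlas.parcel_id)]
    if extra:
        raise ValueError(f"{path}: unknown parcel_id {extra[0]!r}")
    return np.asarray([pos[p] for p in atlas.parcel_id], dtype=int)


def load_atlas(path) -> AtlasMetadata:
    """Read atlas.tsv (parcel_id, hemisphere, cx, cy, cz[, cyto_class])."""
    df = _read_table(path)
    need = {"parcel_id", "hemisphere", "cx", "cy", "cz"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: atlas table needs columns {sorted(need)}")
    cyto = None
    if "cyto_class" in df.columns and df["cyto_class"].notna().all():
        cyto = df["cyto_class"].to_numpy(dtype=object)
    return AtlasMetadata(
        parcel_id=np.asarray([canonical_parcel_id(s) for s in df["parcel_id"]], dtype=object),
        hemisphere=df["hemisphere"].to_numpy(dtype=object),
        centroid=df[["cx", "cy", "cz"]].to_numpy(dtype=float),
        cyto_class=cyto,
    )


def write_atlas(atlas: AtlasMetadata, path) -> None:
    df = pd.DataFrame(
        {
            "parcel_id": atlas.parcel_id,
            "hemisphere": atlas.hemisphere,
            "cx": atlas.centroid[:, 0],
            "cy": atlas.centroid[:, 1],
            "cz": atlas.centroid[:, 2],
        }
    )
    if atlas.cyto_class is not None:
        df["cyto_class"] = atlas.cyto_class
    df.to_csv(path, sep=SEP, index=False)


def load_effect_table(path, atlas: AtlasMetadata) -> DisorderEffectSet:
    """Read effects.tsv (parcel_id + one numeric Cohen's d column per disorder)."""
    df = _read_table(path)
    if "parcel_id" not in df.columns:
        raise ValueError(f"{path}: missing parcel_id column")
    order = _atlas_row_order(df["parcel_id"], atlas, path)
    disorders = [c for c in df.columns if c != "parcel_id"]
    if not disorders:
        raise ValueError(f"{path}: no disorder columns")
    values = _numeric(df[disorders], path).to_numpy(dtype=float)[order]
    na_frac = np.isnan(values).mean(axis=0)
    if np.any(na_frac > MAX_NA_FRACTION):
        bad = disorders[int(np.argmax(na_frac))]
        raise ValueError(f"{path}: column {bad!r} exceeds {MAX_NA_FRACTION:.0%} missing values")
    return DisorderEffectSet(values, disorders)


def write_effect_table(effects: DisorderEffectSet, atlas: AtlasMetadata, path) -> None:
    df = pd.DataFrame(effects.effects, columns=effects.disorder_id)
    df.insert(0, "parcel_id", atlas.parcel_id)
    df.to_csv(path, sep=SEP, index=False)


def load_square_matrix(path, atlas: AtlasMetadata, kind: str = "connectivity") -> SquareMatrix:
    """Read an n x n labelled matrix; labels validated against the atlas."""
    df = pd.read_csv(path, sep=SEP, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square")
    order = _atlas_row_order(df.index, atlas, path)
    col_order = _atlas_row_order(df.columns, atlas, path)
    entries = _numeric(df, path).to_numpy(dtype=float)[np.ix_(order, col_order)]
    return SquareMatrix(entries, list(atlas.parcel_id), kind=kind)


def write_square_matrix(m: SquareMatrix, path) -> None:
    pd.DataFrame(m.entries, index=m.labels, columns=m.labels).to_csv(path, sep=SEP)


def load_subcortical_seeds(path, atlas: AtlasMetadata) -> tuple[np.ndarray, list[str]]:
    """Read seed-to-cortex profiles (seed label index column, cortical parcel columns)."""
    df = pd.read_csv(path, sep=SEP, index_col=0)
    col_order = _atlas_row_order(df.columns, atlas, path)
    return _numeric(df, path).to_numpy(dtype=float)[:, col_order], [str(s) for s in df.index]


def write_subcortical_seeds(seeds: np.ndarray, seed_labels, atlas: AtlasMetadata, path) -> None:
    pd.DataFrame(seeds, index=list(seed_labels), columns=list(atlas.parcel_id)).to_csv(path, sep=SEP)


def load_connectivity_bundle(cortical_path, subcortical_path, atlas: AtlasMetadata,
                             modality: str = "rs-fMRI") -> ConnectivityBundle:
    cortical = load_square_matrix(cortical_path, atlas, kind="connectivity")
    seeds, labels = load_subcortical_seeds(subcortical_path, atlas)
    return ConnectivityBundle(cortical, seeds, labels, modality=modality)


def load_annotation_table(path, atlas: AtlasMetadata) -> pd.DataFrame:
    """Read a parcels x annotations table (term z maps or gene expression)."""
    df = _read_table(path)
    if "parcel_id" not in df.columns:
        raise ValueError(f"{path}: missing parcel_id column")
    order = _atlas_row_order(df["parcel_id"], atlas, path)
    cols = [c for c in df.columns if c != "parcel_id"]
    values = _numeric(df[cols], path).to_numpy(dtype=float)[order]
    return pd.DataFrame(values, index=list(atlas.parcel_id), columns=cols)


def write_annotation_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.insert(0, "parcel_id", table.index)
    out.to_csv(path, sep=SEP, index=False)


def write_parcel_map(m: ParcelMap, atlas: AtlasMetadata, path, column: str | None = None) -> None:
    pd.DataFrame({"parcel_id": atlas.parcel_id, column or (m.name or "value"): m.values}).to_csv(
        path, sep=SEP, index=False
    )


def load_parcel_map(path, atlas: AtlasMetadata) -> ParcelMap:
    df = _read_table(path)
    if "parcel_id" not in df.columns or df.columns.size != 2:
        raise ValueError(f"{path}: expected columns (parcel_id, <value>)")
    order = _atlas_row_order(df["parcel_id"], atlas, path)
    col = [c for c in df.columns if c != "parcel_id"][0]
    values = _numeric(df[[col]], path).to_numpy(dtype=float)[order, 0]
    return ParcelMap(values, name=col)


def config_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_run_manifest(path, stage: str, params: dict, seed=None) -> None:
    """Structured provenance record: stage, parameters, seed, config hash, version."""
    from . import __version__

    manifest = {
        "stage": stage,
        "software": "coalt",
        "version": __version__,
        "seed": seed,
        "params": params,
        "config_hash": config_hash({"stage": stage, "seed": seed, **params}),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_report(tables: dict[str, pd.DataFrame], out_dir, stage: str, params: dict, seed=None) -> None:
    """Write named result tables plus one run manifest into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep=SEP, index=False)
    write_run_manifest(out / "run_manifest.json", stage, params, seed=seed)
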