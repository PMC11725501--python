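"""File I/O: count matrices (MatrixMarket or dense CSV/TSV), prediction
tables, and lossless serialization of the frozen reference model.

A persisted model is a directory holding a JSON manifest (schema version,
config, array shapes, SHA-256 checksums), an HDF5 container for all numeric
arrays, and pickled embedding/classifier models. Loading re-verifies
checksums and the model invariants, so a round trip reproduces projections
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import pickle
from pathlib import Path
from typing import List, Optional

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .config import Config
from .containers import (
    ClassifierSet,
    CountMatrix,
    GeneSelection,
    MergeRecord,
    PredictionResult,
    ReferenceModel,
)
from .errors import FormatError, IncompatibleModelError, ValidationError

SCHEMA_VERSION = "1.0"
_ARRAYS_FILE = "arrays.h5"
_PICKLES = ("embed2.pkl", "embed_latent.pkl", "classifiers.pkl")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path,
    format: str = "mtx",
    meta_path=None,
    genes_path=None,
    cells_path=None,
) -> CountMatrix:
    """Read raw counts from MatrixMarket (+ gene/cell ID files) or dense CSV/TSV.

    MTX uses 1-based indices with genes as rows; ``genes_path``/``cells_path``
    default to genes.tsv / barcodes.tsv next to the matrix. Dense files carry
    gene ids in the first column and cell ids in the header. ``meta_path`` is
    an optional TSV with columns cell_id, batch, time_point, label; cells
    missing metadata get batch="default".
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "mtx":
        genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
        cells_path = Path(cells_path) if cells_path else path.parent / "barcodes.tsv"
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"no such file: {p}")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as e:
            raise FormatError(f"cannot parse MatrixMarket file {path}: {e}") from e
        mat = sp.coo_matrix(mat)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix declares {mat.shape} but ID files list "
                f"{len(genes)} genes x {len(cells)} cells"
            )
        dense = np.asarray(mat.todense())
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        dense = df.to_numpy()
    else:
        raise FormatError(f"unknown format {format!r}")
    if not np.allclose(dense, np.round(dense)) or (dense < 0).any():
        raise ValidationError("counts must be non-negative integers")
    dense = np.round(dense).astype(np.int64)

    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    if meta_path is not None:
        user = pd.read_csv(meta_path, sep="\t").set_index("cell_id")
        meta = meta.join(user, how="left")
    for col, default in (("batch", "default"), ("time_point", None), ("label", None)):
        if col not in meta.columns:
            meta[col] = default
    meta["batch"] = meta["batch"].fillna("default")
    return CountMatrix(genes, cells, dense, meta)


def write_count_matrix(m: CountMatrix, out_dir) -> None:
    """Inverse of the MTX reader: matrix.mtx + genes.tsv + barcodes.tsv + meta.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts))
    pd.Series(m.genes).to_csv(out / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cells).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)
    m.cell_meta.rename_axis("cell_id").to_csv(out / "meta.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Prediction table
# ---------------------------------------------------------------------------

def write_prediction_table(pred: PredictionResult, path) -> int:
    """TSV with cell_id, predicted_label, probability, flags, neighborhood_ids
    in input cell order; returns the number of data rows."""
    t = pred.table
    out = pd.DataFrame(
        dict(
            cell_id=t["cell_id"],
            predicted_label=t["label"],
            probability=["" if pd.isna(p) else f"{p:.6g}" for p in t["probability"]],
            flags=[",".join(sorted(f)) for f in t["flags"]],
            neighborhood_ids=[",".join(str(i) for i in ids) for ids in t["neighborhood_ids"]],
        )
    )
    out.to_csv(path, sep="\t", index=False)
    return len(out)


# ---------------------------------------------------------------------------
# Reference model persistence
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_strings(grp, name: str, values: List[str]) -> None:
    grp.create_dataset(name, data=np.array([s.encode() for s in values]))


def _read_strings(grp, name: str) -> List[str]:
    return [b.decode() for b in grp[name][()]]


def save_reference_model(model: ReferenceModel, path) -> dict:
    """Persist the model to a directory; returns the manifest."""
    missing = model.missing_fields()
    if missing:
        raise ValidationError(f"cannot save incomplete model; missing: {missing}")
    model.validate()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    h5path = out / _ARRAYS_FILE
    with h5py.File(h5path, "w") as f:
        f.create_dataset("grand_centers", data=model.grand_centers)
        f.create_dataset("rotation", data=model.rotation)
        f.create_dataset("corrected_coords", data=model.corrected_coords)
        f.create_dataset("ref_unit_matrix", data=model.ref_unit_matrix)
        f.create_dataset("clusters", data=np.asarray(model.clusters, dtype=np.int64))
        _write_strings(f, "cells", model.cells)
        _write_strings(f, "lineages", list(model.lineages))
        _write_strings(f, "dataset_of_cell", list(model.dataset_of_cell))
        _write_strings(f, "gene_selection", model.gene_selection.genes)
        mg = f.create_group("merge_records")
        for rec in model.merge_records:
            g = mg.create_group(f"step{rec.step:03d}")
            g.attrs["step"] = rec.step
            g.attrs["batch_id"] = rec.batch_id
            g.attrs["target_mean"] = rec.target_mean
            g.attrs["mean_proj_existing"] = rec.mean_proj_existing
            g.attrs["mean_proj_incoming"] = rec.mean_proj_incoming
            g.attrs["kernel_bandwidth"] = rec.kernel_bandwidth
            g.attrs["variance_adjusted"] = rec.variance_adjusted
            g.attrs["degenerate"] = rec.degenerate
            g.create_dataset("pairs_existing", data=rec.pairs_existing)
            g.create_dataset("pairs_incoming", data=rec.pairs_incoming)
            g.create_dataset("batch_vector", data=rec.batch_vector)
    for name, obj in (("embed2.pkl", model.embed2), ("embed_latent.pkl", model.embed_latent),
                      ("classifiers.pkl", model.classifiers)):
        with open(out / name, "wb") as fh:
            pickle.dump(obj, fh)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": model.config.to_dict(),
        "rescale": model.rescale,
        "gene_selection_truncated": model.gene_selection.truncated,
        "shapes": {
            "grand_centers": list(model.grand_centers.shape),
            "rotation": list(model.rotation.shape),
            "corrected_coords": list(model.corrected_coords.shape),
            "ref_unit_matrix": list(model.ref_unit_matrix.shape),
        },
        "n_cells": len(model.cells),
        "n_merge_records": len(model.merge_records),
        "checksums": {p.name: _sha256(p) for p in [h5path] + [out / n for n in _PICKLES]},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_reference_model(path) -> ReferenceModel:
    """Load a persisted model, verifying schema version and checksums."""
    out = Path(path)
    mpath = out / "manifest.json"
    if not mpath.exists():
        raise IncompatibleModelError(f"no manifest.json in {out}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    major = str(manifest.get("schema_version", "")).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise IncompatibleModelError(
            f"schema version {manifest.get('schema_version')} incompatible with {SCHEMA_VERSION}"
        )
    for name, expected in manifest["checksums"].items():
        p = out / name
        if not p.exists():
            raise IncompatibleModelError(f"missing array file: {name}")
        actual = _sha256(p)
        if actual != expected:
            raise IncompatibleModelError(f"checksum mismatch for {name}")
    with h5py.File(out / _ARRAYS_FILE, "r") as f:
        grand_centers = f["grand_centers"][()]
        rotation = f["rotation"][()]
        corrected = f["corrected_coords"][()]
        ref_units = f["ref_unit_matrix"][()]
        clusters = f["clusters"][()]
        cells = _read_strings(f, "cells")
        lineages = _read_strings(f, "lineages")
        dataset_of_cell = _read_strings(f, "dataset_of_cell")
        sel_genes = _read_strings(f, "gene_selection")
        records = []
        for key in sorted(f["merge_records"]):
            g = f["merge_records"][key]
            records.append(
                MergeRecord(
                    step=int(g.attrs["step"]),
                    batch_id=str(g.attrs["batch_id"]),
                    pairs_existing=g["pairs_existing"][()],
                    pairs_incoming=g["pairs_incoming"][()],
                    batch_vector=g["batch_vector"][()],
                    target_mean=float(g.attrs["target_mean"]),
                    mean_proj_existing=float(g.attrs["mean_proj_existing"]),
                    mean_proj_incoming=float(g.attrs["mean_proj_incoming"]),
                    kernel_bandwidth=float(g.attrs["kernel_bandwidth"]),
                    variance_adjusted=bool(g.attrs["variance_adjusted"]),
                    degenerate=bool(g.attrs.get("degenerate", False)),
                )
            )
    objs = {}
    for name in _PICKLES:
        with open(out / name, "rb") as fh:
            objs[name] = pickle.load(fh)
    model = ReferenceModel(
        config=Config.from_dict(manifest["config"]),
        gene_selection=GeneSelection(sel_genes, None, manifest.get("gene_selection_truncated", False)),
        rescale=manifest["rescale"],
        grand_centers=grand_centers,
        rotation=rotation,
        merge_records=records,
        corrected_coords=corrected,
        clusters=clusters,
        lineages=lineages,
        embed2=objs["embed2.pkl"],
        embed_latent=objs["embed_latent.pkl"],
        classifiers=objs["classifiers.pkl"],
        ref_unit_matrix=ref_units,
        cells=cells,
        dataset_of_cell=dataset_of_cell,
    )
    model.validate()
    return model
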