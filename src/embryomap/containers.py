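"""In-memory data containers shared by the pipeline stages.

All expression matrices are stored gene x cell with explicit, ordered string
identifiers on both axes to avoid silent transposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: labels a prediction may carry besides a reference lineage
SPECIAL_LABELS = ("ambiguous", "nonrelated", "nb_failed")

META_COLUMNS = ("batch", "time_point", "label")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate {what} identifiers")


@dataclass
class CountMatrix:
    """Raw integer counts (genes x cells) plus per-cell metadata.

    ``cell_meta`` is indexed by cell id with columns batch / time_point / label.
    """

    genes: List[str]
    cells: List[str]
    counts: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.genes, "gene")
        _check_unique(self.cells, "cell")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != (genes={len(self.genes)}, cells={len(self.cells)})"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts must be non-negative")
        missing = set(self.cells) - set(self.cell_meta.index)
        if missing:
            raise ValidationError(f"cells missing from cell_meta: {sorted(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in self.cell_meta.columns:
                self.cell_meta[col] = None
        self.cell_meta = self.cell_meta.loc[self.cells]

    # -- helpers -----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def totals(self) -> np.ndarray:
        """Per-cell library sizes."""
        return self.counts.sum(axis=0)

    def subset_cells(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        cells = [self.cells[i] for i in keep]
        return CountMatrix(
            list(self.genes), cells, self.counts[:, keep], self.cell_meta.iloc[keep].copy()
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        genes = [self.genes[i] for i in keep]
        return CountMatrix(genes, list(self.cells), self.counts[keep, :], self.cell_meta.copy())

    def batches(self) -> pd.Series:
        return self.cell_meta["batch"]


@dataclass
class SizeFactors:
    """Per-cell positive scale factors, mean 1 within the dataset."""

    cells: List[str]
    factors: np.ndarray
    method: str  # "library" or "pooling"

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if self.factors.shape != (len(self.cells),):
            raise ValidationError("SizeFactors: one factor per cell required")
        if not np.all(self.factors > 0):
            raise ValidationError("SizeFactors: all factors must be positive")
        if not np.all(np.isfinite(self.factors)):
            raise ValidationError("SizeFactors: factors must be finite")


@dataclass
class LogMatrix:
    """log2(1 + normalized count), genes x cells, with its rescale provenance."""

    genes: List[str]
    cells: List[str]
    values: np.ndarray
    rescale_record: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError("LogMatrix: shape mismatch")
        if self.values.size and self.values.min() < -1e-9:
            raise ValidationError("LogMatrix: entries must be >= 0")


@dataclass
class UnitMatrix:
    """Expression restricted to the integration features, each cell unit-norm."""

    genes: List[str]
    cells: List[str]
    values: np.ndarray
    zero_columns: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValidationError("UnitMatrix: shape mismatch")


@dataclass
class GeneSelection:
    """Ordered integration-feature list plus the per-batch ranks used in voting."""

    genes: List[str]
    ranks: Optional[pd.DataFrame] = None  # genes x batches, 0-based rank per batch
    truncated: bool = False  # fewer shared genes than requested

    def __post_init__(self) -> None:
        _check_unique(self.genes, "selected gene")


@dataclass
class PCASpace:
    """Grand-centered SVD subspace shared by all reference batches."""

    genes: List[str]
    cells: List[str]
    grand_centers: np.ndarray  # (n_genes,)
    rotation: np.ndarray  # (n_genes, d), orthonormal columns
    coords: np.ndarray  # (n_cells, d)

    def __post_init__(self) -> None:
        d = self.rotation.shape[1]
        gram = self.rotation.T @ self.rotation
        if not np.allclose(gram, np.eye(d), atol=1e-8):
            raise ValidationError("PCASpace: rotation columns not orthonormal")


@dataclass
class MergeRecord:
    """Everything needed to replay one MNN merge step on a query."""

    step: int
    batch_id: str
    pairs_existing: np.ndarray  # indices into merged-so-far reference
    pairs_incoming: np.ndarray  # indices into the incoming batch
    batch_vector: np.ndarray  # unit direction in the subspace
    target_mean: float  # pooled mean projection both sides were centered to
    mean_proj_existing: float
    mean_proj_incoming: float
    kernel_bandwidth: float
    variance_adjusted: bool
    degenerate: bool = False  # no detectable batch direction: orthogonalization skipped

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.batch_vector))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValidationError("MergeRecord: batch_vector must be unit norm")


@dataclass
class PairSet:
    """Filtered/unfiltered MNN links between query and reference cells.

    ``pairs`` columns: query (int), ref (int), ref_dataset, ref_lineage,
    corr (Spearman), repeat, chunk, k.
    """

    pairs: pd.DataFrame

    COLUMNS = ("query", "ref", "ref_dataset", "ref_lineage", "corr", "repeat", "chunk", "k")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.pairs.columns:
                raise ValidationError(f"PairSet missing column {col!r}")
        if len(self.pairs):
            c = self.pairs["corr"].to_numpy(float)
            if np.nanmax(np.abs(c)) > 1 + 1e-9:
                raise ValidationError("PairSet: Spearman correlations must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls) -> "PairSet":
        return cls(pd.DataFrame({c: [] for c in cls.COLUMNS}))

    def supported_lineages(self) -> set:
        return set(self.pairs["ref_lineage"].unique())


@dataclass
class ProjectionResult:
    """Query coordinates in the frozen reference frame plus gating statistics."""

    cells: List[str]
    raw_coords: np.ndarray
    corrected_coords: np.ndarray
    embed2_coords: np.ndarray
    latent_coords: np.ndarray
    pair_set: PairSet  # after filtering
    pair_set_unfiltered: PairSet
    nonrelated_mask: np.ndarray
    corr_stats: np.ndarray
    no_mnn_support: bool = False  # correction fell back to identity
    imputed_gene_count: int = 0
    filter_report: dict = field(default_factory=dict)
    nhoods: Optional["NeighborhoodAssignment"] = None

    def __post_init__(self) -> None:
        n = len(self.cells)
        for name in ("raw_coords", "corrected_coords", "embed2_coords", "latent_coords"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"ProjectionResult: {name} row count != cell count")
        if self.nonrelated_mask.shape != (n,) or self.corr_stats.shape != (n,):
            raise ValidationError("ProjectionResult: mask/stat length != cell count")


@dataclass
class PredictionResult:
    """Per-cell label over lineages plus the abstention labels.

    ``table`` columns: cell_id, label, probability (NaN for non-lineage labels),
    flags (frozenset), neighborhood_ids (tuple of ints).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"cell_id", "label", "probability", "flags", "neighborhood_ids"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"PredictionResult missing columns {need - set(self.table.columns)}")
        special = self.table["label"].isin(SPECIAL_LABELS)
        has_prob = self.table["probability"].notna()
        if (special & has_prob).any():
            raise ValidationError("PredictionResult: non-lineage labels must not carry probability")
        if ((~special) & (~has_prob)).any():
            raise ValidationError("PredictionResult: lineage labels must carry probability")

    def labels(self) -> pd.Series:
        return self.table.set_index("cell_id")["label"]


@dataclass
class NeighborhoodAssignment:
    """Index cells, memberships and summed counts of kNN neighborhoods."""

    index_cells: List[int]
    members: List[np.ndarray]
    aggregated_counts: CountMatrix
    cell_to_nhoods: Dict[int, List[int]]
    unassigned: List[int]

    def __post_init__(self) -> None:
        if len(self.index_cells) != len(self.members):
            raise ValidationError("NeighborhoodAssignment: one member list per index cell")
        assigned = set()
        for m in self.members:
            assigned.update(int(i) for i in m)
        if assigned & set(self.unassigned):
            raise ValidationError("NeighborhoodAssignment: unassigned cell appears in a neighborhood")


@dataclass
class Metrics:
    """Agreement metrics between predicted and reference annotations."""

    kappa: float
    accuracy: float
    per_class: pd.DataFrame  # index class, columns precision / recall / support
    confusion: pd.DataFrame

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.kappa <= 1 + 1e-9:
            raise ValidationError("Metrics: kappa outside [-1, 1]")
        if not 0 <= self.accuracy <= 1:
            raise ValidationError("Metrics: accuracy outside [0, 1]")


@dataclass
class ClassifierSet:
    """One probabilistic one-vs-rest classifier per reference lineage."""

    lineages: List[str]
    models: dict  # lineage -> fitted sklearn estimator with predict_proba
    best_params: dict  # lineage -> {"C": float, "gamma": float}
    cv_records: dict  # lineage -> DataFrame(C, gamma, mean_kappa)

    def __post_init__(self) -> None:
        missing = [l for l in self.lineages if l not in self.models]
        if missing:
            raise ValidationError(f"ClassifierSet: missing models for {missing}")

    def predict_proba(self, X: np.ndarray) -> pd.DataFrame:
        """Per-lineage positive-class probability for each row of X."""
        cols = {}
        for lin in self.lineages:
            model = self.models[lin]
            proba = model.predict_proba(X)
            pos = list(model.classes_).index(1)
            cols[lin] = proba[:, pos]
        return pd.DataFrame(cols)


@dataclass
class ReferenceModel:
    """The frozen atlas: everything recorded during construction that a query
    projection replays (rescale target, gene selection, grand centers, rotation,
    merge records) plus embeddings, clusters, lineage labels and classifiers."""

    config: "object"
    gene_selection: GeneSelection
    rescale: dict  # {"target_coverage": float, "scale_by_batch": {batch: s}, "method": str}
    grand_centers: np.ndarray
    rotation: np.ndarray
    merge_records: List[MergeRecord]
    corrected_coords: np.ndarray
    clusters: np.ndarray
    lineages: List[str]  # per-cell lineage label
    embed2: "object"
    embed_latent: "object"
    classifiers: ClassifierSet
    ref_unit_matrix: np.ndarray  # selection genes x reference cells
    cells: List[str]
    dataset_of_cell: List[str]

    REQUIRED = (
        "config", "gene_selection", "rescale", "grand_centers", "rotation",
        "merge_records", "corrected_coords", "clusters", "lineages", "embed2",
        "embed_latent", "classifiers", "ref_unit_matrix", "cells", "dataset_of_cell",
    )

    def missing_fields(self) -> List[str]:
        return [f for f in self.REQUIRED if getattr(self, f, None) is None]

    def validate(self) -> None:
        missing = self.missing_fields()
        if missing:
            raise ValidationError(f"ReferenceModel incomplete; missing: {missing}")
        d = self.rotation.shape[1]
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(d), atol=1e-8):
            raise ValidationError("ReferenceModel: rotation columns not orthonormal")
        n = len(self.cells)
        if self.corrected_coords.shape[0] != n:
            raise ValidationError("ReferenceModel: corrected_coords row count != cell count")
        if len(self.lineages) != n or len(self.dataset_of_cell) != n or len(self.clusters) != n:
            raise ValidationError("ReferenceModel: per-cell annotations length mismatch")

    @property
    def lineage_names(self) -> List[str]:
        return sorted(set(self.lineages))
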