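"""Configuration objects for the reference/projection/prediction pipeline.

Defaults follow the published protocol the pipeline implements: query MNN
search with K=30 (K=5 for queries under 50 cells) on 200-cell subsamples
repeated five times, a Spearman threshold of 0.5 with the top-20 correlated
reference cells, a classifier probability floor of 0.5, a 50-dimensional
corrected PCA subspace, 4,000 integration features (2,000 in a first pass over
the designated early-stage batches), a 20-dimensional classifier latent space,
and a neighborhood sampling proportion of 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

from .errors import ValidationError


@dataclass
class QCThresholds:
    """Per-cell and per-gene quality-control cutoffs.

    ``min_genes`` is the minimum number of expressed genes per cell (cells with
    fewer are dropped), ``max_mito_frac`` the maximum tolerated mitochondrial
    count fraction (strict upper bound), and ``min_cells_per_gene`` the minimum
    number of remaining cells in which a gene must be expressed to be kept.
    """

    min_genes: int = 2000
    max_genes: Optional[int] = None
    max_mito_frac: float = 0.125
    min_cells_per_gene: int = 5

    def __post_init__(self) -> None:
        if self.max_genes is not None and not self.min_genes < self.max_genes:
            raise ValidationError("QCThresholds: min_genes must be < max_genes when both set")
        if not 0.0 <= self.max_mito_frac <= 1.0:
            raise ValidationError("QCThresholds: max_mito_frac must lie in [0, 1]")
        if self.min_genes < 0 or self.min_cells_per_gene < 0:
            raise ValidationError("QCThresholds: negative threshold")


@dataclass
class DEGCriteria:
    """Multi-criteria consensus filters for differential expression.

    A gene is retained only if it passes every enabled criterion across the
    per-comparison results: minimum average expression in the upregulated
    group, a log2 fold-change floor met in at least ``min_comparisons_fc``
    comparisons, an adjusted-p ceiling met in at least ``min_comparisons_p``
    comparisons, expressing-fraction bounds (``pct_high_floor`` in the high
    group, ``pct_low_ceiling`` in the low group) met in at least
    ``min_comparisons_pct`` comparisons (None = all), and optionally a
    Bonferroni-adjusted Stouffer-combined p below ``alpha``. Setting a
    threshold to None disables that criterion.
    """

    min_mean_expr_up: Optional[float] = 10.0
    min_log2fc: float = 0.25
    min_comparisons_fc: Optional[int] = None  # None = all comparisons
    min_comparisons_p: Optional[int] = None
    min_comparisons_pct: Optional[int] = None
    alpha: float = 0.05
    pct_high_floor: Optional[float] = 0.5
    pct_low_ceiling: Optional[float] = 0.25
    require_stouffer: bool = False
    exclude_sex_chromosomes: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValidationError("DEGCriteria: alpha must lie in (0, 1]")
        for name in ("pct_high_floor", "pct_low_ceiling"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValidationError(f"DEGCriteria: {name} must lie in [0, 1]")


def _pow2_range(lo: int, hi: int) -> tuple:
    return tuple(float(2.0**e) for e in range(lo, hi + 1))


@dataclass
class Config:
    """Pipeline-wide parameters; see module docstring for provenance of defaults."""

    k_mnn_query: int = 30
    k_mnn_small: int = 5
    k_mnn_ref: int = 20
    subsample_size: int = 200
    n_repeats: int = 5
    corr_threshold: float = 0.5
    top_n_corr: int = 20
    prob_threshold: float = 0.5
    n_pcs: int = 50
    n_hvg_total: int = 4000
    n_hvg_stage1: int = 2000
    latent_dim: int = 20
    nhood_prop: float = 0.15
    nhood_k: int = 30
    ndist: float = 3.0
    leiden_resolution: float = 1.0
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    rng_seed: int = 0
    size_factor_method: str = "pooling"
    mnn_space: str = "subspace"  # or "cosine": search MNNs on unit-vector values
    per_cell_mnn_support: bool = False
    sparse_gene_floor: int = 5000  # median expressed genes below this triggers aggregation
    min_query_gene_coverage: float = 0.8
    svm_c_grid: Sequence[float] = field(default_factory=lambda: _pow2_range(-2, 6))
    svm_gamma_grid: Sequence[float] = field(default_factory=lambda: _pow2_range(-8, 2))
    qc: QCThresholds = field(default_factory=QCThresholds)
    deg: DEGCriteria = field(default_factory=DEGCriteria)
    ambiguous_lineage_pairs: Sequence[Sequence[str]] = field(
        default_factory=lambda: [("TE", "Amnion")]
    )

    def __post_init__(self) -> None:
        counts = dict(
            k_mnn_query=self.k_mnn_query,
            k_mnn_small=self.k_mnn_small,
            k_mnn_ref=self.k_mnn_ref,
            subsample_size=self.subsample_size,
            n_repeats=self.n_repeats,
            top_n_corr=self.top_n_corr,
            n_pcs=self.n_pcs,
            n_hvg_total=self.n_hvg_total,
            n_hvg_stage1=self.n_hvg_stage1,
            latent_dim=self.latent_dim,
            nhood_k=self.nhood_k,
            umap_neighbors=self.umap_neighbors,
        )
        for name, v in counts.items():
            if int(v) < 1:
                raise ValidationError(f"Config: {name} must be >= 1 (got {v})")
        for name in ("corr_threshold", "prob_threshold", "nhood_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"Config: {name} must lie in [0, 1] (got {v})")
        if self.latent_dim > self.n_pcs:
            raise ValidationError("Config: latent_dim must be <= n_pcs")
        if self.subsample_size < self.k_mnn_query:
            raise ValidationError("Config: subsample_size must be >= k_mnn_query")
        if self.size_factor_method not in ("library", "pooling"):
            raise ValidationError("Config: size_factor_method must be 'library' or 'pooling'")
        if self.mnn_space not in ("subspace", "cosine"):
            raise ValidationError("Config: mnn_space must be 'subspace' or 'cosine'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        d = dict(d)
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCThresholds(**d["qc"])
        if isinstance(d.get("deg"), dict):
            d["deg"] = DEGCriteria(**d["deg"])
        if "ambiguous_lineage_pairs" in d:
            d["ambiguous_lineage_pairs"] = [tuple(p) for p in d["ambiguous_lineage_pairs"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
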