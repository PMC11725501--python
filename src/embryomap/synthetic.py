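"""Synthetic single-cell count data with the structure the pipeline assumes.

The generator emulates a small embryo-like study: a handful of batches, each
containing the same branching lineage hierarchy (root -> inner/outer -> two
terminal fates), deep full-length-style counts with log-normal library sizes,
negative-binomial gene-level noise, and per-batch gene-wise multiplicative
distortions. A "sparse" mode binomially downsamples counts to droplet-like
depth. All randomness flows from a single seed through named child streams so
that the reference series, queries and unrelated datasets drawn from the same
config share the same underlying gene programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import CountMatrix
from .errors import ValidationError

DEFAULT_TREE: Dict[str, Optional[str]] = {
    "Prelineage": None,
    "TE": "Prelineage",
    "ICM": "Prelineage",
    "Epiblast": "ICM",
    "Hypoblast": "ICM",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic embryo-like series.

    Defaults: 5 lineages on a two-level branching tree, 3 batches of 40 cells
    per lineage, a genome-scale 20,000 genes with 50 markers per lineage at
    log2FC 2, gene-wise batch factors with log-sd 0.15, library sizes ~
    LogNormal(log 5e4, 0.3), NB dispersion 0.1, and 5% depth retention for
    droplet-style data.
    """

    lineage_tree: Dict[str, Optional[str]] = field(default_factory=lambda: dict(DEFAULT_TREE))
    n_batches: int = 3
    n_cells_per_lineage_per_batch: int = 40
    n_genes: int = 20000
    n_markers_per_lineage: int = 50
    marker_log2fc: float = 2.0
    batch_effect_sd: float = 0.15
    libsize_log_mean: float = float(np.log(5e4))
    libsize_log_sd: float = 0.3
    nb_dispersion: float = 0.1
    sparse_depth_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self._check_tree()
        if self.n_batches < 1 or self.n_cells_per_lineage_per_batch < 1 or self.n_genes < 1:
            raise ValidationError("SimConfig: all counts must be >= 1")
        if not 0 < self.sparse_depth_fraction <= 1:
            raise ValidationError("SimConfig: sparse_depth_fraction must lie in (0, 1]")
        if self.n_markers_per_lineage * len(self.lineage_tree) > self.n_genes:
            raise ValidationError("SimConfig: not enough genes for disjoint marker sets")

    def _check_tree(self) -> None:
        roots = [l for l, p in self.lineage_tree.items() if p is None]
        if len(roots) != 1:
            raise ValidationError("SimConfig: lineage_tree must have exactly one root")
        for lin in self.lineage_tree:
            seen, cur = set(), lin
            while cur is not None:
                if cur in seen:
                    raise ValidationError("SimConfig: lineage_tree contains a cycle")
                seen.add(cur)
                parent = self.lineage_tree.get(cur, "__missing__")
                if parent == "__missing__":
                    raise ValidationError(f"SimConfig: parent of {cur!r} not in tree")
                cur = parent

    @property
    def lineages(self) -> List[str]:
        return list(self.lineage_tree)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    cell_meta: pd.DataFrame  # index cell id; lineage, batch, library_size
    marker_genes: Dict[str, List[str]]  # lineage -> its marker gene ids
    batch_factors: pd.DataFrame  # genes x batches multiplicative factors
    programs: pd.DataFrame  # genes x lineages relative expression


# ---------------------------------------------------------------------------


def _streams(cfg: SimConfig) -> Dict[str, np.random.Generator]:
    """Named child RNG streams so programs are shared across generator calls."""
    root = np.random.SeedSequence(cfg.seed)
    names = ["programs", "batch", "reference", "query", "unrelated"]
    children = root.spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _topological(tree: Dict[str, Optional[str]]) -> List[str]:
    order: List[str] = []
    remaining = dict(tree)
    while remaining:
        ready = [l for l, p in remaining.items() if p is None or p in order]
        if not ready:
            raise ValidationError("SimConfig: degenerate lineage tree")
        for l in sorted(ready):
            order.append(l)
            del remaining[l]
    return order


def _gene_programs(cfg: SimConfig, rng: np.random.Generator) -> Tuple[pd.DataFrame, Dict[str, List[str]]]:
    """Relative expression per lineage: parent program plus marker up-shifts."""
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    base = rng.gamma(shape=0.6, scale=2.0, size=cfg.n_genes) + 0.05
    order = _topological(cfg.lineage_tree)
    marker_pool = rng.permutation(cfg.n_genes)
    markers: Dict[str, List[str]] = {}
    programs: Dict[str, np.ndarray] = {}
    for i, lin in enumerate(order):
        idx = marker_pool[i * cfg.n_markers_per_lineage : (i + 1) * cfg.n_markers_per_lineage]
        markers[lin] = [genes[j] for j in idx]
        parent = cfg.lineage_tree[lin]
        prog = (base if parent is None else programs[parent]).copy()
        prog[idx] = prog[idx] * (2.0 ** cfg.marker_log2fc)
        programs[lin] = prog
    prog_df = pd.DataFrame({lin: programs[lin] for lin in order}, index=genes)
    return prog_df, markers


def _batch_factors(cfg: SimConfig, rng: np.random.Generator, genes: List[str]) -> pd.DataFrame:
    cols = {}
    for b in range(cfg.n_batches):
        cols[f"batch{b}"] = np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=len(genes)))
    return pd.DataFrame(cols, index=genes)


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson sampling; dispersion 0 degenerates to Poisson."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _draw_cells(
    cfg: SimConfig,
    programs: pd.DataFrame,
    factors: np.ndarray,
    lineages: List[str],
    n_per_lineage: int,
    rng: np.random.Generator,
    prefix: str,
    batch_name: str,
    time_of: Optional[Dict[str, float]] = None,
) -> Tuple[np.ndarray, pd.DataFrame]:
    n_cells = n_per_lineage * len(lineages)
    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    meta_rows = []
    col = 0
    for lin in lineages:
        rate = programs[lin].to_numpy() * factors
        p = rate / rate.sum()
        for _ in range(n_per_lineage):
            lib = float(np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd)))
            counts[:, col] = _nb_counts(lib * p, cfg.nb_dispersion, rng)
            meta_rows.append(
                dict(
                    cell_id=f"{prefix}_{lin}_{col:04d}",
                    batch=batch_name,
                    time_point=None if time_of is None else time_of.get(lin),
                    label=lin,
                    library_size=lib,
                )
            )
            col += 1
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    return counts, meta


def _depth_of_lineage(tree: Dict[str, Optional[str]]) -> Dict[str, float]:
    depth = {}
    for lin in tree:
        d, cur = 0, tree[lin]
        while cur is not None:
            d += 1
            cur = tree[cur]
        depth[lin] = float(d)
    return depth


# ---------------------------------------------------------------------------


def simulate_reference_series(cfg: SimConfig) -> Tuple[List[CountMatrix], SimTruth]:
    """Generate one CountMatrix per batch sharing lineage programs.

    Batches differ by gene-wise multiplicative factors (the batch effect) and
    by their random cells; lineage composition is identical across batches so
    mutual-nearest-neighbor links exist at every merge step.
    """
    streams = _streams(cfg)
    programs, markers = _gene_programs(cfg, streams["programs"])
    genes = list(programs.index)
    bf = _batch_factors(cfg, streams["batch"], genes)
    time_of = _depth_of_lineage(cfg.lineage_tree)
    rng = streams["reference"]
    batches, truth_meta = [], []
    for b in range(cfg.n_batches):
        name = f"batch{b}"
        counts, meta = _draw_cells(
            cfg, programs, bf[name].to_numpy(), cfg.lineages,
            cfg.n_cells_per_lineage_per_batch, rng, name, name, time_of,
        )
        batches.append(
            CountMatrix(genes, list(meta.index), counts, meta[["batch", "time_point", "label"]])
        )
        truth_meta.append(meta)
    truth = SimTruth(
        cell_meta=pd.concat(truth_meta).rename(columns={"label": "lineage"}),
        marker_genes=markers,
        batch_factors=bf,
        programs=programs,
    )
    return batches, truth


def simulate_query(
    cfg: SimConfig,
    mode: str = "deep",
    new_batch_effect: bool = False,
    n_cells_per_lineage: Optional[int] = None,
    lineages: Optional[List[str]] = None,
    extra_lineages: Optional[Dict[str, str]] = None,
) -> Tuple[CountMatrix, SimTruth]:
    """Draw a query batch from the same gene programs as the reference series.

    ``mode='sparse'`` binomially downsamples each cell to
    ``cfg.sparse_depth_fraction`` of its deep depth. ``extra_lineages`` maps new
    lineage names to a parent in the tree, planting populations absent from the
    reference. ``new_batch_effect`` draws an unseen gene-wise batch factor.
    """
    if mode not in ("deep", "sparse"):
        raise ValidationError("simulate_query: mode must be 'deep' or 'sparse'")
    streams = _streams(cfg)
    programs, markers = _gene_programs(cfg, streams["programs"])
    genes = list(programs.index)
    rng = streams["query"]
    lineages = list(lineages if lineages is not None else cfg.lineages)
    if extra_lineages:
        for new, parent in extra_lineages.items():
            if parent not in programs.columns:
                raise ValidationError(f"simulate_query: unknown parent lineage {parent!r}")
            prog = programs[parent].to_numpy().copy()
            idx = rng.choice(cfg.n_genes, size=cfg.n_markers_per_lineage, replace=False)
            prog[idx] = prog[idx] * (2.0 ** cfg.marker_log2fc)
            programs[new] = prog
            markers[new] = [genes[j] for j in idx]
            lineages.append(new)
    factors = (
        np.exp(rng.normal(0.0, cfg.batch_effect_sd, size=cfg.n_genes))
        if new_batch_effect
        else np.ones(cfg.n_genes)
    )
    n_per = n_cells_per_lineage or cfg.n_cells_per_lineage_per_batch
    counts, meta = _draw_cells(
        cfg, programs, factors, lineages, n_per, rng, "query", "query",
        _depth_of_lineage(cfg.lineage_tree),
    )
    if mode == "sparse":
        counts = rng.binomial(counts, cfg.sparse_depth_fraction)
    cm = CountMatrix(genes, list(meta.index), counts, meta[["batch", "time_point", "label"]])
    truth = SimTruth(
        cell_meta=meta.rename(columns={"label": "lineage"}),
        marker_genes=markers,
        batch_factors=pd.DataFrame({"query": factors}, index=genes),
        programs=programs,
    )
    return cm, truth


def simulate_unrelated(cfg: SimConfig, n_cells: int = 200) -> CountMatrix:
    """A dataset from fresh gene programs, unrelated to the reference tree.

    Gene identities are permuted and lineage programs redrawn, so query cells
    should fail the reference correlation gate and be flagged nonrelated.
    """
    streams = _streams(cfg)
    programs, _ = _gene_programs(cfg, streams["programs"])
    genes = list(programs.index)
    rng = streams["unrelated"]
    n_tissues = 4
    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    meta_rows = []
    fresh = []
    for t in range(n_tissues):
        prog = rng.gamma(shape=0.6, scale=2.0, size=cfg.n_genes) + 0.05
        idx = rng.choice(cfg.n_genes, size=cfg.n_markers_per_lineage, replace=False)
        prog[idx] *= 2.0 ** (cfg.marker_log2fc + 1)
        fresh.append(prog[rng.permutation(cfg.n_genes)])
    for c in range(n_cells):
        t = c % n_tissues
        p = fresh[t] / fresh[t].sum()
        lib = float(np.exp(rng.normal(cfg.libsize_log_mean, cfg.libsize_log_sd)))
        counts[:, c] = _nb_counts(lib * p, cfg.nb_dispersion, rng)
        meta_rows.append(dict(cell_id=f"unrel_{c:04d}", batch="unrelated",
                              time_point=None, label=f"tissue{t}"))
    meta = pd.DataFrame(meta_rows).set_index("cell_id")
    return CountMatrix(genes, list(meta.index), counts, meta)
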