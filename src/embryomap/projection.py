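"""Project query cells into the frozen reference frame.

The query replays the recorded reference normalization (rescale to the
reference's lowest-coverage target), cosine normalization on the reference's
integration features, grand-center removal, rotation into the SVD subspace and
the orthogonalization of every recorded merge step — then receives its own MNN
correction from filtered, subsampled pairs, and is finally transformed through
the reference's fitted embedding models. The reference is never modified.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import Config
from .containers import CountMatrix, PairSet, ProjectionResult, ReferenceModel, UnitMatrix
from .errors import EmbryoMapError, StageError, ValidationError
from .preprocess import compute_size_factors, cosine_normalize, rescale_query
from .reference import compute_correction_field, find_mnn_pairs, orthogonalize_along_vector


# ---------------------------------------------------------------------------
# Spearman helpers
# ---------------------------------------------------------------------------

def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Column-wise mid-ranks, centered and scaled to unit norm, so Spearman
    correlations become plain dot products."""
    ranks = np.apply_along_axis(rankdata, 0, values)
    ranks -= ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(ranks, axis=0)
    norms[norms == 0] = 1.0
    return ranks / norms


def spearman_matrix(query_units: np.ndarray, ref_units: np.ndarray) -> np.ndarray:
    """Spearman correlation of every query column against every reference column."""
    rq = _rank_normalize(query_units)
    rr = _rank_normalize(ref_units)
    return rq.T @ rr


# ---------------------------------------------------------------------------
# Stage 1: replay normalization and subspace placement
# ---------------------------------------------------------------------------

def embed_query(query: CountMatrix, ref: ReferenceModel) -> Tuple[np.ndarray, UnitMatrix, int]:
    """Place query cells in the reference subspace without touching the reference.

    Returns (raw coords before MNN correction, the query unit matrix on the
    reference feature selection, number of imputed selection genes).
    """
    cfg: Config = ref.config
    sel = ref.gene_selection.genes
    present = set(query.genes)
    coverage = sum(1 for g in sel if g in present) / len(sel)
    if coverage < cfg.min_query_gene_coverage:
        raise ValidationError(
            f"embed_query: query covers only {coverage:.1%} of the reference "
            f"integration features (floor {cfg.min_query_gene_coverage:.0%})"
        )
    n_imputed = sum(1 for g in sel if g not in present)
    sf = compute_size_factors(query, method=ref.rescale.get("method", cfg.size_factor_method))
    lm = rescale_query(query, sf, ref.rescale["target_coverage"])
    units = cosine_normalize(lm, sel, impute_missing=True)
    Xc = units.values - ref.grand_centers[:, None]
    coords = Xc.T @ ref.rotation
    for rec in ref.merge_records:
        if rec.degenerate:
            continue
        coords = orthogonalize_along_vector(coords, rec.batch_vector, rec.target_mean)
    return coords, units, n_imputed


# ---------------------------------------------------------------------------
# Stage 2: subsampled MNN pairing + filtering
# ---------------------------------------------------------------------------

def subsampled_mnn_pairs(
    raw_coords: np.ndarray,
    query_units: UnitMatrix,
    ref: ReferenceModel,
    cfg: Optional[Config] = None,
) -> PairSet:
    """Union of MNN pairs over seeded subsample repeats, per reference dataset.

    The query is shuffled and split into chunks of ``subsample_size`` for each
    of ``n_repeats`` repeats; each chunk is matched against every reference
    dataset separately with K=``k_mnn_query`` (K=``k_mnn_small`` when the whole
    query has fewer than 50 cells). Each surviving (query, ref) pair carries
    the Spearman correlation of the two cells over the integration features.
    """
    cfg = cfg or ref.config
    n = raw_coords.shape[0]
    K = cfg.k_mnn_query if n >= 50 else cfg.k_mnn_small
    rng = np.random.default_rng(cfg.rng_seed)
    ref_space, query_space = _search_spaces(raw_coords, query_units, ref, cfg)
    datasets = np.asarray(ref.dataset_of_cell)
    lineage_arr = np.asarray(ref.lineages)
    rows: List[dict] = []
    for r in range(cfg.n_repeats):
        perm = rng.permutation(n)
        chunks = [perm[i: i + cfg.subsample_size] for i in range(0, n, cfg.subsample_size)]
        for ci, chunk in enumerate(chunks):
            qcoords = query_space[chunk]
            for ds in dict.fromkeys(ref.dataset_of_cell):  # preserve merge order
                ds_idx = np.flatnonzero(datasets == ds)
                ia, ib = find_mnn_pairs(ref_space[ds_idx], qcoords, K, K)
                for a, b in zip(ia, ib):
                    rows.append(
                        dict(query=int(chunk[b]), ref=int(ds_idx[a]), ref_dataset=ds,
                             ref_lineage=lineage_arr[ds_idx[a]], repeat=r, chunk=ci, k=K)
                    )
    if not rows:
        return PairSet.empty()
    df = pd.DataFrame(rows).drop_duplicates(subset=["query", "ref"], keep="first")
    df = df.sort_values(["query", "ref"], kind="stable").reset_index(drop=True)
    # Spearman over integration-feature unit values, computed once per pair
    rq = _rank_normalize(query_units.values)
    rr = _rank_normalize(ref.ref_unit_matrix)
    q_idx = df["query"].to_numpy(int)
    r_idx = df["ref"].to_numpy(int)
    df["corr"] = np.einsum("ij,ij->j", rq[:, q_idx], rr[:, r_idx])
    return PairSet(df[list(PairSet.COLUMNS)])


def _search_spaces(raw_coords, query_units, ref, cfg):
    """Coordinates MNN search runs in: orthogonalized subspace (default) or
    cosine unit values directly."""
    if cfg.mnn_space == "cosine":
        return ref.ref_unit_matrix.T.copy(), query_units.values.T.copy()
    ref_coords = ref.corrected_coords
    return ref_coords, raw_coords


def filter_mnn_pairs(pairs: PairSet, ref: ReferenceModel, cfg: Optional[Config] = None) -> Tuple[PairSet, dict]:
    """Drop unreliable pairs; returns the filtered set and per-filter counts.

    1. any query cell linked to BOTH lineages of a configured mutually
       exclusive pair (default TE/Amnion) loses all its pairs;
    2. pairs with Spearman correlation below ``corr_threshold`` are dropped;
    3. a reference lineage whose top ``top_n_corr`` pair correlations are all
       below ``corr_threshold`` loses every remaining pair.
    """
    cfg = cfg or ref.config
    df = pairs.pairs.copy()
    report = {"input": len(df)}
    # (1) ambiguous-lineage gate
    drop_cells: set = set()
    for pair in cfg.ambiguous_lineage_pairs:
        a, b = pair
        by_cell = df.groupby("query")["ref_lineage"].agg(set)
        drop_cells |= set(by_cell.index[by_cell.apply(lambda s: a in s and b in s)])
    df = df[~df["query"].isin(drop_cells)]
    report["ambiguous_pair_cells"] = len(drop_cells)
    # (2) low-correlation pairs
    before = len(df)
    df = df[df["corr"] >= cfg.corr_threshold]
    report["low_corr_pairs"] = before - len(df)
    # (3) lineages whose best pairs are all weak (evaluated on pre-threshold pairs
    # of surviving cells so the rule matches its statement independently of (2))
    pre = pairs.pairs[~pairs.pairs["query"].isin(drop_cells)]
    weak_lineages = []
    for lin, sub in pre.groupby("ref_lineage"):
        top = sub["corr"].nlargest(cfg.top_n_corr)
        if (top < cfg.corr_threshold).all():
            weak_lineages.append(lin)
    df = df[~df["ref_lineage"].isin(weak_lineages)]
    report["weak_lineages"] = weak_lineages
    report["output"] = len(df)
    if len(df) == 0:
        warnings.warn("filter_mnn_pairs removed every pair; downstream will abstain")
    return PairSet(df.reset_index(drop=True)), report


# ---------------------------------------------------------------------------
# Stage 3: correction + gating
# ---------------------------------------------------------------------------

def correct_query(
    raw_coords: np.ndarray,
    pairs: PairSet,
    ref: ReferenceModel,
    cfg: Optional[Config] = None,
) -> Tuple[np.ndarray, bool]:
    """Kernel-smoothed, variance-adjusted MNN correction of the query coords.

    With an empty pair set the correction is the identity and the caller is
    told so (cells will carry the no_mnn_support flag). Reference coordinates
    are never modified.
    """
    cfg = cfg or ref.config
    if len(pairs) == 0:
        return raw_coords.copy(), True
    ia = pairs.pairs["ref"].to_numpy(int)
    ib = pairs.pairs["query"].to_numpy(int)
    corr, _ = compute_correction_field(
        (ia, ib), ref.corrected_coords, raw_coords,
        ndist=cfg.ndist, adjust_variance=True, k_bandwidth=cfg.k_mnn_ref,
    )
    return raw_coords + corr, False


def flag_nonrelated(
    query_units: UnitMatrix, ref: ReferenceModel, cfg: Optional[Config] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean Spearman over each query cell's ``top_n_corr`` most correlated
    reference cells; cells strictly below ``corr_threshold`` are nonrelated."""
    cfg = cfg or ref.config
    C = spearman_matrix(query_units.values, ref.ref_unit_matrix)
    k = min(cfg.top_n_corr, C.shape[1])
    top = np.sort(C, axis=1)[:, -k:]
    stats = top.mean(axis=1)
    return stats < cfg.corr_threshold, stats


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def project_query(
    query: CountMatrix,
    ref: ReferenceModel,
    cfg: Optional[Config] = None,
    aggregate: Optional[bool] = None,
) -> ProjectionResult:
    """Full projection pipeline; deterministic given ``cfg.rng_seed``.

    ``aggregate`` forces (True) or suppresses (False) milo-style neighborhood
    aggregation; by default it triggers when the median number of expressed
    genes per cell falls below ``cfg.sparse_gene_floor``.
    """
    from .annotate import make_neighborhoods

    cfg = cfg or ref.config
    nhoods = None
    work = query
    if aggregate is None:
        median_genes = float(np.median((query.counts > 0).sum(axis=0)))
        aggregate = median_genes < cfg.sparse_gene_floor and query.n_cells > cfg.nhood_k + 1
    if aggregate:
        nhoods = make_neighborhoods(work, cfg.nhood_prop, cfg.nhood_k, cfg.rng_seed)
        work = nhoods.aggregated_counts

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except EmbryoMapError as e:
            raise StageError(f"{name}: {e}") from e

    raw, units, n_imputed = stage("embed_query", embed_query, work, ref)
    unfiltered = stage("subsampled_mnn_pairs", subsampled_mnn_pairs, raw, units, ref, cfg)
    filtered, report = stage("filter_mnn_pairs", filter_mnn_pairs, unfiltered, ref, cfg)
    corrected, no_support = stage("correct_query", correct_query, raw, filtered, ref, cfg)
    embed2 = ref.embed2.transform(corrected)
    latent = ref.embed_latent.transform(corrected)
    mask, stats = stage("flag_nonrelated", flag_nonrelated, units, ref, cfg)
    return ProjectionResult(
        cells=list(work.cells),
        raw_coords=raw,
        corrected_coords=corrected,
        embed2_coords=embed2,
        latent_coords=latent,
        pair_set=filtered,
        pair_set_unfiltered=unfiltered,
        nonrelated_mask=mask,
        corr_stats=stats,
        no_mnn_support=no_support,
        imputed_gene_count=n_imputed,
        filter_report=report,
        nhoods=nhoods,
    )
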