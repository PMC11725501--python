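"""Reference atlas construction: grand-centered SVD subspace, sequential MNN
merging with kernel-smoothed and variance-adjusted corrections followed by
orthogonalization along the recorded batch vector, embedding-model fitting and
Leiden clustering.

Every quantity a query projection must replay — grand centers, rotation, merge
records (batch vector, target mean projection), rescale record and the fitted
embedding models — is recorded in the resulting ReferenceModel.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .config import Config
from .containers import (
    ClassifierSet,
    CountMatrix,
    GeneSelection,
    MergeRecord,
    PCASpace,
    ReferenceModel,
    UnitMatrix,
)
from .errors import EmbryoMapError, StageError, ValidationError
from .preprocess import (
    compute_size_factors,
    cosine_normalize,
    multibatch_rescale,
    qc_filter,
    select_integration_features,
)


# ---------------------------------------------------------------------------
# Subspace
# ---------------------------------------------------------------------------

def multibatch_pca(units: Sequence[UnitMatrix], d: int) -> PCASpace:
    """Plain SVD of the grand-centered concatenation of all batches.

    ``grand_centers`` is the unweighted per-gene mean over every cell of every
    batch; the rotation holds the top-``d`` left singular vectors with a
    deterministic sign convention (largest-magnitude loading positive).
    """
    genes = list(units[0].genes)
    for u in units[1:]:
        if list(u.genes) != genes:
            raise ValidationError("multibatch_pca: batches must share the gene axis")
    X = np.concatenate([u.values for u in units], axis=1)  # genes x cells
    cells = [c for u in units for c in u.cells]
    if X.shape[1] <= d:
        raise ValidationError("multibatch_pca: need more cells than subspace dimensions")
    centers = X.mean(axis=1)
    Xc = X - centers[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if d > rank:
        warnings.warn(f"requested {d} components but rank is {rank}; reducing")
        d = rank
    rotation = U[:, :d].copy()
    # sign convention: per component, the largest-magnitude gene loading is positive
    for j in range(d):
        i = int(np.argmax(np.abs(rotation[:, j])))
        if rotation[i, j] < 0:
            rotation[:, j] = -rotation[:, j]
    coords = Xc.T @ rotation
    return PCASpace(genes, cells, centers, rotation, coords)


# ---------------------------------------------------------------------------
# MNN machinery
# ---------------------------------------------------------------------------

def find_mnn_pairs(
    A: np.ndarray, B: np.ndarray, k_a: int, k_b: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Mutual nearest neighbors between point sets A and B (Euclidean).

    Pair (a, b) is returned iff b is among the k_b nearest neighbors of a in B
    and a is among the k_a nearest neighbors of b in A; ties are broken by
    (distance, index). Returns index arrays (into A, into B) sorted
    lexicographically. k values are capped at the opposing set size.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    k_b = min(k_b, B.shape[0])
    k_a = min(k_a, A.shape[0])
    D = cdist(A, B)
    # neighbor lists with deterministic (distance, index) tie-break
    nbrs_of_a = np.argsort(D, axis=1, kind="stable")[:, :k_b]
    nbrs_of_b = np.argsort(D.T, axis=1, kind="stable")[:, :k_a]
    in_knn_of_b = np.zeros(D.shape, dtype=bool)  # [a, b]: a in kNN(b)
    for b in range(B.shape[0]):
        in_knn_of_b[nbrs_of_b[b], b] = True
    ia, ib = [], []
    for a in range(A.shape[0]):
        for b in nbrs_of_a[a]:
            if in_knn_of_b[a, b]:
                ia.append(a)
                ib.append(int(b))
    ia = np.asarray(ia, dtype=int)
    ib = np.asarray(ib, dtype=int)
    order = np.lexsort((ib, ia))
    return ia[order], ib[order]


def _kth_neighbor_distance(X: np.ndarray, points: np.ndarray, k: int) -> np.ndarray:
    """Distance of each of ``points`` to its k-th nearest neighbor within X."""
    D = cdist(points, X)
    k = min(k, X.shape[0] - 1)
    if k < 1:
        return np.zeros(points.shape[0])
    part = np.sort(D, axis=1)
    return part[:, k]


def compute_correction_field(
    pairs: Tuple[np.ndarray, np.ndarray],
    A_coords: np.ndarray,
    B_coords: np.ndarray,
    ndist: float = 3.0,
    adjust_variance: bool = True,
    k_bandwidth: int = 20,
) -> Tuple[np.ndarray, dict]:
    """Per-B-cell correction vectors moving B toward A.

    Raw pair vectors ``A[a] - B[b]`` are smoothed over B with a Gaussian kernel
    whose bandwidth is ``ndist`` times the median distance of paired B cells to
    their ``k_bandwidth``-th nearest B neighbor. With ``adjust_variance`` each
    cell's correction is additionally scaled (factor >= 1) along the overall
    batch-vector direction so its projected quantile within B matches the
    corresponding quantile in A; orthogonal components are untouched.
    """
    ia, ib = pairs
    if len(ia) == 0:
        raise ValidationError("compute_correction_field: need at least one pair")
    V = A_coords[ia] - B_coords[ib]  # raw pair vectors
    anchors = B_coords[ib]
    kth = _kth_neighbor_distance(B_coords, anchors, k_bandwidth)
    sigma = float(ndist * np.median(kth))
    info: Dict[str, float] = {"bandwidth": sigma}
    if sigma <= 0:
        warnings.warn("degenerate geometry: zero kernel bandwidth; using unweighted mean")
        corr = np.tile(V.mean(axis=0), (B_coords.shape[0], 1))
    else:
        D2 = cdist(B_coords, anchors, "sqeuclidean")
        W = np.exp(-D2 / sigma**2)
        Wsum = W.sum(axis=1, keepdims=True)
        Wsum[Wsum == 0] = 1.0
        corr = (W @ V) / Wsum

    if adjust_variance:
        mean_v = V.mean(axis=0)
        nv = np.linalg.norm(mean_v)
        if nv > 0:
            u = mean_v / nv
            proj_b = B_coords @ u
            proj_a = A_coords @ u
            # empirical quantile of each B cell, mapped to the A distribution
            q = np.searchsorted(np.sort(proj_b), proj_b, side="right") / len(proj_b)
            targets = np.quantile(proj_a, np.clip(q, 0.0, 1.0))
            c_u = corr @ u
            needed = targets - proj_b
            scale = np.ones(len(c_u))
            nonzero = np.abs(c_u) > 1e-12
            same_sign = nonzero & (np.sign(needed) == np.sign(c_u))
            scale[same_sign] = np.maximum(1.0, needed[same_sign] / c_u[same_sign])
            corr = corr + ((scale - 1.0) * c_u)[:, None] * u[None, :]
            info["mean_scale"] = float(scale.mean())
    return corr, info


def orthogonalize_along_vector(
    coords: np.ndarray, v: np.ndarray, target_mean: float = 0.0
) -> np.ndarray:
    """Collapse all variation along unit vector v onto ``target_mean``."""
    v = np.asarray(v, dtype=float)
    if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-8):
        raise ValidationError("orthogonalize_along_vector: v must be unit norm")
    proj = coords @ v
    return coords - np.outer(proj - target_mean, v)


def merge_batches(
    spaces: Dict[str, np.ndarray],
    order: Sequence[str],
    cfg: Config,
) -> Tuple[np.ndarray, List[str], List[MergeRecord]]:
    """Sequential MNN merge in the shared subspace, in developmental order.

    At each step mutual pairs link the merged-so-far reference with the
    incoming batch; the incoming cells receive kernel-smoothed (and variance
    adjusted) corrections, then BOTH sides are orthogonalized along the
    recorded unit mean-correction direction to the pooled mean projection.
    Returns (corrected coords, batch id per cell, merge records).
    """
    if sorted(order) != sorted(spaces):
        raise ValidationError("merge_batches: order must cover all batches exactly once")
    order = list(order)
    merged = spaces[order[0]].copy()
    batch_of = [order[0]] * merged.shape[0]
    records: List[MergeRecord] = []
    for step, bid in enumerate(order[1:], start=1):
        incoming = spaces[bid]
        ia, ib = find_mnn_pairs(merged, incoming, cfg.k_mnn_ref, cfg.k_mnn_ref)
        if len(ia) == 0:
            raise EmbryoMapError(
                f"merge step {step} ({bid}): no mutual nearest neighbors found; "
                "the shared-population assumption is violated"
            )
        corr, info = compute_correction_field(
            (ia, ib), merged, incoming, ndist=cfg.ndist,
            adjust_variance=True, k_bandwidth=cfg.k_mnn_ref,
        )
        V = merged[ia] - incoming[ib]
        mean_v = V.mean(axis=0)
        nv = float(np.linalg.norm(mean_v))
        pair_scale = float(np.linalg.norm(V, axis=1).mean())
        # no detectable batch direction (e.g. coincident batches): the mean pair
        # vector is numerically zero, so there is nothing to orthogonalize away
        degenerate = nv <= 1e-10 * (pair_scale + 1.0)
        if degenerate:
            corrected_in = incoming.copy()
            u = np.zeros(merged.shape[1])
            u[0] = 1.0
            target = float(np.concatenate([merged, corrected_in])[:, 0].mean())
            mean_existing = float(merged[:, 0].mean())
            mean_incoming = float(corrected_in[:, 0].mean())
        else:
            corrected_in = incoming + corr
            u = mean_v / nv
            pooled = np.concatenate([merged, corrected_in], axis=0)
            target = float((pooled @ u).mean())
            mean_existing = float((merged @ u).mean())
            mean_incoming = float((corrected_in @ u).mean())
            merged = orthogonalize_along_vector(merged, u, target)
            corrected_in = orthogonalize_along_vector(corrected_in, u, target)
        records.append(
            MergeRecord(
                step=step,
                batch_id=bid,
                pairs_existing=ia,
                pairs_incoming=ib,
                batch_vector=u,
                target_mean=target,
                mean_proj_existing=mean_existing,
                mean_proj_incoming=mean_incoming,
                kernel_bandwidth=float(info["bandwidth"]),
                variance_adjusted=not degenerate,
                degenerate=degenerate,
            )
        )
        merged = np.concatenate([merged, corrected_in], axis=0)
        batch_of += [bid] * incoming.shape[0]
    return merged, batch_of, records


# ---------------------------------------------------------------------------
# Embedding + clustering
# ---------------------------------------------------------------------------

def fit_embedding_models(corrected_coords: np.ndarray, dims: Sequence[int], cfg: Config) -> dict:
    """Fit one UMAP model per requested dimension with a fixed seed.

    The fitted models support ``transform`` so query points can be mapped into
    the frozen reference embedding without perturbing it.
    """
    import umap

    if not np.all(np.isfinite(corrected_coords)):
        raise ValidationError("fit_embedding_models: non-finite coordinates")
    n_pcs = corrected_coords.shape[1]
    bad = [d for d in dims if d > n_pcs]
    if bad:
        raise ValidationError(f"fit_embedding_models: dims {bad} exceed subspace dimension {n_pcs}")
    models = {}
    for d in dims:
        kwargs = dict(
            n_neighbors=min(cfg.umap_neighbors, corrected_coords.shape[0] - 1),
            min_dist=cfg.umap_min_dist,
            n_components=d,
            random_state=cfg.rng_seed,
            transform_seed=cfg.rng_seed + 1,
            n_jobs=1,
        )
        try:
            model = umap.UMAP(**kwargs).fit(corrected_coords)
        except Exception:
            model = umap.UMAP(init="random", **kwargs).fit(corrected_coords)
        models[d] = model
    return models


def _snn_graph(coords: np.ndarray, k: int):
    """Shared-nearest-neighbor graph: kNN edges weighted by neighbor-set Jaccard."""
    import igraph as ig

    n = coords.shape[0]
    k = min(k, n - 1)
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)
    nbrs = np.argsort(D, axis=1, kind="stable")[:, :k]
    sets = [set(row.tolist()) | {i} for i, row in enumerate(nbrs)]
    edges, weights = [], []
    for i in range(n):
        for j in nbrs[i]:
            j = int(j)
            if j > i or i not in sets[j]:
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                w = inter / union
                if w > 0:
                    edges.append((min(i, j), max(i, j)))
                    weights.append(w)
    uniq = {}
    for e, w in zip(edges, weights):
        uniq[e] = w
    g = ig.Graph(n=n, edges=list(uniq.keys()))
    g.es["weight"] = list(uniq.values())
    return g


def leiden_cluster(corrected_coords: np.ndarray, cfg: Config) -> np.ndarray:
    """Leiden community detection on the SNN graph of the corrected subspace."""
    import leidenalg

    if corrected_coords.shape[0] < 2:
        raise ValidationError("leiden_cluster: need at least two cells")
    g = _snn_graph(corrected_coords, cfg.umap_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=cfg.leiden_resolution,
        seed=cfg.rng_seed,
        n_iterations=5,
    )
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def build_reference(
    batches: Sequence[CountMatrix],
    order: Sequence[str],
    cfg: Config,
    stage1_group: Optional[Sequence[str]] = None,
    lineage_labels: Optional[pd.Series] = None,
    mito_genes=lambda g: g.upper().startswith("MT-"),
) -> ReferenceModel:
    """Run the full construction pipeline and freeze the result.

    Stages: QC -> size factors -> cross-batch rescale -> integration features
    -> cosine normalization -> grand-centered SVD -> sequential MNN merge ->
    embedding models (2-D and latent) -> Leiden clustering -> per-lineage
    classifiers. ``lineage_labels`` defaults to the ``label`` metadata column
    and must cover every post-QC cell.
    """
    from .annotate import train_lineage_classifiers

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except EmbryoMapError as e:
            raise StageError(f"{name}: {e}") from e

    filtered = [stage("qc_filter", qc_filter, b, cfg.qc, mito_genes) for b in batches]
    sfs = [stage("size_factors", compute_size_factors, b, cfg.size_factor_method) for b in filtered]
    logs, rescale_record = stage("multibatch_rescale", multibatch_rescale, list(zip(filtered, sfs)))
    rescale_record = dict(rescale_record, method=cfg.size_factor_method)
    batch_ids = [lm.rescale_record["batch"] for lm in logs]
    if stage1_group is None:
        stage1_group = batch_ids
    selection = stage(
        "select_integration_features", select_integration_features,
        logs, stage1_group, cfg.n_hvg_total, cfg.n_hvg_stage1,
    )
    units = [stage("cosine_normalize", cosine_normalize, lm, selection) for lm in logs]
    space = stage("multibatch_pca", multibatch_pca, units, cfg.n_pcs)

    # per-batch blocks of the shared subspace, keyed by batch id
    sizes = [u.values.shape[1] for u in units]
    offsets = np.cumsum([0] + sizes)
    spaces = {bid: space.coords[offsets[i]: offsets[i + 1]] for i, bid in enumerate(batch_ids)}
    corrected, batch_of, records = stage("merge_batches", merge_batches, spaces, order, cfg)

    # cells follow merge order
    cells_by_batch = {bid: list(units[i].cells) for i, bid in enumerate(batch_ids)}
    cells = [c for bid in order for c in cells_by_batch[bid]]

    meta = pd.concat([b.cell_meta for b in filtered])
    if lineage_labels is None:
        lineage_labels = meta["label"]
    unlabeled = [c for c in cells if c not in lineage_labels.index or pd.isna(lineage_labels.loc[c])]
    if unlabeled:
        raise ValidationError(f"build_reference: unlabeled cells: {unlabeled[:5]} "
                              f"({len(unlabeled)} total)")
    lineages = [str(lineage_labels.loc[c]) for c in cells]

    dims = sorted({2, cfg.latent_dim})
    models = stage("fit_embedding_models", fit_embedding_models, corrected, dims, cfg)
    clusters = stage("leiden_cluster", leiden_cluster, corrected, cfg)
    latent_coords = models[cfg.latent_dim].embedding_
    classifiers = stage(
        "train_lineage_classifiers", train_lineage_classifiers,
        latent_coords, lineages, cfg,
    )

    # reference unit matrix in merge order, for query correlation gating
    unit_by_batch = {bid: units[i].values for i, bid in enumerate(batch_ids)}
    ref_units = np.concatenate([unit_by_batch[bid] for bid in order], axis=1)

    model = ReferenceModel(
        config=cfg,
        gene_selection=selection,
        rescale=rescale_record,
        grand_centers=space.grand_centers,
        rotation=space.rotation,
        merge_records=records,
        corrected_coords=corrected,
        clusters=clusters,
        lineages=lineages,
        embed2=models[2],
        embed_latent=models[cfg.latent_dim],
        classifiers=classifiers,
        ref_unit_matrix=ref_units,
        cells=cells,
        dataset_of_cell=batch_of,
    )
    model.validate()
    return model
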