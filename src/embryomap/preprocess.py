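"""QC filtering, size-factor normalization, cross-batch rescaling, integration
feature selection and cosine normalization.

Normalization follows the deconvolution idea of pooling cells and solving for
per-cell factors by least squares, after which every batch is rescaled so its
expected normalized coverage matches the lowest-coverage batch; the rescale
record is kept so queries can be placed on the identical scale later.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import QCThresholds
from .containers import CountMatrix, GeneSelection, LogMatrix, SizeFactors, UnitMatrix
from .errors import EmptyResultError, ValidationError

POOL_SIZES = (21, 41, 61, 81, 101)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_filter(
    m: CountMatrix,
    t: QCThresholds,
    mito_genes: Callable[[str], bool] = lambda g: g.upper().startswith("MT-"),
) -> CountMatrix:
    """Drop low-quality cells, then mitochondrial genes, then rare genes.

    Cells are kept iff their expressed-gene count lies in
    [min_genes, max_genes] and their mitochondrial count fraction is strictly
    below ``max_mito_frac``. Mitochondrial genes are then removed, and genes
    kept iff expressed in at least ``min_cells_per_gene`` remaining cells.
    """
    mito_mask = np.array([bool(mito_genes(g)) for g in m.genes])
    n_expressed = (m.counts > 0).sum(axis=0)
    totals = m.totals().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.counts[mito_mask].sum(axis=0) / totals, 1.0)
    keep_cells = (n_expressed >= t.min_genes) & (mito_frac < t.max_mito_frac)
    if t.max_genes is not None:
        keep_cells &= n_expressed <= t.max_genes
    if not keep_cells.any():
        raise EmptyResultError("qc_filter removed every cell")
    out = m.subset_cells(np.flatnonzero(keep_cells))
    out = out.subset_genes(np.flatnonzero(~mito_mask))
    cells_per_gene = (out.counts > 0).sum(axis=1)
    out = out.subset_genes(np.flatnonzero(cells_per_gene >= t.min_cells_per_gene))
    if out.n_genes == 0:
        raise EmptyResultError("qc_filter removed every gene")
    return out


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def compute_size_factors(m: CountMatrix, method: str = "pooling") -> SizeFactors:
    """Per-cell scale factors, mean 1.

    ``library``: factor proportional to the cell's total count.
    ``pooling``: pool-and-deconvolve — cells ordered by library size on a ring
    are summed in sliding pools of sizes {21,41,61,81,101} (capped at the cell
    count); each pool's factor is estimated as the median gene-wise ratio to
    the average pseudo-cell, and per-cell factors solve the resulting sparse
    linear system by least squares.
    """
    totals = m.totals().astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(f"cell with zero total count: {m.cells[zero[0]]!r}")
    if method == "library":
        factors = totals / totals.mean()
    elif method == "pooling":
        factors = _pooling_factors(m.counts.astype(float), totals)
    else:
        raise ValidationError(f"unknown size-factor method {method!r}")
    factors = np.maximum(factors, 1e-8)
    factors = factors / factors.mean()
    return SizeFactors(list(m.cells), factors, method)


def _pooling_factors(counts: np.ndarray, totals: np.ndarray) -> np.ndarray:
    n = counts.shape[1]
    order = np.argsort(totals, kind="stable")
    ref = counts.mean(axis=1)  # average pseudo-cell
    ok = ref > 0
    rows, cols, data, b = [], [], [], []
    eq = 0
    for size in POOL_SIZES:
        s = min(size, n)
        for start in range(n):
            members = order[(start + np.arange(s)) % n]
            pooled = counts[:, members].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = pooled[ok] / ref[ok]
            theta = float(np.median(ratio))
            rows.extend([eq] * s)
            cols.extend(members.tolist())
            data.extend([1.0] * s)
            b.append(theta)
            eq += 1
        if s == n and size >= n:
            break
    # low-weight anchor rows keep the system well-posed and scale-consistent
    w = 0.1
    lib = totals / totals.mean()
    for i in range(n):
        rows.append(eq)
        cols.append(i)
        data.append(w)
        b.append(w * lib[i])
        eq += 1
    A = sp.csr_matrix((data, (rows, cols)), shape=(eq, n))
    sol = spla.lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10)[0]
    return sol


# ---------------------------------------------------------------------------
# Cross-batch rescaling
# ---------------------------------------------------------------------------

def multibatch_rescale(
    batches: Sequence[Tuple[CountMatrix, SizeFactors]],
) -> Tuple[List[LogMatrix], dict]:
    """log2(1 + count / (factor * s_b)) with s_b matching every batch's expected
    normalized coverage to the lowest-coverage batch.

    Returns the per-batch log matrices (restricted to the shared gene axis) and
    a record {"target_coverage", "scale_by_batch", "shared_genes"} reused when
    a query is normalized onto the reference scale.
    """
    if not batches:
        raise ValidationError("multibatch_rescale: no batches")
    shared = set(batches[0][0].genes)
    for cm, _ in batches[1:]:
        shared &= set(cm.genes)
    if not shared:
        raise ValidationError("multibatch_rescale: empty gene intersection")
    shared_genes = [g for g in batches[0][0].genes if g in shared]

    coverages, restricted = [], []
    for cm, sf in batches:
        idx = [cm.genes.index(g) for g in shared_genes] if cm.genes != shared_genes else None
        counts = cm.counts if idx is None else cm.counts[np.asarray(idx), :]
        coverages.append(float((counts.sum(axis=0) / sf.factors).mean()))
        restricted.append((cm, counts, sf))
    target = min(coverages)
    scale_by_batch, out = {}, []
    for (cm, counts, sf), cov in zip(restricted, coverages):
        s_b = cov / target
        batch_id = str(cm.cell_meta["batch"].iloc[0]) if cm.n_cells else "batch"
        scale_by_batch[batch_id] = s_b
        values = np.log2(1.0 + counts / (sf.factors * s_b)[None, :])
        out.append(
            LogMatrix(shared_genes, list(cm.cells), values,
                      {"scale": s_b, "target_coverage": target, "batch": batch_id})
        )
    record = {
        "target_coverage": target,
        "scale_by_batch": scale_by_batch,
        "shared_genes": shared_genes,
    }
    return out, record


def rescale_query(query: CountMatrix, sf: SizeFactors, target_coverage: float) -> LogMatrix:
    """Normalize a query onto the reference's lowest-coverage target scale."""
    cov = float((query.counts.sum(axis=0) / sf.factors).mean())
    s_q = cov / target_coverage
    values = np.log2(1.0 + query.counts / (sf.factors * s_q)[None, :])
    return LogMatrix(list(query.genes), list(query.cells), values,
                     {"scale": s_q, "target_coverage": target_coverage, "batch": "query"})


# ---------------------------------------------------------------------------
# Integration features
# ---------------------------------------------------------------------------

def _dispersion_rank(lm: LogMatrix) -> pd.Series:
    """Rank genes by variance of log-expression standardized against a
    lowess mean-variance trend (span 0.3); rank 0 = most variable."""
    mean = lm.values.mean(axis=1)
    var = lm.values.var(axis=1)
    if len(mean) >= 10 and np.ptp(mean) > 0:
        trend = lowess(var, mean, frac=0.3, return_sorted=False)
        trend = np.maximum(trend, 1e-12)
        score = var / trend
    else:
        score = var
    s = pd.Series(score, index=lm.genes)
    order = s.sort_values(ascending=False, kind="stable")
    ranks = pd.Series(np.arange(len(order)), index=order.index)
    return ranks.loc[lm.genes]


def select_integration_features(
    batches: Sequence[LogMatrix],
    stage1_group: Iterable[str],
    n_hvg_total: int = 4000,
    n_hvg_stage1: int = 2000,
) -> GeneSelection:
    """Two-stage cross-batch voting on per-batch variability ranks.

    Stage 1 selects ``n_hvg_stage1`` genes by how many of the designated
    early-stage batches rank them inside their own top-``n_hvg_stage1`` list
    (ties broken by median rank, then name); stage 2 extends the selection to
    ``n_hvg_total`` using the same vote over all batches, skipping genes
    already chosen.
    """
    stage1_group = set(stage1_group)
    ids = [lm.rescale_record.get("batch", f"b{i}") for i, lm in enumerate(batches)]
    if not stage1_group or not stage1_group <= set(ids):
        raise ValidationError("select_integration_features: stage1_group must be a non-empty "
                              f"subset of batch ids {ids}")
    shared = set(batches[0].genes)
    for lm in batches[1:]:
        shared &= set(lm.genes)
    shared_order = [g for g in batches[0].genes if g in shared]
    ranks = pd.DataFrame(
        {bid: _dispersion_rank(lm).reindex(shared_order) for bid, lm in zip(ids, batches)}
    )
    truncated = len(shared_order) < n_hvg_total
    if truncated:
        warnings.warn("fewer shared genes than n_hvg_total; selecting all shared genes")
        return GeneSelection(shared_order, ranks, truncated=True)

    def vote(cols: List[str], top_n: int, exclude: set, n_pick: int) -> List[str]:
        sub = ranks[cols]
        votes = (sub < top_n).sum(axis=1)
        med = sub.median(axis=1)
        tab = pd.DataFrame({"votes": votes, "med": med})
        tab = tab.drop(index=[g for g in exclude if g in tab.index])
        tab = tab.sort_values(["votes", "med"], ascending=[False, True], kind="stable")
        # stable name tie-break inside equal (votes, med) groups
        tab = tab.reset_index().sort_values(
            ["votes", "med", "index"], ascending=[False, True, True], kind="stable"
        )
        return tab["index"].head(n_pick).tolist()

    stage1_cols = [b for b in ids if b in stage1_group]
    picked = vote(stage1_cols, n_hvg_stage1, set(), min(n_hvg_stage1, len(shared_order)))
    remaining = n_hvg_total - len(picked)
    if remaining > 0:
        picked += vote(list(ids), n_hvg_total, set(picked), remaining)
    return GeneSelection(picked, ranks, truncated=False)


# ---------------------------------------------------------------------------
# Cosine normalization
# ---------------------------------------------------------------------------

def cosine_normalize(m: LogMatrix, genes: GeneSelection | Sequence[str],
                     impute_missing: bool = False) -> UnitMatrix:
    """Restrict columns to the feature selection and scale each to unit norm.

    All-zero columns are left as zeros and recorded in ``zero_columns``. With
    ``impute_missing``, selection genes absent from the matrix contribute
    zero rows (used for queries with partial gene coverage).
    """
    sel = list(genes.genes) if isinstance(genes, GeneSelection) else list(genes)
    index = {g: i for i, g in enumerate(m.genes)}
    if impute_missing:
        rows = np.array([index.get(g, -1) for g in sel])
        values = np.zeros((len(sel), len(m.cells)))
        present = rows >= 0
        values[present, :] = m.values[rows[present], :]
    else:
        missing = [g for g in sel if g not in index]
        if missing:
            raise ValidationError(f"cosine_normalize: genes not in matrix: {missing[:5]}")
        values = m.values[np.array([index[g] for g in sel]), :]
    norms = np.linalg.norm(values, axis=0)
    zero_cols = np.flatnonzero(norms == 0).tolist()
    safe = np.where(norms == 0, 1.0, norms)
    return UnitMatrix(sel, list(m.cells), values / safe[None, :], zero_cols)
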