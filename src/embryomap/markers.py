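"""Marker detection, module scoring, p-value combination and the consensus
multi-criteria differential-expression filters.

Per-gene testing uses the two-sided Wilcoxon rank-sum statistic on log
expression with Bonferroni adjustment; fold changes are computed on de-logged
means with a pseudocount of 1. Meta-analytic combination across comparisons
uses Stouffer's weighted-Z method, with two-sided p-values halved and signed
by fold-change direction before combination and re-two-sided afterwards.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEGCriteria
from .containers import LogMatrix
from .errors import ValidationError


# ---------------------------------------------------------------------------
# Wilcoxon markers
# ---------------------------------------------------------------------------

def _group_stats(expr: np.ndarray, in_mask: np.ndarray) -> Tuple[np.ndarray, ...]:
    x_in, x_out = expr[:, in_mask], expr[:, ~in_mask]
    mean_in = (2.0 ** x_in - 1.0).mean(axis=1)
    mean_out = (2.0 ** x_out - 1.0).mean(axis=1)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
    pct_in = (x_in > 0).mean(axis=1)
    pct_out = (x_out > 0).mean(axis=1)
    return log2fc, pct_in, pct_out, mean_in


def _wilcoxon_pvalues(expr: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    x_in, x_out = expr[:, in_mask], expr[:, ~in_mask]
    p = np.ones(expr.shape[0])
    for g in range(expr.shape[0]):
        a, b = x_in[g], x_out[g]
        if np.ptp(np.concatenate([a, b])) == 0:
            p[g] = 1.0
            continue
        p[g] = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    return p


def wilcoxon_markers(
    expr: LogMatrix,
    groups: Sequence[str],
    mode: str = "one_vs_rest",
    pair: Optional[Tuple[str, str]] = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Marker table with columns gene, group, log2_fold_change, pct_in,
    pct_out, p_value, p_adjusted (Bonferroni over tested genes), sorted by
    group then adjusted p. ``mode='pairwise'`` tests ``pair[0]`` against
    ``pair[1]`` only."""
    groups = np.asarray([str(g) for g in groups])
    if groups.shape[0] != len(expr.cells):
        raise ValidationError("wilcoxon_markers: one group label per cell required")
    if mode == "pairwise":
        if pair is None:
            raise ValidationError("wilcoxon_markers: pairwise mode needs pair=(a, b)")
        jobs = [(pair[0], groups == pair[0], groups == pair[1])]
    elif mode == "one_vs_rest":
        jobs = [(g, groups == g, groups != g) for g in sorted(set(groups))]
    else:
        raise ValidationError(f"wilcoxon_markers: unknown mode {mode!r}")

    frames = []
    n_genes = len(expr.genes)
    for name, in_mask, out_mask in jobs:
        if in_mask.sum() < min_cells or out_mask.sum() < min_cells:
            warnings.warn(f"group {name!r} below {min_cells} cells; skipped")
            continue
        sub = expr.values[:, in_mask | out_mask]
        rel_in = in_mask[in_mask | out_mask]
        log2fc, pct_in, pct_out, _ = _group_stats(sub, rel_in)
        p = _wilcoxon_pvalues(sub, rel_in)
        frames.append(
            pd.DataFrame(
                dict(
                    gene=expr.genes,
                    group=name,
                    log2_fold_change=log2fc,
                    pct_in=pct_in,
                    pct_out=pct_out,
                    p_value=p,
                    p_adjusted=np.minimum(p * n_genes, 1.0),
                )
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["gene", "group", "log2_fold_change", "pct_in", "pct_out",
                     "p_value", "p_adjusted"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["group", "p_adjusted", "gene"], kind="stable").reset_index(drop=True)


def compare_groups(expr: LogMatrix, groups: Sequence[str], high: str, low: str) -> pd.DataFrame:
    """One comparison's per-gene record: log2fc (high over low), p, p_adj,
    pct_high, pct_low, mean_expr_up — the row format consensus_deg consumes."""
    tab = wilcoxon_markers(expr, groups, mode="pairwise", pair=(high, low))
    groups = np.asarray([str(g) for g in groups])
    in_mask = groups == high
    sub = expr.values[:, (groups == high) | (groups == low)]
    rel_in = (groups == high)[(groups == high) | (groups == low)]
    _, _, _, mean_in = _group_stats(sub, rel_in)
    out = tab.rename(
        columns={"log2_fold_change": "log2fc", "p_value": "p",
                 "p_adjusted": "p_adj", "pct_in": "pct_high", "pct_out": "pct_low"}
    ).set_index("gene")
    out["mean_expr_up"] = pd.Series(mean_in, index=expr.genes)
    return out[["log2fc", "p", "p_adj", "pct_high", "pct_low", "mean_expr_up"]]


# ---------------------------------------------------------------------------
# Module score
# ---------------------------------------------------------------------------

def module_score(
    expr: LogMatrix,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Mean program expression minus mean of expression-bin-matched controls.

    Genes are binned by average expression into ``n_bins``; each program gene
    contributes ``n_ctrl`` control genes sampled (seeded) from its own bin.
    """
    present = [g for g in gene_set if g in expr.genes]
    if not present:
        raise ValidationError("module_score: gene_set does not intersect the matrix")
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(expr.genes)}
    avg = expr.values.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    n_bins = min(n_bins, len(expr.genes))
    bins = np.empty(len(expr.genes), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    prog_idx = np.array([idx[g] for g in present])
    ctrl_idx: List[int] = []
    for gi in prog_idx:
        pool = np.flatnonzero(bins == bins[gi])
        take = rng.choice(pool, size=min(n_ctrl, len(pool)), replace=len(pool) < n_ctrl)
        ctrl_idx.extend(take.tolist())
    prog_mean = expr.values[prog_idx].mean(axis=0)
    ctrl_mean = expr.values[np.asarray(ctrl_idx)].mean(axis=0)
    return prog_mean - ctrl_mean


# ---------------------------------------------------------------------------
# Stouffer combination
# ---------------------------------------------------------------------------

def stouffer_combine(
    p_values: Sequence[float], weights: Optional[Sequence[float]] = None
) -> float:
    """One-sided Stouffer: Z = sum(w_i * Phi^-1(1 - p_i)) / sqrt(sum w_i^2);
    returns 1 - Phi(Z). p = 0 is clamped to the smallest positive float."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("stouffer_combine: empty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("stouffer_combine: p-values must lie in (0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clamped to the smallest positive representable value")
        p = np.maximum(p, np.finfo(float).tiny)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape or np.any(w <= 0):
        raise ValidationError("stouffer_combine: weights must be positive, one per p")
    z = stats.norm.isf(p)
    Z = float((w * z).sum() / np.sqrt((w**2).sum()))
    return float(stats.norm.sf(Z))


def stouffer_combine_signed(
    p_two_sided: Sequence[float], directions: Sequence[float],
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Two-sided combination: halve each p, sign its z by the fold-change
    direction, combine, then re-two-side the pooled Z."""
    p = np.asarray(p_two_sided, dtype=float)
    d = np.sign(np.asarray(directions, dtype=float))
    d[d == 0] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    z = stats.norm.isf(p / 2.0) * d
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    Z = float((w * z).sum() / np.sqrt((w**2).sum()))
    return float(2.0 * stats.norm.sf(abs(Z)))


# ---------------------------------------------------------------------------
# Consensus DEG
# ---------------------------------------------------------------------------

def consensus_deg(
    results: Sequence[pd.DataFrame],
    criteria: DEGCriteria,
    sex_genes: Optional[Sequence[str]] = None,
) -> Tuple[List[str], pd.DataFrame]:
    """Genes passing every enabled criterion across comparisons.

    Each element of ``results`` is one comparison's per-gene table with
    columns log2fc, p, p_adj, pct_high, pct_low, mean_expr_up (see
    ``compare_groups``). Returns the surviving gene list and the boolean
    per-criterion pass table for audit.
    """
    if not results:
        raise ValidationError("consensus_deg: need at least one comparison")
    n_cmp = len(results)
    for name, v in (("min_comparisons_fc", criteria.min_comparisons_fc),
                    ("min_comparisons_p", criteria.min_comparisons_p),
                    ("min_comparisons_pct", criteria.min_comparisons_pct)):
        if v is not None and v > n_cmp:
            raise ValidationError(f"consensus_deg: {name}={v} exceeds {n_cmp} comparisons")
    genes = results[0].index
    for r in results[1:]:
        genes = genes.intersection(r.index)
    genes = sorted(genes)
    fc = pd.DataFrame({i: r.loc[genes, "log2fc"] for i, r in enumerate(results)})
    padj = pd.DataFrame({i: r.loc[genes, "p_adj"] for i, r in enumerate(results)})
    praw = pd.DataFrame({i: r.loc[genes, "p"] for i, r in enumerate(results)})
    pct_hi = pd.DataFrame({i: r.loc[genes, "pct_high"] for i, r in enumerate(results)})
    pct_lo = pd.DataFrame({i: r.loc[genes, "pct_low"] for i, r in enumerate(results)})
    mean_up = pd.DataFrame({i: r.loc[genes, "mean_expr_up"] for i, r in enumerate(results)})

    need_fc = criteria.min_comparisons_fc if criteria.min_comparisons_fc is not None else n_cmp
    need_p = criteria.min_comparisons_p if criteria.min_comparisons_p is not None else n_cmp
    need_pct = criteria.min_comparisons_pct if criteria.min_comparisons_pct is not None else n_cmp

    passes = pd.DataFrame(index=genes)
    passes["fc"] = (fc > criteria.min_log2fc).sum(axis=1) >= need_fc
    passes["p_adj"] = (padj < criteria.alpha).sum(axis=1) >= need_p
    if criteria.min_mean_expr_up is not None:
        passes["mean_expr"] = mean_up.mean(axis=1) > criteria.min_mean_expr_up
    if criteria.pct_high_floor is not None:
        pct_ok = (pct_hi > criteria.pct_high_floor) & (pct_lo < criteria.pct_low_ceiling)
        passes["pct"] = pct_ok.sum(axis=1) >= need_pct
    if criteria.require_stouffer:
        combined = np.array([
            stouffer_combine_signed(praw.loc[g].to_numpy(), fc.loc[g].to_numpy())
            for g in genes
        ])
        adj = np.minimum(combined * len(genes), 1.0)
        passes["stouffer"] = adj < criteria.alpha
    if criteria.exclude_sex_chromosomes:
        sex = set(sex_genes or [])
        passes["autosomal"] = [g not in sex for g in genes]
    surviving = passes.index[passes.all(axis=1)].tolist()
    return surviving, passes
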