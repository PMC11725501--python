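"""Neighborhood aggregation, per-lineage SVM training, gated identity
prediction with explicit abstention labels, and evaluation metrics.

Prediction gating: a unit is assigned its argmax lineage only when that
probability is at least the probability threshold AND the lineage has support
from the filtered MNN pairs; failing either gate yields "ambiguous". A failed
reference-correlation gate overrides everything with "nonrelated", and cells
never captured by any neighborhood are "nb_failed".
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import Config
from .containers import (
    ClassifierSet,
    CountMatrix,
    Metrics,
    NeighborhoodAssignment,
    PredictionResult,
    ProjectionResult,
    SPECIAL_LABELS,
)
from .errors import EmbryoMapError, ValidationError


# ---------------------------------------------------------------------------
# Neighborhoods
# ---------------------------------------------------------------------------

def make_neighborhoods(
    counts: CountMatrix,
    prop: float = 0.15,
    k: int = 30,
    seed: int = 0,
    coords: Optional[np.ndarray] = None,
) -> NeighborhoodAssignment:
    """milo-style kNN neighborhoods with summed raw counts.

    ``ceil(prop * n)`` candidate index cells are sampled uniformly, each
    refined to the member of its kNN set closest to that set's mean position,
    then deduplicated; a neighborhood is the index cell plus its k nearest
    neighbors, and its profile is the elementwise sum of member raw counts.
    ``coords`` defaults to a log-library-size-normalized PCA of the counts.
    """
    n = counts.n_cells
    if n < k + 1:
        raise ValidationError(f"make_neighborhoods: need at least k+1={k + 1} cells, got {n}")
    if coords is None:
        coords = _default_nhood_coords(counts, seed)
    rng = np.random.default_rng(seed)
    n_candidates = int(np.ceil(prop * n))
    candidates = rng.choice(n, size=n_candidates, replace=False)
    D = cdist(coords, coords)
    np.fill_diagonal(D, 0.0)
    order = np.argsort(D, axis=1, kind="stable")
    knn = order[:, 1 : k + 1]  # excludes self
    refined = []
    for c in candidates:
        group = np.concatenate(([c], knn[c]))
        center = coords[group].mean(axis=0)
        d2 = ((coords[group] - center) ** 2).sum(axis=1)
        refined.append(int(group[int(np.argmin(d2))]))
    index_cells = sorted(dict.fromkeys(refined))
    members = [np.concatenate(([i], knn[i])) for i in index_cells]
    agg = np.zeros((counts.n_genes, len(index_cells)), dtype=np.int64)
    cell_to_nhoods: Dict[int, List[int]] = {}
    for j, m in enumerate(members):
        agg[:, j] = counts.counts[:, m].sum(axis=1)
        for cell in m:
            cell_to_nhoods.setdefault(int(cell), []).append(j)
    nb_cells = [f"nb{j:04d}" for j in range(len(index_cells))]
    meta = pd.DataFrame(
        {
            "batch": [str(counts.cell_meta["batch"].iloc[i]) for i in index_cells],
            "time_point": [counts.cell_meta["time_point"].iloc[i] for i in index_cells],
            "label": [counts.cell_meta["label"].iloc[i] for i in index_cells],
        },
        index=nb_cells,
    )
    aggregated = CountMatrix(list(counts.genes), nb_cells, agg, meta)
    unassigned = [i for i in range(n) if i not in cell_to_nhoods]
    return NeighborhoodAssignment(index_cells, members, aggregated, cell_to_nhoods, unassigned)


def _default_nhood_coords(counts: CountMatrix, seed: int, n_pcs: int = 30,
                          n_hvg: int = 2000) -> np.ndarray:
    """Log library-size-normalized PCA on the most variable genes."""
    from sklearn.decomposition import PCA

    totals = counts.totals().astype(float)
    totals[totals == 0] = 1.0
    norm = np.log2(1.0 + counts.counts / totals[None, :] * np.median(totals))
    n_hvg = min(n_hvg, max(1, counts.n_genes // 4))
    if counts.n_genes > n_hvg:
        hvg = np.argsort(norm.var(axis=1), kind="stable")[-n_hvg:]
        norm = norm[hvg]
    d = min(n_pcs, counts.n_cells - 1, norm.shape[0])
    return PCA(n_components=d, random_state=seed).fit_transform(norm.T)


# ---------------------------------------------------------------------------
# Classifier training
# ---------------------------------------------------------------------------

def train_lineage_classifiers(
    latent_coords: np.ndarray,
    lineages: Sequence[str],
    cfg: Config,
) -> ClassifierSet:
    """One-vs-rest RBF-kernel SVMs, one per lineage, tuned by CV kappa.

    For each lineage a stratified 5-fold grid search over (C, gamma) selects
    the combination with the best mean Cohen's kappa on the binary task; the
    winner is refit on all cells with balanced class weights and Platt-scaled
    probabilities. Lineages with fewer than 10 cells skip the search and train
    on everything with mid-grid parameters (with a warning); fewer than 2
    cells is an error.
    """
    y_all = np.asarray([str(l) for l in lineages])
    names = sorted(set(y_all))
    for lin in names:
        if int((y_all == lin).sum()) < 2:
            raise ValidationError(f"lineage {lin!r} has fewer than 2 cells")
    models, best_params, cv_records = {}, {}, {}
    for lin in names:
        y = (y_all == lin).astype(int)
        n_pos = int(y.sum())
        n_splits = min(5, n_pos, len(y) - n_pos)
        if n_pos < 10 or n_splits < 2:
            warnings.warn(f"lineage {lin!r} has too few cells per class; "
                          "training without CV search")
            C, gamma = 1.0, float(np.median(cfg.svm_gamma_grid))
            cv_records[lin] = pd.DataFrame(columns=["C", "gamma", "mean_kappa"])
        else:
            C, gamma, record = _grid_search(latent_coords, y, cfg, n_splits)
            cv_records[lin] = record
        base = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
                   random_state=cfg.rng_seed)
        if n_splits >= 2:
            model = CalibratedClassifierCV(base, method="sigmoid", ensemble=False,
                                           cv=n_splits)
            model.fit(latent_coords, y)
        else:  # too few cells in a class to fold: calibrate on the training data
            from sklearn.frozen import FrozenEstimator

            base.fit(latent_coords, y)
            model = CalibratedClassifierCV(FrozenEstimator(base), method="sigmoid")
            model.fit(latent_coords, y)
        models[lin] = model
        best_params[lin] = {"C": C, "gamma": gamma}
    return ClassifierSet(names, models, best_params, cv_records)


def _grid_search(X: np.ndarray, y: np.ndarray, cfg: Config,
                 n_splits: int = 5) -> Tuple[float, float, pd.DataFrame]:
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=cfg.rng_seed)
    folds = list(skf.split(X, y))
    rows = []
    best = (-np.inf, None, None)
    for C in cfg.svm_c_grid:
        for gamma in cfg.svm_gamma_grid:
            kappas = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
                          random_state=cfg.rng_seed)
                clf.fit(X[tr], y[tr])
                kappas.append(cohen_kappa_score(y[te], clf.predict(X[te])))
            mean_kappa = float(np.mean(kappas))
            rows.append(dict(C=C, gamma=gamma, mean_kappa=mean_kappa))
            if mean_kappa > best[0]:  # strict: first grid entry wins ties
                best = (mean_kappa, C, gamma)
    return float(best[1]), float(best[2]), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_identities(
    proj: ProjectionResult,
    classifiers: ClassifierSet,
    cfg: Config,
    nhoods: Optional[NeighborhoodAssignment] = None,
    query_cells: Optional[Sequence[str]] = None,
    per_cell_support: Optional[bool] = None,
) -> PredictionResult:
    """Gated per-unit prediction, propagated to member cells when aggregated.

    ``proj`` holds coordinates of the predicted units (cells, or neighborhoods
    when ``nhoods`` is given, in which case ``query_cells`` must list the
    original per-cell ids).
    """
    nhoods = nhoods if nhoods is not None else proj.nhoods
    probs = classifiers.predict_proba(proj.latent_coords)
    supported = proj.pair_set.supported_lineages()
    per_cell_support = cfg.per_cell_mnn_support if per_cell_support is None else per_cell_support
    support_by_query: Dict[int, set] = {}
    if per_cell_support and len(proj.pair_set):
        support_by_query = proj.pair_set.pairs.groupby("query")["ref_lineage"].agg(set).to_dict()

    unit_rows = []
    lineage_order = list(probs.columns)
    arr = probs.to_numpy()
    for i in range(arr.shape[0]):
        flags: set = set()
        order = np.lexsort((lineage_order, -arr[i]))  # prob desc, name asc on ties
        cand = lineage_order[int(order[0])]
        p = float(arr[i, int(order[0])])
        if arr.shape[1] > 1 and np.isclose(arr[i, int(order[0])], arr[i, int(order[1])]):
            flags.add("tie_broken")
        label: str = cand
        prob: Optional[float] = p
        if proj.nonrelated_mask[i]:
            label, prob = "nonrelated", None
            flags = {"low_correlation"}
        elif p < cfg.prob_threshold:
            label, prob = "ambiguous", None
            flags.add("below_threshold")
        else:
            sup = support_by_query.get(i, supported) if per_cell_support else supported
            if proj.no_mnn_support or cand not in sup:
                label, prob = "ambiguous", None
                flags.add("no_mnn_support")
        unit_rows.append(dict(label=label, probability=prob, flags=frozenset(flags)))

    if nhoods is None:
        table = pd.DataFrame(
            dict(
                cell_id=list(proj.cells),
                label=[r["label"] for r in unit_rows],
                probability=[r["probability"] for r in unit_rows],
                flags=[r["flags"] for r in unit_rows],
                neighborhood_ids=[() for _ in unit_rows],
            )
        )
        return PredictionResult(table)

    if query_cells is None:
        raise ValidationError("predict_identities: query_cells required with neighborhoods")
    rows = []
    for i, cell in enumerate(query_cells):
        nb_ids = nhoods.cell_to_nhoods.get(i, [])
        if not nb_ids:
            rows.append(dict(cell_id=cell, label="nb_failed", probability=None,
                             flags=frozenset({"not_in_neighborhood"}), neighborhood_ids=()))
            continue
        # conflicts across neighborhoods resolved by highest probability;
        # lineage assignments outrank abstentions
        best = None
        for j in nb_ids:
            r = unit_rows[j]
            key = (r["probability"] is not None, r["probability"] or 0.0)
            if best is None or key > best[0]:
                best = (key, r)
        r = best[1]
        rows.append(dict(cell_id=cell, label=r["label"], probability=r["probability"],
                         flags=r["flags"], neighborhood_ids=tuple(nb_ids)))
    return PredictionResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_predictions(
    pred: PredictionResult,
    truth: pd.Series,
    label_map: Optional[Dict[str, str]] = None,
    include_special: bool = False,
) -> Metrics:
    """Confusion table, accuracy, Cohen's kappa and per-class precision/recall.

    By default cells with abstention labels are excluded from scoring; with
    ``include_special`` they enter the table as their own predicted classes
    (and count as errors). ``label_map`` coarsens both sides before scoring.
    """
    labels = pred.labels()
    common = [c for c in labels.index if c in truth.index]
    if not common:
        raise ValidationError("evaluate_predictions: no overlapping cells")
    y_pred = labels.loc[common].astype(str)
    y_true = truth.loc[common].astype(str)
    if label_map:
        y_pred = y_pred.map(lambda v: label_map.get(v, v))
        y_true = y_true.map(lambda v: label_map.get(v, v))
    if not include_special:
        keep = ~y_pred.isin(SPECIAL_LABELS)
        y_pred, y_true = y_pred[keep], y_true[keep]
    if len(y_pred) == 0:
        raise ValidationError("evaluate_predictions: nothing left to score")
    classes = sorted(set(y_true) | set(y_pred))
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    return metrics_from_confusion(pd.DataFrame(conf, index=classes, columns=classes))


def metrics_from_confusion(conf: pd.DataFrame) -> Metrics:
    """Accuracy = trace/total; kappa = (p_o - p_e)/(1 - p_e) with p_e from the
    marginals; per-class precision/recall from columns/rows (true on rows)."""
    M = conf.to_numpy(float)
    total = M.sum()
    if total == 0:
        raise ValidationError("metrics_from_confusion: empty table")
    p_o = np.trace(M) / total
    row = M.sum(axis=1) / total
    col = M.sum(axis=0) / total
    p_e = float(row @ col)
    kappa = 1.0 if np.isclose(p_e, 1.0) else (p_o - p_e) / (1.0 - p_e)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(M.sum(axis=0) > 0, np.diag(M) / M.sum(axis=0), np.nan)
        recall = np.where(M.sum(axis=1) > 0, np.diag(M) / M.sum(axis=1), np.nan)
    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall, "support": M.sum(axis=1).astype(int)},
        index=conf.index,
    )
    return Metrics(float(kappa), float(p_o), per_class, conf)
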