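"""Shared fixtures.

The expensive artifacts — a synthetic multi-batch reference model and the
projection of its held-out halves — are built once per session and shared by
the unit and acceptance tests. Problem sizes are scaled down from genome scale
(1,200 genes, 5 lineages x 3 batches x 40 cells) so the whole suite runs on
one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import embryomap as em

SIM_SEED = 11
PIPE_SEED = 5
ORDER = ["batch0", "batch1", "batch2"]


@pytest.fixture(scope="session")
def sim_cfg() -> em.SimConfig:
    return em.SimConfig(n_genes=1200, n_markers_per_lineage=25, seed=SIM_SEED)


@pytest.fixture(scope="session")
def pipe_cfg() -> em.Config:
    return em.Config(
        n_pcs=30,
        latent_dim=10,
        n_hvg_total=400,
        n_hvg_stage1=200,
        qc=em.QCThresholds(min_genes=200),
        umap_neighbors=15,
        rng_seed=PIPE_SEED,
        svm_c_grid=(0.25, 1.0, 4.0, 16.0),
        svm_gamma_grid=(2.0**-6, 2.0**-4, 2.0**-2),
    )


def split_halves(cm: em.CountMatrix):
    """Even/odd cell split preserving lineage balance."""
    even = np.arange(0, cm.n_cells, 2)
    odd = np.arange(1, cm.n_cells, 2)
    return cm.subset_cells(even), cm.subset_cells(odd)


@pytest.fixture(scope="session")
def ref_split(sim_cfg):
    batches, truth = em.simulate_reference_series(sim_cfg)
    train, held = [], []
    for b in batches:
        tr, ho = split_halves(b)
        train.append(tr)
        held.append(ho)
    genes = list(held[0].genes)
    counts = np.concatenate([h.counts for h in held], axis=1)
    cells = [c for h in held for c in h.cells]
    meta = pd.concat([h.cell_meta for h in held]).copy()
    truth_labels = meta["label"].copy()
    meta["batch"] = "query"
    heldout = em.CountMatrix(genes, cells, counts, meta)
    return train, heldout, truth_labels, truth


@pytest.fixture(scope="session")
def reference_model(ref_split, pipe_cfg) -> em.ReferenceModel:
    train, _, _, _ = ref_split
    return em.build_reference(train, ORDER, pipe_cfg)


@pytest.fixture(scope="session")
def heldout_projection(reference_model, ref_split) -> em.ProjectionResult:
    _, heldout, _, _ = ref_split
    return em.project_query(heldout, reference_model, aggregate=False)


@pytest.fixture(scope="session")
def heldout_predictions(reference_model, heldout_projection, pipe_cfg):
    return em.predict_identities(heldout_projection, reference_model.classifiers, pipe_cfg)
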