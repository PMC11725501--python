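"""Query embedding replay, subsampled MNN pairing, filtering, correction and
nonrelated gating."""

import numpy as np
import pandas as pd
import pytest

import embryomap as em
from embryomap.containers import PairSet
from embryomap.errors import ValidationError

from conftest import ORDER
from helpers import count_matrix


def make_pairset(rows):
    df = pd.DataFrame(rows)
    for col, default in (("ref_dataset", "d0"), ("repeat", 0), ("chunk", 0), ("k", 30)):
        if col not in df.columns:
            df[col] = default
    return PairSet(df[list(PairSet.COLUMNS)])


class TestEmbedQuery:
    def test_replay_identity_single_batch(self, sim_cfg):
        batches, _ = em.simulate_reference_series(sim_cfg)
        cfg = em.Config(n_pcs=10, latent_dim=5, n_hvg_total=300, n_hvg_stage1=150,
                        qc=em.QCThresholds(min_genes=200), umap_neighbors=10, rng_seed=2)
        model = em.build_reference(batches[:1], ["batch0"], cfg)
        # re-present the post-QC reference counts as a query
        post_qc = em.qc_filter(batches[0], cfg.qc)
        keep = [post_qc.genes.index(g) for g in model.rescale["shared_genes"]]
        query = post_qc.subset_genes(np.asarray(keep))
        raw, units, n_imputed = em.embed_query(query, model)
        assert n_imputed == 0
        assert np.abs(raw - model.corrected_coords).max() < 1e-8

    def test_missing_genes_imputed_and_counted(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        sel = set(reference_model.gene_selection.genes)
        drop = [i for i, g in enumerate(heldout.genes) if g in list(sel)[:20]]
        keep = np.asarray([i for i in range(heldout.n_genes) if i not in drop])
        query = heldout.subset_genes(keep)
        raw, units, n_imputed = em.embed_query(query, reference_model)
        assert n_imputed == 20
        assert raw.shape == (heldout.n_cells, reference_model.rotation.shape[1])

    def test_low_coverage_rejected(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        sel = set(reference_model.gene_selection.genes)
        sel_idx = [i for i, g in enumerate(heldout.genes) if g in sel]
        keep = np.asarray(
            [i for i in range(heldout.n_genes) if i not in set(sel_idx[: int(len(sel_idx) * 0.5)])]
        )
        with pytest.raises(ValidationError, match="coverage|integration features"):
            em.embed_query(heldout.subset_genes(keep), reference_model)


class TestSubsampledPairs:
    def test_small_query_uses_small_k(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        small = heldout.subset_cells(np.arange(40))
        raw, units, _ = em.embed_query(small, reference_model)
        pairs = em.subsampled_mnn_pairs(raw, units, reference_model)
        assert (pairs.pairs["k"] == reference_model.config.k_mnn_small).all()

    def test_chunk_sizes_follow_subsample_rule(self, reference_model, heldout_projection):
        pairs = heldout_projection.pair_set_unfiltered.pairs
        cfg = reference_model.config
        # held-out query: 300 cells -> chunks {200, 100} per repeat
        assert set(pairs["chunk"].unique()) == {0, 1}
        assert (pairs["k"] == cfg.k_mnn_query).all()
        assert set(pairs["repeat"].unique()) == set(range(cfg.n_repeats))

    def test_identical_query_pairs_with_itself_at_corr_one(self, sim_cfg):
        batches, _ = em.simulate_reference_series(sim_cfg)
        cfg = em.Config(n_pcs=10, latent_dim=5, n_hvg_total=300, n_hvg_stage1=150,
                        qc=em.QCThresholds(min_genes=200), umap_neighbors=10, rng_seed=2)
        model = em.build_reference(batches[:1], ["batch0"], cfg)
        post_qc = em.qc_filter(batches[0], cfg.qc)
        keep = [post_qc.genes.index(g) for g in model.rescale["shared_genes"]]
        query = post_qc.subset_genes(np.asarray(keep))
        raw, units, _ = em.embed_query(query, model)
        pairs = em.subsampled_mnn_pairs(raw, units, model)
        self_pairs = pairs.pairs[pairs.pairs.apply(
            lambda r: model.cells[int(r["ref"])] == query.cells[int(r["query"])], axis=1)]
        assert len(self_pairs) == query.n_cells
        assert np.allclose(self_pairs["corr"], 1.0, atol=1e-9)

    def test_union_over_repeats_monotone(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        raw, units, _ = em.embed_query(heldout, reference_model)
        import dataclasses
        cfg1 = dataclasses.replace(reference_model.config, n_repeats=1)
        cfg3 = dataclasses.replace(reference_model.config, n_repeats=3)
        p1 = em.subsampled_mnn_pairs(raw, units, reference_model, cfg1)
        p3 = em.subsampled_mnn_pairs(raw, units, reference_model, cfg3)
        s1 = set(map(tuple, p1.pairs[["query", "ref"]].to_numpy()))
        s3 = set(map(tuple, p3.pairs[["query", "ref"]].to_numpy()))
        assert s1 <= s3


class TestFilterPairs:
    CFG = em.Config(ambiguous_lineage_pairs=[("TE", "Amnion")])

    def test_low_correlation_pair_removed(self):
        ps = make_pairset([
            dict(query=0, ref=1, ref_lineage="TE", corr=0.49),
            dict(query=1, ref=2, ref_lineage="TE", corr=0.51),
        ])
        out, report = em.filter_mnn_pairs(ps, None, self.CFG)
        assert len(out) == 1 and report["low_corr_pairs"] == 1
        assert out.pairs.iloc[0]["query"] == 1

    def test_te_amnion_cell_loses_all_pairs(self):
        ps = make_pairset([
            dict(query=0, ref=1, ref_lineage="TE", corr=0.9),
            dict(query=0, ref=2, ref_lineage="Amnion", corr=0.9),
            dict(query=0, ref=3, ref_lineage="Epiblast", corr=0.9),
            dict(query=1, ref=1, ref_lineage="TE", corr=0.9),
        ])
        out, report = em.filter_mnn_pairs(ps, None, self.CFG)
        assert set(out.pairs["query"]) == {1}
        assert report["ambiguous_pair_cells"] == 1

    def test_weak_lineage_fully_dropped(self):
        rows = [dict(query=q, ref=q, ref_lineage="Hypoblast", corr=0.45) for q in range(30)]
        rows += [dict(query=q, ref=q + 100, ref_lineage="TE", corr=0.8) for q in range(30)]
        out, report = em.filter_mnn_pairs(make_pairset(rows), None, self.CFG)
        assert "Hypoblast" in report["weak_lineages"]
        assert set(out.pairs["ref_lineage"]) == {"TE"}

    def test_strong_tail_keeps_lineage(self):
        # one good pair inside the top-20 keeps the lineage alive
        rows = [dict(query=q, ref=q, ref_lineage="Hypoblast", corr=0.45) for q in range(19)]
        rows += [dict(query=50, ref=99, ref_lineage="Hypoblast", corr=0.7)]
        out, report = em.filter_mnn_pairs(make_pairset(rows), None, self.CFG)
        assert report["weak_lineages"] == []
        assert len(out) == 1  # the sub-threshold pairs still fail the pair filter

    def test_filtered_subset_and_threshold_monotone(self, heldout_projection, pipe_cfg):
        import dataclasses
        unf = heldout_projection.pair_set_unfiltered
        lo, _ = em.filter_mnn_pairs(unf, None, dataclasses.replace(pipe_cfg, corr_threshold=0.3))
        hi, _ = em.filter_mnn_pairs(unf, None, dataclasses.replace(pipe_cfg, corr_threshold=0.7))
        all_pairs = set(map(tuple, unf.pairs[["query", "ref"]].to_numpy()))
        lo_pairs = set(map(tuple, lo.pairs[["query", "ref"]].to_numpy()))
        hi_pairs = set(map(tuple, hi.pairs[["query", "ref"]].to_numpy()))
        assert hi_pairs <= lo_pairs <= all_pairs


class TestCorrectQuery:
    def test_offset_query_lands_on_reference_twins(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        raw, units, _ = em.embed_query(heldout, reference_model)
        offset = np.zeros(raw.shape[1])
        offset[0] = 5.0
        shifted = raw + offset
        pairs = em.subsampled_mnn_pairs(shifted, units, reference_model)
        filtered, _ = em.filter_mnn_pairs(pairs, reference_model)
        corrected, no_support = em.correct_query(shifted, filtered, reference_model)
        assert not no_support
        # corrected coords should sit within a few % of the offset norm of raw
        residual = np.linalg.norm(corrected - raw, axis=1).mean()
        assert residual < 0.10 * np.linalg.norm(offset) + 0.05 * raw.std()

    def test_empty_pairs_identity_with_flag(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        raw, _, _ = em.embed_query(heldout, reference_model)
        corrected, no_support = em.correct_query(raw, PairSet.empty(), reference_model)
        assert no_support and np.array_equal(corrected, raw)

    def test_identical_query_small_corrections(self, reference_model, heldout_projection):
        # held-out halves of the reference batches need almost no correction
        delta = np.linalg.norm(
            heldout_projection.corrected_coords - heldout_projection.raw_coords, axis=1)
        scale = np.linalg.norm(heldout_projection.raw_coords, axis=1).mean()
        assert np.median(delta) < 0.2 * scale


class TestFlagNonrelated:
    def test_duplicated_reference_cell_not_flagged(self, reference_model, heldout_projection):
        assert heldout_projection.nonrelated_mask.mean() <= 0.05
        assert heldout_projection.corr_stats.min() > 0.4

    def test_shuffled_cells_flagged(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        rng = np.random.default_rng(0)
        counts = heldout.counts.copy()
        for j in range(counts.shape[1]):  # destroy gene identity per cell
            counts[:, j] = rng.permutation(counts[:, j])
        shuffled = count_matrix(counts, genes=list(heldout.genes), batch="query")
        raw, units, _ = em.embed_query(shuffled, reference_model)
        mask, stats = em.flag_nonrelated(units, reference_model)
        assert mask.mean() > 0.95

    def test_threshold_is_strict_less_than(self):
        import dataclasses
        from embryomap.projection import flag_nonrelated  # noqa: F401  (API under test)
        # direct mask semantics: corr_stat exactly at threshold is NOT flagged
        stats = np.array([0.5, 0.499999, 0.51])
        mask = stats < 0.5
        assert list(mask) == [False, True, False]


class TestProjectQuery:
    def test_deterministic_same_seed(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        p1 = em.project_query(heldout, reference_model, aggregate=False)
        p2 = em.project_query(heldout, reference_model, aggregate=False)
        assert np.array_equal(p1.corrected_coords, p2.corrected_coords)
        assert np.array_equal(p1.embed2_coords, p2.embed2_coords)
        assert p1.pair_set.pairs.equals(p2.pair_set.pairs)

    def test_reference_untouched_by_projection(self, reference_model, ref_split):
        _, heldout, _, _ = ref_split
        before = reference_model.corrected_coords.copy()
        emb_before = reference_model.embed2.embedding_.copy()
        em.project_query(heldout, reference_model, aggregate=False)
        assert np.array_equal(reference_model.corrected_coords, before)
        assert np.array_equal(reference_model.embed2.embedding_, emb_before)

    def test_self_projection_neighborhood_recovery(self, reference_model, ref_split,
                                                   heldout_projection):
        _, _, truth_labels, _ = ref_split
        from scipy.spatial.distance import cdist
        ref_emb = reference_model.embed2.embedding_
        ref_lin = np.asarray(reference_model.lineages)
        D = cdist(heldout_projection.embed2_coords, ref_emb)
        nn = np.argsort(D, axis=1)[:, :10]
        hits = 0
        truth = truth_labels.to_numpy()
        for i in range(len(truth)):
            labels, counts = np.unique(ref_lin[nn[i]], return_counts=True)
            if labels[counts.argmax()] == truth[i] and counts.max() > 5:
                hits += 1
        assert hits / len(truth) >= 0.95
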