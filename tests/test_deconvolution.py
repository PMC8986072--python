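import numpy as np
import pandas as pd
import pytest

from triomics.deconvolution import (CompositionScorer, MarkerSelector,
                                    composition_scores, score_recovery_report,
                                    select_markers)
from triomics.io import ExpressionMatrix, MarkerPanel, ValidationError
from triomics.simulate import SimulationConfig, candidate_panel, simulate_study


def expr_from_array(arr, gene_ids=None, sample_ids=None):
    n_g, n_s = arr.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_g)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    vals = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(vals, pd.Series("coding", index=gene_ids))


def panel_of(genes, subset="A", panel_group="main"):
    return MarkerPanel(pd.DataFrame({"subset": subset, "gene_id": genes,
                                     "panel_group": panel_group}))


class TestMarkerSelection:
    def test_near_duplicate_candidates_all_kept(self):
        rng = np.random.default_rng(0)
        base = rng.normal(7, 1, 30)
        arr = np.tile(base, (6, 1)) + rng.normal(0, 1e-4, (6, 30))
        panel = select_markers(expr_from_array(arr), panel_of([f"g{i}" for i in range(6)]))
        assert len(panel.table) == 6
        assert (panel.record["mean_r"] > 0.999).all()

    def test_planted_block_vs_decoys(self):
        # 8 candidates sharing a latent factor (pairwise r ~ 0.9) and 4
        # independent decoys: selection separates them in every seed.  The
        # mean pairwise r of a true candidate is diluted by its decoy pairs
        # (factor 7/11 here), so the block correlation must clear the 0.50
        # gate with margin for exact separation.
        for seed in range(20):
            rng = np.random.default_rng(seed)
            latent = rng.normal(0, 1, 60)
            block = 7 + latent + rng.normal(0, 0.3, (8, 60))
            decoys = rng.normal(7, 1, (4, 60))
            expr = expr_from_array(np.vstack([block, decoys]))
            panel = select_markers(expr, panel_of([f"g{i}" for i in range(12)]))
            kept = set(panel.table["gene_id"])
            assert kept == {f"g{i}" for i in range(8)}, f"seed {seed}"

    def test_threshold_one_keeps_nothing(self):
        rng = np.random.default_rng(1)
        base = rng.normal(7, 1, 20)
        arr = np.tile(base, (4, 1)) + rng.normal(0, 1e-6, (4, 20))
        panel = select_markers(expr_from_array(arr),
                               panel_of([f"g{i}" for i in range(4)]),
                               r_threshold=1.0)
        assert len(panel.table) == 0

    def test_selection_monotone_in_r_threshold(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(0, 1, 30)
        arr = 7 + 0.7 * latent + rng.normal(0, 0.7, (10, 30))
        expr = expr_from_array(arr)
        cands = panel_of([f"g{i}" for i in range(10)])
        kept = [set(select_markers(expr, cands, r_threshold=r).table["gene_id"])
                for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo

    def test_constant_gene_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        base = rng.normal(7, 1, 20)
        arr = np.vstack([np.tile(base, (3, 1)) + rng.normal(0, 1e-5, (3, 20)),
                         np.full((1, 20), 5.0)])
        with caplog.at_level("WARNING", logger="triomics"):
            panel = select_markers(expr_from_array(arr),
                                   panel_of([f"g{i}" for i in range(4)]))
        assert "g3" not in set(panel.table["gene_id"])
        assert any("constant" in r.message for r in caplog.records)

    def test_pairwise_all_mode_is_stricter(self):
        rng = np.random.default_rng(4)
        latent = rng.normal(0, 1, 40)
        arr = 7 + latent + rng.normal(0, 0.6, (8, 40))
        expr = expr_from_array(arr)
        cands = panel_of([f"g{i}" for i in range(8)])
        per_gene = set(select_markers(expr, cands).table["gene_id"])
        pairwise = set(select_markers(expr, cands,
                                      mode="pairwise_all").table["gene_id"])
        assert pairwise <= per_gene

    def test_too_few_samples_rejected(self):
        arr = np.random.default_rng(5).normal(7, 1, (4, 3))
        with pytest.raises(ValidationError, match="samples"):
            select_markers(expr_from_array(arr),
                           panel_of([f"g{i}" for i in range(4)]))


class TestCompositionScores:
    def test_constant_markers_give_constant_score(self):
        arr = np.full((3, 5), 4.5)
        panel = MarkerPanel(pd.DataFrame({"subset": "A",
                                          "gene_id": ["g0", "g1", "g2"],
                                          "panel_group": "main"}),
                            stage="selected")
        scores = composition_scores(expr_from_array(arr), panel)
        assert np.allclose(scores["A"], 4.5)

    def test_two_panel_groups_add(self):
        arr = np.vstack([np.full((2, 4), 1.5), np.full((2, 4), 2.25)])
        panel = MarkerPanel(pd.DataFrame({
            "subset": "A", "gene_id": ["g0", "g1", "g2", "g3"],
            "panel_group": ["x", "x", "y", "y"]}), stage="selected")
        scores = composition_scores(expr_from_array(arr), panel)
        assert np.allclose(scores["A"], 1.5 + 2.25)

    def test_translation_equivariance_single_group(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(7, 1, (4, 6))
        panel = MarkerPanel(pd.DataFrame({"subset": "A",
                                          "gene_id": [f"g{i}" for i in range(4)],
                                          "panel_group": "main"}),
                            stage="selected")
        s0 = composition_scores(expr_from_array(arr), panel)
        s1 = composition_scores(expr_from_array(arr + 2.5), panel)
        assert np.allclose(s1["A"], s0["A"] + 2.5)

    def test_invariant_to_marker_and_sample_order(self):
        rng = np.random.default_rng(7)
        arr = rng.normal(7, 1, (5, 6))
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{i}" for i in range(6)]
        panel = MarkerPanel(pd.DataFrame({"subset": "A", "gene_id": genes,
                                          "panel_group": "main"}),
                            stage="selected")
        s0 = composition_scores(expr_from_array(arr, genes, samples), panel)
        perm_g, perm_s = rng.permutation(5), rng.permutation(6)
        expr_p = expr_from_array(arr[np.ix_(perm_g, perm_s)],
                                 [genes[i] for i in perm_g],
                                 [samples[i] for i in perm_s])
        panel_p = MarkerPanel(panel.table.iloc[rng.permutation(5)], stage="selected")
        s1 = composition_scores(expr_p, panel_p).loc[s0.index]
        assert np.allclose(s0["A"], s1["A"])

    def test_candidate_panel_rejected(self):
        arr = np.full((2, 4), 1.0)
        with pytest.raises(ValidationError, match="selected"):
            composition_scores(expr_from_array(arr), panel_of(["g0", "g1"]))

    def test_empty_subset_gets_na_column_and_warning(self, caplog):
        rng = np.random.default_rng(8)
        arr = rng.normal(7, 1, (4, 8))
        record = pd.DataFrame({"subset": ["A", "A", "B", "B"],
                               "gene_id": [f"g{i}" for i in range(4)],
                               "panel_group": "main",
                               "mean_r": [0.9, 0.9, 0.1, 0.1],
                               "p": [1e-4] * 4,
                               "kept": [True, True, False, False]})
        panel = MarkerPanel(record[record["kept"]][["subset", "gene_id",
                                                    "panel_group"]],
                            stage="selected", record=record)
        with caplog.at_level("WARNING", logger="triomics"):
            scores = composition_scores(expr_from_array(arr), panel)
        assert scores["B"].isna().all()
        assert not scores["A"].isna().any()


class TestRecovery:
    def test_default_study_recovery(self, default_study):
        st = default_study
        panel = select_markers(st.expression, candidate_panel(st))
        scores = composition_scores(st.expression, panel)
        report = score_recovery_report(scores, st)
        assert np.nanmin(report["r"]) >= 0.9

    def test_noise_free_recovery_is_exact(self):
        cfg = SimulationConfig(n_families=6, n_hc=6, n_genes=400,
                               noise_sd=0.0, family_effect_sd=0.0, seed=9)
        st = simulate_study(cfg)
        scores = composition_scores(
            st.expression,
            MarkerPanel(candidate_panel(st).table[
                candidate_panel(st).table["gene_id"].isin(
                    st.marker_genes["gene_id"])].reset_index(drop=True),
                stage="selected"))
        report = score_recovery_report(scores, st)
        assert np.allclose(report["r"], 1.0, atol=1e-9)

    def test_report_covers_all_subsets(self, default_study):
        st = default_study
        panel = select_markers(st.expression, candidate_panel(st))
        scores = composition_scores(st.expression, panel)
        report = score_recovery_report(scores, st)
        assert list(report["subset"]) == list(scores.columns)

    def test_myeloid_scores_depressed_in_trios(self, default_study):
        st = default_study
        panel = select_markers(st.expression, candidate_panel(st))
        scores = composition_scores(st.expression, panel)
        trio = (st.metadata["group"] != "HC").to_numpy()
        for subset in ("monocyte", "macrophage", "DC"):
            a = scores.loc[trio, subset]
            b = scores.loc[~trio, subset]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert a.mean() - b.mean() < -3 * se
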