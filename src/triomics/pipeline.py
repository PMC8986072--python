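"""End-to-end pipeline on a simulated trio study.

``run_all`` simulates two cohorts sharing one gene universe (a direct-PBMC
model and a plasma model), runs differential expression, trio set logic,
marker selection and composition scoring, group and clinical comparisons,
clustering with the family-adjacency metric, and overlap enrichment, writing
every stage's table under ``out_dir``.  All outputs are deterministic in the
seed, byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, deconvolution, diffexpr, enrichment, set_logic, structure
from .group_stats import compare_scores
from .io import (Contrast, write_expression, write_gmt, write_marker_panel,
                 write_metadata, write_table)
from .simulate import (MYELOID_SUBSETS, SimulationConfig, candidate_panel,
                       marker_collection, simulate_study, truth_report)

logger = logging.getLogger("triomics")

DEFAULT_COMPARISONS = ["proband:HC", "parent:HC", "proband:mother"]
DEFAULT_PAIRED = ["proband:mother"]


def run_all(config: SimulationConfig | None = None, out_dir=".",
            fold_threshold: float = 2.0, q_threshold: float = 0.05,
            r_threshold: float = 0.50, p_threshold: float = 0.01,
            top: int = 10) -> dict:
    """Run the full pipeline; returns a dict of headline numbers."""
    cfg = config or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate: two cohorts over one gene universe
    layout = cfg.seed if cfg.layout_seed is None else cfg.layout_seed
    cfg_pbmc = replace(cfg, model="PBMC", layout_seed=layout)
    cfg_plasma = replace(cfg, model="plasma", seed=cfg.seed + 1,
                         layout_seed=layout)
    study = simulate_study(cfg_pbmc)
    study2 = simulate_study(cfg_plasma)
    write_expression(study.expression, out / "expression.tsv")
    write_metadata(study.metadata, out / "metadata.tsv")
    panel0 = candidate_panel(study)
    write_marker_panel(panel0, out / "markers.tsv")
    gene_tbl, sample_tbl = truth_report(study)
    write_table(gene_tbl, out / "truth_genes.tsv")
    write_table(sample_tbl, out / "truth_samples.tsv")

    # --- differential expression
    contrasts = {
        "proband_vs_hc": Contrast("proband_vs_hc", "proband", "HC"),
        "mother_vs_hc": Contrast("mother_vs_hc", "mother", "HC"),
    }
    de = {name: diffexpr.fit_moderated(study.expression, study.metadata, c,
                                       fold_threshold, q_threshold)
          for name, c in contrasts.items()}
    de2 = diffexpr.fit_moderated(study2.expression, study2.metadata,
                                 contrasts["proband_vs_hc"], fold_threshold,
                                 q_threshold)
    for name, res in {**de, "plasma_proband_vs_hc": de2}.items():
        write_table(res, out / f"de_{name}.tsv")
    summary = diffexpr.deg_summary(de["proband_vs_hc"],
                                   study.expression.locus_type)
    write_table(summary, out / "deg_summary.tsv")
    write_table(diffexpr.volcano_table(de["proband_vs_hc"]),
                out / "volcano_proband_vs_hc.tsv")

    # --- trio set logic
    fam = set_logic.venn_partition(de["proband_vs_hc"], de["mother_vs_hc"])
    trio_shared, proband_unique = sorted(fam.shared), sorted(fam.a_unique)
    (out / "trio_shared.txt").write_text("\n".join(trio_shared) + "\n")
    (out / "proband_unique.txt").write_text("\n".join(proband_unique) + "\n")
    write_table(pd.DataFrame([fam.counts]), out / "venn_counts.tsv")
    input_set, counts = set_logic.build_input_gene_set(
        de["proband_vs_hc"], de2, de["mother_vs_hc"],
        coding_only=True, locus_type=study.expression.locus_type)
    write_table(input_set, out / "input_gene_set.tsv")

    # --- deconvolution
    panel = deconvolution.select_markers(study.expression, panel0,
                                         r_threshold, p_threshold)
    write_table(panel.record, out / "selection_record.tsv")
    scores = deconvolution.composition_scores(study.expression, panel)
    write_table(scores.reset_index(), out / "scores.tsv")
    recovery = deconvolution.score_recovery_report(scores, study)
    write_table(recovery, out / "score_recovery.tsv")

    # --- group comparisons
    comparisons = compare_scores(scores, study.metadata, DEFAULT_COMPARISONS,
                                 paired=DEFAULT_PAIRED)
    write_table(comparisons, out / "comparisons.tsv")

    # --- clinical associations
    assoc_frames = [clinical.subgroup_compare(scores, study.metadata, strat)
                    for strat in clinical.STRATIFIERS]
    write_table(pd.concat(assoc_frames, ignore_index=True),
                out / "subgroup_comparisons.tsv")
    corr = clinical.correlate_clinical(scores, study.metadata)
    write_table(corr, out / "clinical_correlations.tsv")
    conc_genes = trio_shared if len(trio_shared) >= 6 else \
        list(de["proband_vs_hc"].loc[de["proband_vs_hc"]["is_deg"], "gene_id"])
    if conc_genes:
        conc = clinical.fold_change_concordance(de["proband_vs_hc"],
                                                de["mother_vs_hc"], conc_genes)
        write_table(conc, out / "fold_change_concordance.tsv")

    # --- structure
    cluster_genes = trio_shared if len(trio_shared) >= 2 else \
        list(gene_tbl.loc[gene_tbl["family_effect"], "gene_id"])
    coords, varfrac = structure.pca_embed(study.expression, cluster_genes)
    write_table(coords.reset_index(), out / "embedding.tsv")
    clust = structure.hier_cluster(study.expression, cluster_genes)
    write_table(pd.DataFrame(clust.linkage,
                             columns=["left", "right", "height", "size"]),
                out / "linkage.tsv")
    adjacency, detail = structure.family_adjacency(clust, study.metadata)
    write_table(detail, out / "family_adjacency.tsv")

    # --- enrichment
    collection = marker_collection(study)
    write_gmt(collection, out / "collection.gmt")
    universe = study.expression.gene_ids
    query = list(input_set["gene_id"]) if len(input_set) else \
        list(de["proband_vs_hc"].loc[de["proband_vs_hc"]["is_deg"], "gene_id"])
    enr = enrichment.enrich(query, collection, universe)
    write_table(enr, out / "enrichment.tsv")
    write_table(enrichment.top_k(enr, top), out / "enrichment_top.tsv")

    myeloid = [s for s in scores.columns if s in MYELOID_SUBSETS]
    headline = {
        "n_deg_proband_vs_hc": int(de["proband_vs_hc"]["is_deg"].sum()),
        "n_trio_shared": len(trio_shared),
        "n_proband_unique": len(proband_unique),
        "input_gene_set_counts": counts,
        "markers_kept": int(panel.record["kept"].sum()),
        "min_recovery_r": float(np.nanmin(recovery["r"])),
        "family_adjacency": adjacency,
        "top_enrichment_set": enr.iloc[0]["set_name"] if len(enr) else None,
        "myeloid_min_adj_p": float(
            comparisons.loc[(comparisons["score"].isin(myeloid))
                            & (comparisons["comparison"] == "proband:HC"),
                            "p_adjusted"].min()) if len(comparisons) else None,
    }
    write_table(pd.DataFrame([{"key": k, "value": str(v)}
                              for k, v in headline.items()]),
                out / "summary.tsv")
    return headline
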