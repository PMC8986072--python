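"""Trio-structured synthetic expression studies with known ground truth.

The generator emulates the statistical structure the analysis stages assume:
a log2 expression matrix over proband/father/mother trios plus unrelated
healthy controls (HC), where

* each sample is a mixture of immune-cell subsets with weights drawn from a
  Dirichlet distribution; marker genes of subset ``k`` carry the additive
  log-ratio signal ``a * log2(w_k / w_bar_k)``;
* a myeloid suppression effect ``delta`` (log2 units) lowers myeloid marker
  genes in all trio members, mirroring the reduced mononuclear-phagocyte
  abundance the composition analysis is meant to detect;
* a familial effect ``gamma_f ~ Normal(0, tau^2)``, shared by all members of
  a family, acts on a declared subset of background genes (the
  "trio-shared-like" genes that drive family-structured clustering);
* i.i.d. Gaussian noise ``epsilon ~ Normal(0, sigma^2)`` everywhere;
* clinical covariates are linked to the realized myeloid signal deficit of
  each proband, so correlation analyses have a planted sign to recover.

Per-family severity is two-level: a balanced half of families are "severe"
(``delta_f = 1.3 * delta``, CFTR class I/II/III, pancreatic insufficient) and
half "mild" (``delta_f = 0.7 * delta``, class IV, pancreatic sufficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GeneSetCollection, MarkerPanel,
                 ValidationError, validate_metadata)

DEFAULT_SUBSETS = (
    "T_total", "T_CD4", "B", "NK", "other_lymphoid",
    "monocyte", "macrophage", "monocyte_act", "macrophage_act", "DC",
)
MYELOID_SUBSETS = frozenset(
    {"monocyte", "macrophage", "monocyte_act", "macrophage_act", "DC"})

# Dirichlet concentration per subset.  Uniform by default: every subset then
# carries comparable log-scale weight variability, so marker selection and
# score recovery behave uniformly across subsets (the generator emulates the
# statistical structure of a mixture, not literal PBMC proportions).
DEFAULT_CONCENTRATION = (8.0,) * 10


@dataclass
class SimulationConfig:
    """Study-design and generative parameters (all log2 units unless noted)."""

    n_families: int = 14
    n_hc: int = 18
    n_genes: int = 2000
    subsets: tuple = DEFAULT_SUBSETS
    markers_per_subset: int = 20
    decoys_per_subset: int = 3
    mixture_concentration: tuple = DEFAULT_CONCENTRATION
    mixture_scale: float = 1.0          # 'a': log-ratio signal amplitude
    myeloid_suppression_delta: float = 0.8
    family_effect_sd: float = 0.6       # tau
    noise_sd: float = 0.3               # sigma
    family_effect_frac: float = 0.3     # fraction of background genes with gamma
    frac_coding: float = 0.45
    frac_multiple_complex: float = 0.25
    frac_noncoding: float = 0.25
    clinical_link_slope: float = 15.0   # units (mmol/L or %pred) per log2 deficit
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    model: str = "PBMC"
    seed: int = 0
    # draw the gene layout/baselines from a separate seed so that several
    # cellular models can share one gene universe while sampling fresh cohorts
    layout_seed: int | None = None

    def __post_init__(self):
        if len(self.subsets) != len(self.mixture_concentration):
            raise ValidationError("one concentration parameter per subset required")
        if self.markers_per_subset < 2:
            raise ValidationError("markers_per_subset must be >= 2")
        if self.n_genes < len(self.subsets) * self.markers_per_subset:
            raise ValidationError(
                f"n_genes={self.n_genes} cannot host "
                f"{len(self.subsets)} x {self.markers_per_subset} marker genes")
        if self.frac_coding + self.frac_multiple_complex + self.frac_noncoding > 1 + 1e-12:
            raise ValidationError("locus-type fractions must sum to <= 1")
        for name in ("family_effect_sd", "noise_sd", "baseline_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SimulatedStudy:
    """A generated study plus its ground truth."""

    config: SimulationConfig
    expression: ExpressionMatrix
    metadata: pd.DataFrame
    weights: pd.DataFrame          # sample x subset, rows on the simplex
    gene_truth: pd.DataFrame       # gene_id, role, subset, family_effect, baseline
    sample_truth: pd.DataFrame     # severity delta_f, per-subset deficits

    @property
    def marker_genes(self) -> pd.DataFrame:
        return self.gene_truth[self.gene_truth["role"] == "marker"]


def _sample_layout(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for f in range(1, cfg.n_families + 1):
        fam = f"F{f:02d}"
        for group, tag in (("proband", "P"), ("father", "F"), ("mother", "M")):
            rows.append((f"{fam}_{tag}", group, fam))
    for h in range(1, cfg.n_hc + 1):
        sid = f"HC{h:02d}"
        rows.append((sid, "HC", sid))  # singleton pseudo-family
    return pd.DataFrame(rows, columns=["sample_id", "group", "family_id"])


def _gene_layout(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    ids = [f"G{i:05d}" for i in range(1, n + 1)]
    role = np.array(["background"] * n, dtype=object)
    subset = np.array([""] * n, dtype=object)
    i = 0
    for s in cfg.subsets:
        role[i:i + cfg.markers_per_subset] = "marker"
        subset[i:i + cfg.markers_per_subset] = s
        i += cfg.markers_per_subset
    for s in cfg.subsets:
        j = min(i + cfg.decoys_per_subset, n)
        role[i:j] = "decoy"
        subset[i:j] = s
        i = j
    locus = np.array(["other"] * n, dtype=object)
    # markers/decoys are protein-coding by construction
    locus[role != "background"] = "coding"
    bg = np.flatnonzero(role == "background")
    n_bg = len(bg)
    counts = [int(round(cfg.frac_coding * n_bg)),
              int(round(cfg.frac_multiple_complex * n_bg)),
              int(round(cfg.frac_noncoding * n_bg))]
    labels = (["coding"] * counts[0] + ["multiple_complex"] * counts[1]
              + ["noncoding"] * counts[2])
    labels += ["other"] * (n_bg - len(labels))
    locus[bg] = np.array(labels[:n_bg], dtype=object)[rng.permutation(n_bg)]
    fam_eff = np.zeros(n, dtype=bool)
    n_fam = int(round(cfg.family_effect_frac * n_bg))
    fam_eff[rng.choice(bg, size=n_fam, replace=False)] = True
    return pd.DataFrame({"gene_id": ids, "locus_type": locus, "role": role,
                         "subset": subset, "family_effect": fam_eff})


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study; fully determined by ``config`` (incl. its seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rng_layout = (np.random.default_rng(cfg.layout_seed)
                  if cfg.layout_seed is not None else rng)
    samples = _sample_layout(cfg)
    genes = _gene_layout(cfg, rng_layout)
    baseline = rng_layout.normal(cfg.baseline_mean, cfg.baseline_sd,
                                 size=cfg.n_genes)
    n_s, n_g = len(samples), cfg.n_genes
    subsets = list(cfg.subsets)

    alpha = np.asarray(cfg.mixture_concentration, dtype=float)
    w = rng.dirichlet(alpha, size=n_s)                      # samples x subsets
    w_bar = alpha / alpha.sum()
    log_ratio = np.log2(np.clip(w, 1e-12, None) / w_bar)

    x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_g, n_s))

    # mixture signal on marker genes
    sub_index = {s: i for i, s in enumerate(subsets)}
    marker_mask = (genes["role"] == "marker").to_numpy()
    marker_sub = genes.loc[marker_mask, "subset"].map(sub_index).to_numpy()
    x[marker_mask] += cfg.mixture_scale * log_ratio[:, marker_sub].T

    # per-family severity and the myeloid suppression
    fams = [f"F{f:02d}" for f in range(1, cfg.n_families + 1)]
    n_sev = cfg.n_families // 2
    severe = np.zeros(cfg.n_families, dtype=bool)
    severe[rng.permutation(cfg.n_families)[:n_sev]] = True
    delta_f = np.where(severe, 1.3, 0.7) * cfg.myeloid_suppression_delta
    fam_delta = dict(zip(fams, delta_f))
    fam_severe = dict(zip(fams, severe))
    sample_delta = np.array([fam_delta.get(f, 0.0)
                             for f in samples["family_id"]])
    is_trio = (samples["group"] != "HC").to_numpy()
    myeloid_marker = marker_mask & genes["subset"].isin(MYELOID_SUBSETS).to_numpy()
    x[np.ix_(myeloid_marker, is_trio)] -= sample_delta[is_trio]

    # shared familial effect on declared background genes (HC = singleton families)
    fam_genes = genes["family_effect"].to_numpy()
    n_fg = int(fam_genes.sum())
    if cfg.family_effect_sd > 0 and n_fg:
        all_fams = list(dict.fromkeys(samples["family_id"]))
        gamma = {f: rng.normal(0.0, cfg.family_effect_sd, size=n_fg)
                 for f in all_fams}
        for j, f in enumerate(samples["family_id"]):
            x[fam_genes, j] += gamma[f]

    expression = ExpressionMatrix(
        pd.DataFrame(x, index=pd.Index(genes["gene_id"], name="gene_id"),
                     columns=samples["sample_id"]),
        pd.Series(genes["locus_type"].to_numpy(), index=genes["gene_id"].to_numpy()),
    )

    # per-sample realized myeloid deficits (positive = lower myeloid signal)
    deficit = {}
    for s in ("monocyte", "macrophage"):
        k = sub_index[s]
        deficit[s] = np.where(is_trio, sample_delta, 0.0) \
            - cfg.mixture_scale * log_ratio[:, k]

    meta = samples.copy()
    meta["model"] = cfg.model
    is_proband = (meta["group"] == "proband").to_numpy()
    sev_sample = np.array([fam_severe.get(f, False) for f in meta["family_id"]])
    meta["cftr_class"] = np.where(is_proband,
                                  np.where(sev_sample, "I_II_III", "IV"), "NA")
    meta["pancreatic"] = np.where(is_proband,
                                  np.where(sev_sample, "PI", "PS"), "NA")
    pa = np.where(rng.random(n_s) < np.where(sev_sample, 0.75, 0.25), "pos", "neg")
    meta["pa_infection"] = np.where(is_proband, pa, "NA")
    sweat = np.where(
        is_proband,
        100.0 + cfg.clinical_link_slope * deficit["macrophage"]
        + rng.normal(0.0, 5.0, n_s),
        rng.uniform(10.0, 40.0, n_s))
    meta["sweat_chloride"] = np.clip(sweat, 0.0, None).round(4)
    fev1 = np.where(
        is_proband,
        95.0 - cfg.clinical_link_slope * deficit["monocyte"]
        + rng.normal(0.0, 5.0, n_s),
        rng.normal(95.0, 7.0, n_s))
    meta["fev1_pct"] = np.clip(fev1, 10.0, 140.0).round(4)
    meta = meta[["sample_id", "group", "family_id", "model", "cftr_class",
                 "pancreatic", "pa_infection", "sweat_chloride", "fev1_pct"]]
    validate_metadata(meta)

    weights = pd.DataFrame(w, index=pd.Index(meta["sample_id"], name="sample_id"),
                           columns=subsets)
    gene_truth = genes.assign(baseline=baseline)
    sample_truth = pd.DataFrame({
        "sample_id": meta["sample_id"],
        "group": meta["group"],
        "family_id": meta["family_id"],
        "severity_delta": np.where(is_trio, sample_delta, 0.0),
        "monocyte_deficit": deficit["monocyte"],
        "macrophage_deficit": deficit["macrophage"],
    })
    return SimulatedStudy(cfg, expression, meta, weights, gene_truth, sample_truth)


def expected_signal(study: SimulatedStudy) -> pd.DataFrame:
    """Planted expected marker-signal deviation per (sample, subset).

    ``a * log2(w / w_bar)`` minus the myeloid suppression for trio samples —
    the deterministic part of every marker gene's deviation from baseline,
    hence the target a composition score should recover.
    """
    cfg = study.config
    alpha = np.asarray(cfg.mixture_concentration, dtype=float)
    w_bar = alpha / alpha.sum()
    sig = cfg.mixture_scale * np.log2(
        np.clip(study.weights.to_numpy(), 1e-12, None) / w_bar)
    sig = pd.DataFrame(sig, index=study.weights.index, columns=study.weights.columns)
    trio = (study.metadata["group"] != "HC").to_numpy()
    delta = study.sample_truth.set_index("sample_id")["severity_delta"]
    for s in study.weights.columns:
        if s in MYELOID_SUBSETS:
            sig[s] = sig[s] - np.where(trio, delta.loc[sig.index], 0.0)
    return sig


def candidate_panel(study: SimulatedStudy) -> MarkerPanel:
    """Candidate marker panel: the true markers plus the decoy candidates."""
    gt = study.gene_truth
    rows = gt[gt["role"].isin(["marker", "decoy"])]
    table = pd.DataFrame({"subset": rows["subset"].to_numpy(),
                          "gene_id": rows["gene_id"].to_numpy(),
                          "panel_group": "main"})
    return MarkerPanel(table, stage="candidate")


def truth_report(study: SimulatedStudy) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth tables (per gene, per sample) for recovery tests."""
    gene_tbl = study.gene_truth.copy()
    sample_tbl = study.sample_truth.merge(
        study.weights.add_prefix("w_"), left_on="sample_id", right_index=True)
    return gene_tbl, sample_tbl


def marker_collection(study: SimulatedStudy, n_random: int = 20,
                      set_size: int = 30) -> GeneSetCollection:
    """A gene-set collection for enrichment runs: one set of true markers per
    subset plus random background sets, drawn deterministically from the
    study's seed."""
    rng = np.random.default_rng(study.config.seed + 104729)
    sets, desc = {}, {}
    gt = study.gene_truth
    for s in study.config.subsets:
        sets[f"MARKERS_{s.upper()}"] = set(
            gt.loc[(gt["role"] == "marker") & (gt["subset"] == s), "gene_id"])
        desc[f"MARKERS_{s.upper()}"] = f"true marker genes of {s}"
    universe = gt["gene_id"].to_numpy()
    for i in range(1, n_random + 1):
        name = f"RANDOM_{i:03d}"
        sets[name] = set(rng.choice(universe, size=set_size, replace=False))
        desc[name] = "random background set"
    return GeneSetCollection("simulated_collection", sets, desc)


def null_config(base: SimulationConfig | None = None, **overrides) -> SimulationConfig:
    """A global-null configuration: no group effect, no mixture signal."""
    cfg = base or SimulationConfig()
    return replace(cfg, myeloid_suppression_delta=0.0, mixture_scale=0.0,
                   **overrides)
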