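"""Clinical associations of composition scores and fold-change concordance.

Correlations between scores and continuous severity measures (sweat
chloride, percent-predicted FEV1) are plain Pearson analyses on complete
pairs, unadjusted for multiplicity by default (the multiple-comparison
behaviour is an explicit flag); subgroup comparisons stratify probands on
CFTR class, pancreatic status or P. aeruginosa infection and reuse the
pooled-variance t machinery with Holm-Šidák adjustment within each score.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .group_stats import guarded_ttest, holm_sidak
from .io import ValidationError

logger = logging.getLogger("triomics")

STRATIFIERS = ("cftr_class", "pancreatic", "pa_infection")
DEFAULT_COVARIATES = ("sweat_chloride", "fev1_pct")


def subgroup_compare(scores: pd.DataFrame, meta: pd.DataFrame,
                     stratifier: str, include_hc: bool = True) -> pd.DataFrame:
    """Compare scores between clinical strata (and each stratum vs HC)."""
    if stratifier not in STRATIFIERS:
        raise ValidationError(f"unknown stratifier {stratifier!r}")
    meta = meta.set_index("sample_id").loc[scores.index].reset_index()
    strata = [lv for lv in meta[stratifier].unique() if lv not in ("NA", "")]
    strata = sorted(strata)
    if len(strata) < 2 and not include_hc:
        raise ValidationError(f"need >= 2 strata of {stratifier}")
    members = {lv: meta.loc[meta[stratifier] == lv, "sample_id"] for lv in strata}
    if include_hc:
        members["HC"] = meta.loc[meta["group"] == "HC", "sample_id"]
    pairs = []
    names = strata + (["HC"] if include_hc else [])
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs.append((a, b))
    rows = []
    for score_name in scores.columns:
        s = scores[score_name]
        fam = []
        for a, b in pairs:
            va, vb = s.loc[members[a]].to_numpy(), s.loc[members[b]].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                logger.warning("%s %s vs %s skipped (stratum too small)",
                               score_name, a, b)
                continue
            t, p = guarded_ttest("independent", va, vb)
            fam.append({"score": score_name, "stratifier": stratifier,
                        "comparison": f"{a}:{b}",
                        "estimate": float(np.mean(va) - np.mean(vb)),
                        "n_case": len(va), "n_ref": len(vb),
                        "t": float(t), "p_raw": float(p)})
        if fam:
            for r, q in zip(fam, holm_sidak([r["p_raw"] for r in fam])):
                r["p_adjusted"] = float(q)
            rows.extend(fam)
    return pd.DataFrame(rows)


def correlate_clinical(scores: pd.DataFrame, meta: pd.DataFrame,
                       covariates=DEFAULT_COVARIATES,
                       groups: tuple = ("proband",),
                       adjust: bool = False) -> pd.DataFrame:
    """Pearson correlation of each score with each clinical covariate.

    Only samples in ``groups`` enter (covariates are defined for probands);
    missing covariate values are dropped pairwise, and fewer than 4 complete
    pairs yields an NA row.  ``adjust=True`` applies Holm-Šidák across the
    covariates within each score.
    """
    meta = meta.set_index("sample_id").loc[scores.index]
    keep = meta["group"].isin(groups)
    rows = []
    for score_name in scores.columns:
        fam = []
        for cov in covariates:
            x = scores.loc[keep.to_numpy(), score_name]
            y = pd.to_numeric(meta.loc[keep, cov], errors="coerce")
            ok = x.notna().to_numpy() & y.notna().to_numpy()
            n = int(ok.sum())
            if n < 4:
                fam.append({"score": score_name, "covariate": cov, "n": n,
                            "r": np.nan, "r2": np.nan, "p": np.nan,
                            "slope": np.nan, "intercept": np.nan})
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            lr = stats.linregress(xv, yv)
            r = float(lr.rvalue)
            fam.append({"score": score_name, "covariate": cov, "n": n,
                        "r": r, "r2": r * r, "p": float(lr.pvalue),
                        "slope": float(lr.slope),
                        "intercept": float(lr.intercept)})
        if adjust:
            ps = [f["p"] for f in fam if np.isfinite(f.get("p", np.nan))]
            if ps:
                adj = iter(holm_sidak(ps))
                for f in fam:
                    f["p_adjusted"] = (float(next(adj))
                                       if np.isfinite(f["p"]) else np.nan)
        rows.extend(fam)
    return pd.DataFrame(rows)


def fold_change_concordance(deA: pd.DataFrame, deB: pd.DataFrame,
                            genes) -> pd.DataFrame:
    """Per-direction concordance of log2 fold changes between two contrasts.

    Genes are split by their direction in ``deA``; within each half the
    Pearson r, R^2, p, and the least-squares line of ``deB`` fold changes on
    ``deA`` fold changes are reported (NA when a half has < 3 genes).
    """
    a = deA.set_index("gene_id")
    b = deB.set_index("gene_id")
    genes = [g for g in genes]
    missing = [g for g in genes if g not in a.index or g not in b.index]
    if missing:
        raise ValidationError(f"genes absent from a universe: {missing[:5]}")
    rows = []
    for direction in ("up", "down"):
        sel = [g for g in genes if a.loc[g, "direction"] == direction]
        if len(sel) < 3:
            rows.append({"direction": direction, "n": len(sel), "r": np.nan,
                         "r2": np.nan, "p": np.nan, "slope": np.nan,
                         "intercept": np.nan})
            continue
        x = a.loc[sel, "log2fc"].to_numpy(dtype=float)
        y = b.loc[sel, "log2fc"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"direction": direction, "n": len(sel), "r": np.nan,
                         "r2": np.nan, "p": np.nan, "slope": np.nan,
                         "intercept": np.nan})
            continue
        lr = stats.linregress(x, y)
        r = float(lr.rvalue)
        rows.append({"direction": direction, "n": len(sel), "r": r,
                     "r2": r * r, "p": float(lr.pvalue),
                     "slope": float(lr.slope), "intercept": float(lr.intercept)})
    return pd.DataFrame(rows)
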