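"""Group comparisons of per-sample scores with family-wise error control.

Trio-vs-HC comparisons use the unpaired pooled-variance two-sided t test
(normality and equal variances assumed); within-trio comparisons use the
paired two-sided t test, pairing samples on family_id.  Within each score,
p values across its family of comparisons are adjusted by the Holm-Šidák
step-down procedure; the number of scores is deliberately not adjusted for.
The growth-assay style design (>= 3 groups, one control) uses the
Kruskal-Wallis test with tie correction followed, when significant, by
Dunn's control comparisons with Bonferroni multiplication.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError

logger = logging.getLogger("triomics")

DEFAULT_POOLING = {"parent": ("father", "mother")}


def holm_sidak(p) -> np.ndarray:
    """Holm-Šidák step-down adjusted p values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to holm_sidak")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):   # p == 1 is legal input
        return multipletests(p, method="holm-sidak")[1]


def _group_members(meta: pd.DataFrame, group: str, pooling: dict) -> pd.DataFrame:
    groups = pooling.get(group, (group,))
    return meta[meta["group"].isin(groups)]


def _paired_values(score: pd.Series, meta: pd.DataFrame, g1: str, g2: str,
                   pooling: dict) -> tuple[np.ndarray, np.ndarray]:
    m1 = _group_members(meta, g1, pooling).set_index("family_id")
    m2 = _group_members(meta, g2, pooling).set_index("family_id")
    fams = [f for f in m1.index if f in set(m2.index)]
    a = score.loc[[m1.loc[f, "sample_id"] for f in fams]].to_numpy()
    b = score.loc[[m2.loc[f, "sample_id"] for f in fams]].to_numpy()
    return a, b


def guarded_ttest(kind, a, b) -> tuple[float, float]:
    """Two-sided t test with a conservative p = 1 on degenerate input."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant input is guarded below
        if kind == "paired":
            t, p = stats.ttest_rel(a, b)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(p):
        return 0.0, 1.0
    return float(t), float(p)


def compare_scores(scores: pd.DataFrame, meta: pd.DataFrame, comparisons,
                   paired=(), pooling: dict | None = None) -> pd.DataFrame:
    """Compare every score column between the requested group pairs.

    ``comparisons`` is a list of ``(case, reference)`` pairs (or
    ``"case:ref"`` strings); pairs listed in ``paired`` are tested with the
    paired t test (pairing on family_id).  Group labels may name pooled
    groups defined in ``pooling`` (default: ``parent`` = father + mother).
    Adjustment is Holm-Šidák within each score's family of comparisons.
    """
    pooling = DEFAULT_POOLING if pooling is None else pooling
    comparisons = [tuple(c.split(":")) if isinstance(c, str) else tuple(c)
                   for c in comparisons]
    paired = {tuple(c.split(":")) if isinstance(c, str) else tuple(c)
              for c in paired}
    meta = meta.set_index("sample_id").loc[scores.index].reset_index()
    rows = []
    for score_name in scores.columns:
        s = scores[score_name]
        fam_rows = []
        for (g1, g2) in comparisons:
            is_paired = (g1, g2) in paired
            if is_paired:
                a, b = _paired_values(s, meta, g1, g2, pooling)
                if len(a) < 2:
                    logger.warning("%s %s:%s skipped (<2 complete pairs)",
                                   score_name, g1, g2)
                    continue
                t, p = guarded_ttest("paired", a, b)
                est = float(np.mean(a - b))
                test = "t_paired"
            else:
                a = s.loc[_group_members(meta, g1, pooling)["sample_id"]].to_numpy()
                b = s.loc[_group_members(meta, g2, pooling)["sample_id"]].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    logger.warning("%s %s:%s skipped (<2 observations)",
                                   score_name, g1, g2)
                    continue
                t, p = guarded_ttest("independent", a, b)
                est = float(np.mean(a) - np.mean(b))
                test = "t_independent"
            fam_rows.append({"score": score_name, "comparison": f"{g1}:{g2}",
                             "test": test, "estimate": est,
                             "n_case": len(a), "n_ref": len(b),
                             "t": t, "p_raw": p, "family": score_name})
        if fam_rows:
            adj = holm_sidak([r["p_raw"] for r in fam_rows])
            for r, q in zip(fam_rows, adj):
                r["p_adjusted"] = float(q)
            rows.extend(fam_rows)
    return pd.DataFrame(rows)


def kruskal_dunn(values, groups, control: str,
                 alpha: float = 0.05) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis across >= 3 groups; Dunn's control comparisons post hoc.

    Returns (H, p_kw, posthoc table).  Post hoc runs only when the global
    test is significant at ``alpha``; Dunn z uses mean ranks with the
    tie-corrected variance and p values are Bonferroni-multiplied by the
    number of control comparisons.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 3:
        raise ValidationError("kruskal_dunn requires >= 3 groups")
    if control not in labels:
        raise ValidationError(f"control group {control!r} not present")
    if np.ptp(values) == 0:
        raise ValidationError("all values tied; H is undefined")
    by_group = [values[groups == g] for g in labels]
    h, p_kw = stats.kruskal(*by_group)

    posthoc = pd.DataFrame(columns=["group", "control", "z", "p_raw",
                                    "p_adjusted"])
    if p_kw < alpha:
        n_total = len(values)
        ranks = stats.rankdata(values)
        _, counts = np.unique(values, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
        base_var = n_total * (n_total + 1) / 12.0 - tie_term
        mean_rank = {g: float(ranks[groups == g].mean()) for g in labels}
        n_by = {g: int((groups == g).sum()) for g in labels}
        others = [g for g in labels if g != control]
        rows = []
        for g in others:
            se = np.sqrt(base_var * (1.0 / n_by[g] + 1.0 / n_by[control]))
            z = (mean_rank[g] - mean_rank[control]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group": g, "control": control, "z": float(z),
                         "p_raw": float(p),
                         "p_adjusted": float(min(1.0, p * len(others)))})
        posthoc = pd.DataFrame(rows)
    return float(h), float(p_kw), posthoc
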