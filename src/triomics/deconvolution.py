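"""Marker-based immune cell composition profiling.

Candidate marker genes for each cell subset are screened by a within-subset
pairwise-correlation criterion: a candidate is kept when the mean of its
Pearson correlations with the other candidates of the same subset exceeds
``r_threshold`` (default 0.50) with significance ``p < p_threshold``
(default 0.01), the p value coming from the Fisher z transform of the mean
correlation at the sample count.  The raw cell composition score of a sample
is then the sum over panel groups of the simple average of the selected
marker genes' log2 expression (for a single panel group, the plain marker
mean) — a relative abundance proxy comparable across participant groups, not
an absolute cell fraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ExpressionMatrix, MarkerPanel, ValidationError

logger = logging.getLogger("triomics")


def _fisher_z_p(mean_r: float, n: int) -> float:
    """Two-sided normal p for a correlation via the Fisher z transform."""
    if n <= 3 or not np.isfinite(mean_r):
        return float("nan")
    z = np.arctanh(np.clip(mean_r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(n - 3)
    return float(2.0 * stats.norm.sf(abs(z)))


class MarkerSelector(BaseEstimator):
    """Select subset markers by the within-subset correlation criterion.

    Parameters
    ----------
    r_threshold, p_threshold : float
        Keep a candidate iff mean pairwise r > r_threshold (strict) and the
        Fisher-z p of the mean r is < p_threshold.
    mode : {"per_gene", "pairwise_all"}
        ``per_gene`` tests each candidate's mean pairwise correlation;
        ``pairwise_all`` additionally requires every individual pairwise r
        with co-subset candidates to exceed the threshold.

    Attributes (after ``fit``)
    --------------------------
    record_ : DataFrame with (subset, gene_id, panel_group, mean_r, p, kept)
    panel_ : MarkerPanel at stage "selected"
    """

    def __init__(self, r_threshold: float = 0.50, p_threshold: float = 0.01,
                 mode: str = "per_gene"):
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold
        self.mode = mode

    def fit(self, expr: ExpressionMatrix, panel: MarkerPanel):
        if self.mode not in ("per_gene", "pairwise_all"):
            raise ValidationError(f"unknown selection mode {self.mode!r}")
        if len(expr.sample_ids) < 4:
            raise ValidationError("marker selection needs >= 4 samples")
        known = set(expr.gene_ids)
        rows = []
        for subset in panel.subsets:
            sub = panel.table[panel.table["subset"] == subset]
            genes = [g for g in sub["gene_id"] if g in known]
            missing = set(sub["gene_id"]) - known
            if missing:
                logger.warning("subset %s: %d candidate(s) absent from the "
                               "expression matrix", subset, len(missing))
            if len(genes) < 2:
                raise ValidationError(
                    f"subset {subset!r} has fewer than 2 measurable candidates")
            X = expr.values.loc[genes].to_numpy()
            sd = X.std(axis=1, ddof=1)
            const = sd == 0
            for g in np.asarray(genes)[const]:
                logger.warning("candidate %s (%s) has constant expression; "
                               "dropped", g, subset)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.corrcoef(X)
            np.fill_diagonal(corr, np.nan)
            n = X.shape[1]
            pg = sub.set_index("gene_id")["panel_group"]
            for i, g in enumerate(genes):
                if const[i]:
                    rows.append((subset, g, pg[g], np.nan, np.nan, False))
                    continue
                others = np.delete(corr[i], i)
                others = others[~np.isnan(others)]
                if len(others) == 0:
                    rows.append((subset, g, pg[g], np.nan, np.nan, False))
                    continue
                mean_r = float(np.mean(others))
                p = _fisher_z_p(mean_r, n)
                kept = (mean_r > self.r_threshold) and (p < self.p_threshold)
                if self.mode == "pairwise_all":
                    kept = kept and bool((others > self.r_threshold).all())
                rows.append((subset, g, pg[g], mean_r, p, kept))
        self.record_ = pd.DataFrame(
            rows, columns=["subset", "gene_id", "panel_group", "mean_r", "p",
                           "kept"])
        kept = self.record_[self.record_["kept"]]
        self.panel_ = MarkerPanel(
            kept[["subset", "gene_id", "panel_group"]].reset_index(drop=True),
            stage="selected", record=self.record_)
        logger.info("marker selection: kept %d of %d candidates "
                    "(r>%.2f, p<%.3g)", len(kept), len(self.record_),
                    self.r_threshold, self.p_threshold)
        return self


class CompositionScorer(BaseEstimator, TransformerMixin):
    """Compute raw composition scores from a selected marker panel."""

    def __init__(self, panel: MarkerPanel):
        self.panel = panel

    def fit(self, expr: ExpressionMatrix, y=None):
        if self.panel.stage != "selected":
            raise ValidationError("CompositionScorer requires a selected panel")
        return self

    def transform(self, expr: ExpressionMatrix) -> pd.DataFrame:
        self.fit(expr)
        scores = {}
        known = set(expr.gene_ids)
        # every subset present in the (candidate-stage) record keeps a column
        all_subsets = (list(dict.fromkeys(self.panel.record["subset"]))
                       if self.panel.record is not None else self.panel.subsets)
        for subset in all_subsets:
            sub = self.panel.table[self.panel.table["subset"] == subset]
            genes = [g for g in sub["gene_id"] if g in known]
            if not genes:
                logger.warning("subset %s has no selected markers; score is NA",
                               subset)
                scores[subset] = np.full(len(expr.sample_ids), np.nan)
                continue
            sub = sub[sub["gene_id"].isin(genes)]
            total = np.zeros(len(expr.sample_ids))
            for _, grp in sub.groupby("panel_group", sort=True):
                total += expr.values.loc[list(grp["gene_id"])].mean(
                    axis=0).to_numpy()
            scores[subset] = total
        return pd.DataFrame(scores,
                            index=pd.Index(expr.sample_ids, name="sample_id"))


def select_markers(expr: ExpressionMatrix, candidates: MarkerPanel,
                   r_threshold: float = 0.50, p_threshold: float = 0.01,
                   mode: str = "per_gene") -> MarkerPanel:
    """Functional wrapper over :class:`MarkerSelector`."""
    sel = MarkerSelector(r_threshold=r_threshold, p_threshold=p_threshold,
                         mode=mode).fit(expr, candidates)
    return sel.panel_


def composition_scores(expr: ExpressionMatrix, panel: MarkerPanel) -> pd.DataFrame:
    """Functional wrapper over :class:`CompositionScorer`."""
    return CompositionScorer(panel).transform(expr)


def score_recovery_report(scores: pd.DataFrame, study) -> pd.DataFrame:
    """Per-subset Pearson r between the score and the planted signal.

    The truth transform is the study's expected marker-signal deviation
    (mixture log-ratio plus any planted group effect), i.e. the deterministic
    component a perfect score would equal up to an additive constant.
    """
    from .simulate import expected_signal
    truth = expected_signal(study)
    rows = []
    for subset in scores.columns:
        s = scores[subset].reindex(truth.index)
        if subset not in truth.columns or s.isna().all():
            rows.append({"subset": subset, "r": np.nan, "n": 0})
            continue
        ok = s.notna()
        if s[ok].std(ddof=1) == 0 or truth.loc[ok, subset].std(ddof=1) == 0:
            r = 1.0 if np.allclose(s[ok] - s[ok].mean(),
                                   truth.loc[ok, subset]
                                   - truth.loc[ok, subset].mean()) else np.nan
        else:
            r = float(stats.pearsonr(s[ok], truth.loc[ok, subset])[0])
        rows.append({"subset": subset, "r": r, "n": int(ok.sum())})
    return pd.DataFrame(rows)
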