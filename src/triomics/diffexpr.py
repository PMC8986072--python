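"""Moderated-variance two-group differential expression.

The test is the standard moderated t construction for microarray data: the
per-gene residual variance ``s2_g`` (pooled within-group, or variance of
paired differences) is shrunk toward a prior ``s0_sq`` with prior degrees of
freedom ``d0``,

    s2_tilde_g = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g),

and the moderated statistic ``t = log2fc / (s_tilde_g * SEfactor)`` is
referred to a t distribution with ``d_g + d0`` degrees of freedom.  The prior
is estimated from the observed variances by moment matching on ``log s2_g``
against the scaled-F prior predictive (digamma/trigamma inversion); when the
trigamma equation has no positive root the prior is taken as infinitely
informative (``d0 = inf``, every posterior variance equals ``s0_sq``).

Significance gates follow the 2-fold / FDR < 0.05 convention: a gene is a DEG
iff ``|log2fc| >= log2(fold_threshold)`` and its Benjamini-Hochberg q-value is
``< q_threshold``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import Contrast, ExpressionMatrix, ValidationError, check_samples_match

logger = logging.getLogger("triomics")


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p must be a non-empty 1-d vector")
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to benjamini_hochberg")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-transformed guess)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < tol * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0_sq) from observed residual variances with df each.

    Moment matching of ``log s2`` to the log of a scaled F distribution:
    ``E[log s2] = log s0_sq + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)``
    and ``Var[log s2] = psi'(d/2) + psi'(d0/2)``.
    """
    s2 = np.asarray(s2, dtype=float)
    med = float(np.median(s2))
    if med <= 0:
        raise ValidationError(
            "most residual variances are zero; cannot fit a variance prior")
    s2 = np.maximum(s2, 1e-5 * med)   # guard exact zeros
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid > 0:
        d0 = 2.0 * trigamma_inverse(resid)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        # trigamma equation has no positive root: infinitely informative prior
        d0 = np.inf
        s0_sq = float(np.mean(s2))
    return d0, s0_sq


def moderate_variances(s2: np.ndarray, df: float, d0: float,
                       s0_sq: float) -> np.ndarray:
    """Posterior (shrunk) variances s2_tilde."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


class ModeratedTTest(BaseEstimator):
    """Per-feature moderated two-sample (or paired) t test.

    Parameters
    ----------
    fold_threshold : float, default=2.0
        Fold-change gate on the linear scale; a feature must satisfy
        ``|log2fc| >= log2(fold_threshold)`` to be flagged.
    q_threshold : float, default=0.05
        BH-FDR gate (strict ``<``).
    d0 : float or None, default=None
        Prior degrees of freedom. ``None`` estimates the prior from the data;
        ``0`` reduces to the ordinary pooled-variance (or paired) t test;
        ``numpy.inf`` fixes every variance at the prior value.

    Attributes (after ``fit``)
    --------------------------
    log2fc_, s2_, t_, p_, q_, is_deg_ : ndarray per feature
    d0_, s0_sq_ : the variance prior actually used
    df_residual_, df_total_ : residual and total degrees of freedom
    """

    def __init__(self, fold_threshold: float = 2.0, q_threshold: float = 0.05,
                 d0: float | None = None):
        self.fold_threshold = fold_threshold
        self.q_threshold = q_threshold
        self.d0 = d0

    def fit(self, X, y, pairs=None):
        """Fit on ``X`` (n_samples x n_features) with binary labels ``y``
        (1 = case, 0 = reference); ``pairs`` gives pair identifiers for a
        paired design (every pair must appear once per arm)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("X must be n_samples x n_features matching y")
        case, ref = X[y == 1], X[y == 0]
        if pairs is not None:
            pairs = np.asarray(pairs)
            case_ids, ref_ids = pairs[y == 1], pairs[y == 0]
            common = [p for p in case_ids if p in set(ref_ids)]
            if len(common) < 2:
                raise ValidationError("paired design requires >= 2 complete pairs")
            ci = {p: i for i, p in enumerate(case_ids)}
            ri = {p: i for i, p in enumerate(ref_ids)}
            d = case[[ci[p] for p in common]] - ref[[ri[p] for p in common]]
            n = len(common)
            self.log2fc_ = d.mean(axis=0)
            self.s2_ = d.var(axis=0, ddof=1)
            self.df_residual_ = float(n - 1)
            se_factor = np.sqrt(1.0 / n)
            self.n_case_, self.n_ref_ = n, n
        else:
            if len(case) < 2 or len(ref) < 2:
                raise ValidationError("both groups need >= 2 samples")
            n1, n2 = len(case), len(ref)
            self.log2fc_ = case.mean(axis=0) - ref.mean(axis=0)
            pooled = ((n1 - 1) * case.var(axis=0, ddof=1)
                      + (n2 - 1) * ref.var(axis=0, ddof=1)) / (n1 + n2 - 2)
            self.s2_ = pooled
            self.df_residual_ = float(n1 + n2 - 2)
            se_factor = np.sqrt(1.0 / n1 + 1.0 / n2)
            self.n_case_, self.n_ref_ = n1, n2

        if self.d0 is None:
            self.d0_, self.s0_sq_ = fit_variance_prior(self.s2_, self.df_residual_)
        elif self.d0 == 0:
            self.d0_, self.s0_sq_ = 0.0, float(np.median(self.s2_[self.s2_ > 0])
                                               if (self.s2_ > 0).any() else 1.0)
        else:
            self.d0_ = float(self.d0)
            _, self.s0_sq_ = fit_variance_prior(self.s2_, self.df_residual_)

        s2_tilde = moderate_variances(self.s2_, self.df_residual_, self.d0_,
                                      self.s0_sq_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.t_ = self.log2fc_ / (np.sqrt(s2_tilde) * se_factor)
        self.t_ = np.where(np.isfinite(self.t_), self.t_, 0.0)
        self.s2_tilde_ = s2_tilde
        self.df_total_ = self.df_residual_ + self.d0_
        df_ref = self.df_total_ if np.isfinite(self.df_total_) else np.inf
        if np.isinf(df_ref):
            self.p_ = 2.0 * stats.norm.sf(np.abs(self.t_))
        else:
            self.p_ = 2.0 * stats.t.sf(np.abs(self.t_), df_ref)
        self.q_ = benjamini_hochberg(self.p_)
        self.is_deg_ = ((np.abs(self.log2fc_) >= np.log2(self.fold_threshold))
                        & (self.q_ < self.q_threshold))
        return self

    def results(self, feature_ids=None) -> pd.DataFrame:
        """Assemble the fitted per-feature results as a DEResult table."""
        n = len(self.log2fc_)
        idx = feature_ids if feature_ids is not None else np.arange(n)
        return pd.DataFrame({
            "gene_id": idx,
            "log2fc": self.log2fc_,
            "s2": self.s2_,
            "t_mod": self.t_,
            "df_total": self.df_total_,
            "p_value": self.p_,
            "fdr_q": self.q_,
            "direction": np.where(self.log2fc_ < 0, "down", "up"),
            "is_deg": self.is_deg_,
        })


def fit_moderated(expr: ExpressionMatrix, meta: pd.DataFrame, contrast: Contrast,
                  fold_threshold: float = 2.0, q_threshold: float = 0.05,
                  d0: float | None = None) -> pd.DataFrame:
    """Run the moderated test for one contrast; returns the DEResult table."""
    check_samples_match(expr, meta)
    meta = meta.set_index("sample_id").loc[expr.sample_ids].reset_index()
    in_case = meta["group"] == contrast.case_group
    in_ref = meta["group"] == contrast.reference_group
    if not in_case.any():
        raise ValidationError(f"contrast group {contrast.case_group!r} absent")
    if not in_ref.any():
        raise ValidationError(f"contrast group {contrast.reference_group!r} absent")
    keep = in_case | in_ref
    X = expr.values.T.to_numpy()[keep.to_numpy()]
    y = in_case[keep].astype(int).to_numpy()
    pairs = meta.loc[keep, "family_id"].to_numpy() if contrast.paired else None
    est = ModeratedTTest(fold_threshold=fold_threshold, q_threshold=q_threshold,
                         d0=d0).fit(X, y, pairs=pairs)
    res = est.results(feature_ids=expr.gene_ids)
    logger.info("contrast %s: %d genes, %d/%d samples, d0=%.3g, %d DEGs",
                contrast.name, expr.shape[0], est.n_case_, est.n_ref_,
                est.d0_, int(res["is_deg"].sum()))
    return res


def deg_summary(de: pd.DataFrame, locus_type: pd.Series) -> pd.DataFrame:
    """Per-locus-type counts of up/down DEGs with the up:down ratio."""
    de = de.set_index("gene_id")
    lt = locus_type.reindex(de.index)
    rows = []
    for cat in ("coding", "multiple_complex", "noncoding", "other"):
        sub = de[(lt == cat).to_numpy() & de["is_deg"].to_numpy()]
        up = int((sub["direction"] == "up").sum())
        down = int((sub["direction"] == "down").sum())
        rows.append({"locus_type": cat, "n_deg": up + down, "n_up": up,
                     "n_down": down,
                     "up_down_ratio": up / down if down else np.inf if up else np.nan})
    total = int(de["is_deg"].sum())
    rows.append({"locus_type": "total", "n_deg": total,
                 "n_up": int(sum(r["n_up"] for r in rows)),
                 "n_down": int(sum(r["n_down"] for r in rows)),
                 "up_down_ratio": np.nan})
    return pd.DataFrame(rows)


def volcano_table(de: pd.DataFrame) -> pd.DataFrame:
    """Projection of a DEResult onto volcano-plot coordinates."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(de["p_value"].to_numpy())
    return pd.DataFrame({"gene_id": de["gene_id"], "log2fc": de["log2fc"],
                         "neg_log10_p": neglog, "is_deg": de["is_deg"]})
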