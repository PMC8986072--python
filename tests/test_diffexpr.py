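import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomics.diffexpr import (ModeratedTTest, benjamini_hochberg, deg_summary,
                               fit_moderated, fit_variance_prior,
                               moderate_variances, trigamma_inverse,
                               volcano_table)
from triomics.io import Contrast, ExpressionMatrix, ValidationError
from triomics.simulate import SimulationConfig, null_config, simulate_study
from .conftest import make_de_frame, make_metadata


def brute_force_bh(p):
    """Step-up definition: q_i = min over p_(j) >= p_i of m*p_(j)/j, capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(m)
                      if p[order[j]] >= p[i] - 1e-15]
        q[i] = min(1.0, min(candidates))
    return q


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03], atol=1e-12)

    def test_constant_vector_fixed_point(self):
        q = benjamini_hochberg([0.2] * 5)
        assert np.allclose(q, 0.2, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(benjamini_hochberg(p), brute_force_bh(p),
                               atol=1e-12)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, np.nan])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.1, 1.2])


class TestVariancePrior:
    def test_trigamma_inverse_round_trip(self):
        from scipy.special import polygamma
        for y in (0.1, 1.0, 5.0, 40.0):
            assert abs(trigamma_inverse(float(polygamma(1, y))) - y) < 1e-6

    def test_prior_recovers_known_f_mixture(self):
        # s2 ~ s0^2 * F(d, d0): moment matching should land near (d0, s0^2)
        rng = np.random.default_rng(1)
        d, d0, s0_sq = 10, 8.0, 0.25
        s2 = s0_sq * (rng.chisquare(d, 20000) / d) / (rng.chisquare(d0, 20000) / d0)
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_sq) / s0_sq < 0.1

    def test_homoscedastic_data_gives_infinite_prior(self):
        rng = np.random.default_rng(2)
        s2 = np.full(100, 0.3) * rng.uniform(0.99, 1.01, 100)
        d0, s0 = fit_variance_prior(s2, 10)
        assert np.isinf(d0)
        assert abs(s0 - 0.3) < 0.01

    def test_all_zero_variances_error(self):
        with pytest.raises(ValidationError):
            fit_variance_prior(np.zeros(10), 5)


class TestModeratedTTest:
    def _data(self, seed=0, n_genes=300, n1=6, n2=6, het=True):
        rng = np.random.default_rng(seed)
        sd = rng.uniform(0.2, 1.2, n_genes) if het else np.full(n_genes, 0.5)
        X = rng.normal(7, 1, (n_genes, 1)) + rng.normal(0, 1, (n_genes, n1 + n2)) * sd[:, None]
        y = np.array([1] * n1 + [0] * n2)
        return X.T, y

    def test_identical_groups_null_identity(self):
        X, y = self._data()
        X2 = np.vstack([X[:6], X[:6]])  # reference duplicates the case arm
        est = ModeratedTTest().fit(X2, y)
        assert np.allclose(est.log2fc_, 0)
        assert not est.is_deg_.any()

    def test_d0_zero_equals_ordinary_pooled_t(self):
        X, y = self._data()
        est = ModeratedTTest(d0=0).fit(X, y)
        t_ref, p_ref = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=True)
        assert np.abs(est.t_ - t_ref).max() < 1e-10
        assert np.abs(est.p_ - p_ref).max() < 1e-10

    def test_paired_d0_zero_equals_paired_t(self):
        X, y = self._data()
        pairs = np.array([f"f{i}" for i in range(6)] * 2)
        est = ModeratedTTest(d0=0).fit(X, y, pairs=pairs)
        t_ref, p_ref = stats.ttest_rel(X[y == 1], X[y == 0])
        assert np.abs(est.t_ - t_ref).max() < 1e-10
        assert np.abs(est.p_ - p_ref).max() < 1e-10

    def test_large_d0_posterior_variance_approaches_prior(self):
        rng = np.random.default_rng(3)
        X = rng.normal(7, 0.1, (40, 8))   # small, tight variances
        y = np.array([1] * 4 + [0] * 4)
        est = ModeratedTTest(d0=1e6).fit(X.T, y)
        assert np.abs(est.s2_tilde_ - est.s0_sq_).max() < 1e-6

    def test_moderation_shrinks_toward_prior(self):
        X, y = self._data()
        est = ModeratedTTest().fit(X, y)
        raw, mod = est.s2_, est.s2_tilde_
        assert ((mod - est.s0_sq_) * (raw - est.s0_sq_) >= -1e-12).all()
        assert (np.abs(mod - est.s0_sq_) <= np.abs(raw - est.s0_sq_) + 1e-12).all()

    def test_matches_limma_ebayes(self, tmp_path):
        """Dual route: our moderated t against Bioconductor limma via Rscript."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        X, y = self._data(seed=4, n_genes=200)
        mat = X.T
        np.savetxt(tmp_path / "mat.tsv", mat, delimiter="\t")
        r_code = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{tmp_path}/mat.tsv", sep="\\t"))
        design <- cbind(Intercept=1, Case=c(rep(1,6), rep(0,6)))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,"Case"], p=fit$p.value[,"Case"],
                          d0=fit$df.prior, s02=fit$s2.prior)
        write.table(out, "{tmp_path}/out.tsv", sep="\\t", row.names=FALSE,
                    quote=FALSE)
        """
        (tmp_path / "limma.R").write_text(r_code)
        subprocess.run(["Rscript", str(tmp_path / "limma.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        est = ModeratedTTest().fit(X, y)
        assert abs(est.d0_ - ref["d0"][0]) < 1e-8
        assert abs(est.s0_sq_ - ref["s02"][0]) < 1e-10
        assert np.abs(est.t_ - ref["t"]).max() < 1e-10
        assert np.abs(est.p_ - ref["p"]).max() < 1e-10

    def test_monotone_in_gates(self):
        X, y = self._data(seed=5)
        X[:30, :6] += 2.0   # plant effects
        strict = ModeratedTTest(fold_threshold=2, q_threshold=0.05).fit(X, y)
        loose_fold = ModeratedTTest(fold_threshold=1.5, q_threshold=0.05).fit(X, y)
        loose_q = ModeratedTTest(fold_threshold=2, q_threshold=0.2).fit(X, y)
        assert loose_fold.is_deg_.sum() >= strict.is_deg_.sum()
        assert loose_q.is_deg_.sum() >= strict.is_deg_.sum()

    def test_empirical_fdr_controlled_with_planted_effects(self):
        # 10% true effects (log2fc = 2) at sigma = 0.3: observed FDR among
        # flagged genes stays below 0.05 plus 3 binomial SEs
        rng = np.random.default_rng(6)
        false_flags = total_flags = 0
        for _ in range(15):
            n_genes, n = 2000, 8
            X = rng.normal(7, 1, (n_genes, 1)) + rng.normal(0, 0.3, (n_genes, 2 * n))
            true = np.zeros(n_genes, bool)
            true[:200] = True
            X[true, :n] += 2.0
            y = np.array([1] * n + [0] * n)
            est = ModeratedTTest().fit(X.T, y)
            total_flags += est.is_deg_.sum()
            false_flags += (est.is_deg_ & ~true).sum()
        fdr = false_flags / max(total_flags, 1)
        assert fdr <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / max(total_flags, 1))

    def test_group_absent_raises(self, small_expr):
        meta = make_metadata(["HC"] * 6, [""] * 6)
        with pytest.raises(ValidationError, match="proband"):
            fit_moderated(small_expr, meta, Contrast("c", "proband", "HC"))

    def test_null_simulation_flags_almost_nothing(self):
        cfg = null_config(SimulationConfig(n_families=8, n_hc=8,
                                           n_genes=2000, seed=21))
        st = simulate_study(cfg)
        de = fit_moderated(st.expression, st.metadata,
                           Contrast("p_hc", "proband", "HC"))
        assert de["is_deg"].mean() <= 0.0005


class TestSummaries:
    def test_no_degs_all_zero(self):
        de = make_de_frame([f"g{i}" for i in range(5)], [False] * 5)
        lt = pd.Series(["coding"] * 5, index=de["gene_id"])
        tab = deg_summary(de, lt)
        assert (tab["n_deg"] == 0).all()

    def test_planted_ratio_and_conservation(self):
        genes = [f"g{i}" for i in range(50)]
        is_deg = [True] * 40 + [False] * 10
        fc = np.r_[np.full(10, 2.0), np.full(30, -2.0), np.full(10, 0.0)]
        de = make_de_frame(genes, is_deg, log2fc=fc)
        lt = pd.Series(["coding"] * 45 + ["noncoding"] * 5, index=genes)
        tab = deg_summary(de, lt).set_index("locus_type")
        assert tab.loc["coding", "n_up"] == 10
        assert tab.loc["coding", "n_down"] == 30
        assert tab.loc["coding", "up_down_ratio"] == pytest.approx(1 / 3)
        assert tab.loc["total", "n_deg"] == sum(is_deg)
        assert tab.drop("total")["n_deg"].sum() == tab.loc["total", "n_deg"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_volcano_is_pure_projection(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(20)]
        de = make_de_frame(genes, rng.random(20) < 0.3,
                           log2fc=rng.normal(0, 2, 20), p=rng.random(20))
        v = volcano_table(de)
        assert list(v["gene_id"]) == genes
        assert np.allclose(v["neg_log10_p"], -np.log10(de["p_value"]))
        assert (v["is_deg"] == de["is_deg"]).all()


def test_moderate_variances_interpolates():
    s2 = np.array([0.1, 0.5, 2.0])
    out = moderate_variances(s2, df=6, d0=3, s0_sq=0.5)
    expected = (3 * 0.5 + 6 * s2) / 9
    assert np.allclose(out, expected)
    assert np.allclose(moderate_variances(s2, 6, np.inf, 0.5), 0.5)
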