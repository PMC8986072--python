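# Methods

This note documents the statistical models implemented in `triomics`, the
generative model behind the synthetic study generator, the defaults and why
they were chosen, and the limits of what the synthetic validation can show.

## Study design assumed

A cohort of proband–father–mother trios plus unrelated healthy controls
(HC), profiled on a pre-normalized log2-scale gene-by-sample expression
matrix (one row per gene/transcript ID; probe-level processing such as RMA
is upstream and out of scope).  Each gene carries a locus-type annotation
(`coding`, `multiple_complex`, `noncoding`, `other`); `multiple_complex`
(a transcript reported in multiple locus types) is treated as protein-coding
wherever a coding filter applies.  Samples carry group, family ID, cellular
model, and clinical covariates (CFTR mutation class, pancreatic status,
*P. aeruginosa* infection status, sweat chloride in mmol/L, percent-predicted
FEV1), with missing values written as the literal `NA` and dropped pairwise
by every association.

## Moderated differential expression

For a contrast (case vs reference) the per-gene effect is the difference of
group means on the log2 scale (for paired contrasts, the mean of
within-family differences), and the residual variance `s2_g` is the pooled
within-group variance on `d_g = n1 + n2 - 2` degrees of freedom (paired:
variance of differences, `d_g = n_pairs - 1`).  Information is shared
across genes through a conjugate scaled-inverse-chi-square prior
`(d0, s0_sq)` estimated by matching the first two moments of `log s2_g` to
the log of a scaled F distribution: with
`e_g = log s2_g - digamma(d_g/2) + log(d_g/2)`,

    Var[e] = trigamma(d_g/2) + trigamma(d0/2)
    E[e]   = log s0_sq - digamma(d0/2) + log(d0/2)

the first equation is inverted for `d0` by a Newton iteration on the
trigamma function; when it has no positive root the prior is taken as
infinitely informative (`d0 = inf`, `s0_sq = mean(s2_g)`).  The posterior
variance is `s2~_g = (d0*s0_sq + d_g*s2_g)/(d0 + d_g)` and the moderated t
statistic is referred to a t distribution with `d_g + d0` degrees of
freedom.  This is the canonical moderated-t construction for microarray
data; the test suite verifies exact agreement (1e-10) with Bioconductor
limma's `lmFit`/`eBayes` on shared input, and that forcing `d0 = 0` recovers
the ordinary pooled-variance t exactly.

Significance gates: `|log2FC| >= log2(fold_threshold)` (default 2-fold,
i.e. one log2 unit) **and** BH-FDR `q < q_threshold` (default 0.05, strict
inequality).  Multi-group designs are analyzed as per-contrast two-group
tests (every reported DEG list is pairwise); a pooled multi-group F test is
deliberately not provided.  Contrasts are unadjusted for demographic
covariates.

## Trio set logic

Given two DE results on the same gene universe, the trio-shared set is the
intersection of their DEG sets, and proband-unique/parent-unique are the set
differences.  The cross-model input gene set is built in three logged steps:
(1) intersect the coding DEGs (locus type `coding` or `multiple_complex`;
configurable) of two proband-vs-HC contrasts from different cellular models;
(2) intersect with the parent-vs-HC DEGs; (3) keep genes whose fold-change
direction — `sign(log2FC)` only, not magnitude — agrees between the two
models.  All intermediate counts are reported rather than privileging one.
An empty result is a warning, not an error.

## Composition scores

Marker selection is gene-level: within each cell subset, all pairwise
Pearson correlations between candidate genes are computed across samples;
each candidate's statistic is the mean of its pairwise correlations, with a
p value from the Fisher z transform of that mean
(`z = atanh(r) * sqrt(n - 3)`, two-sided normal).  A candidate is kept iff
`mean r > 0.50` (strict) and `p < 0.01`.  A stricter `pairwise_all` mode
additionally requires every individual pairwise correlation to clear the
threshold.  Constant-expression candidates have undefined correlations and
are dropped with a warning.  The gene-level reading (rather than per-pair
testing) was chosen because selection acts on genes; it is recorded as a
configurable mode rather than hard-coded.

The raw composition score of sample `s` for subset `k` is the sum over
panel groups of the simple average of that group's selected markers' log2
expression; with a single panel group this is the plain marker mean.  Scores
are reported raw — they are relative abundance proxies comparable across
groups, not simplex-normalized cell fractions, and regression-style
deconvolution (CIBERSORT-like) is out of scope.  Subsets with no surviving
markers yield an explicit NA column plus a warning.

## Group comparisons and error control

Trio-vs-HC comparisons use the unpaired pooled-variance two-sided t test
(normality and equal variances assumed); within-trio comparisons pair on
family ID and drop incomplete pairs.  Within each score, the family of
comparisons is adjusted by Holm–Šidák
(`adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j+1)`, clipped at 1); the number
of scores is deliberately **not** adjusted for — scores are strongly
correlated and the within-score family is the unit of inference.  Degenerate
zero-variance comparisons return p = 1 (conservative) rather than NaN so
families stay intact.  `parent` is available as a pooled father+mother
pseudo-group; pooling is configuration, not hard-coded.

The growth-assay design uses Kruskal–Wallis with tie correction; when the
global test is significant at 0.05, Dunn's z for each group against the
control uses mean ranks with the tie-corrected variance and Bonferroni
multiplication by the number of control comparisons (the convention of
common GUI statistics packages for this design).

Clinical correlations are plain Pearson analyses on complete pairs of
proband samples (covariates are undefined for controls; the sample filter is
configurable) and are unadjusted for multiplicity by default, with an
explicit flag to apply Holm–Šidák — multiplicity behaviour is surfaced, not
hidden.

## Family-structure analyses

PCA standardizes each gene (zero mean, unit variance across samples;
zero-variance genes dropped with a warning) and decomposes the sample
configuration restricted to a chosen gene set.  Hierarchical clustering uses
1 − Pearson correlation over the gene set with average linkage — the common
microarray-heatmap convention; both are flags since the choice is not
canonical.  `family_adjacency` quantifies "participants cluster by family":
for every trio sample, an indicator of whether its cophenetic nearest
neighbour shares its family ID; the fraction has chance level
`(family size − 1)/(n − 1)` under exchangeability, which the τ = 0
simulation test verifies.

## Overlap enrichment

The enrichment statistic is the one-sided hypergeometric overlap test:
for a query of `n` genes from a universe of `N`, a collection set of size
`K` (after intersection with the universe) and overlap `k`, `p = P[X >= k]`,
with BH-FDR across the collection and ranking by (q, p, name).  This is a
reproducible offline equivalent of web "investigate/overlap" gene-set
queries; ranked running-sum GSEA with permutation nulls is out of scope.
The universe defaults to all genes on the expression matrix and is
configurable, since universe choice dominates overlap p values.  Gene IDs
are matched case-insensitively (collection symbols are conventionally
uppercase), preserving query spelling in outputs.

## Synthetic study generator

For sample `s` with subset weights `w_s ~ Dirichlet(alpha)`:

* marker gene `g` of subset `k`:
  `x_gs = b_g + a*log2(w_ks / wbar_k) + gamma_f(g,s)
          - delta_f * 1[k myeloid and s in a trio] + eps`,
  `eps ~ Normal(0, sigma^2)`, `wbar_k` the Dirichlet mean;
* background genes: `b_g + gamma + eps`; decoy candidates: `b_g + eps`;
* `gamma_{f,g} ~ Normal(0, tau^2)` is shared by all members of family `f`
  on a declared fraction of background genes (markers are kept free of
  `gamma` so composition scores have a clean planted target); HC samples are
  singleton pseudo-families, which also exercises pairing logic;
* per-family severity is two-level: half the families (balanced split) are
  severe with `delta_f = 1.3*delta`, half mild with `0.7*delta`; severity
  determines CFTR class (I/II/III vs IV), pancreatic status (PI vs PS) and
  the *P. aeruginosa* infection probability (0.75 vs 0.25);
* clinical covariates are linked to the *realized* per-sample myeloid
  signal deficit `delta_f - a*log2(w/wbar)` (not only the family draw):
  sweat chloride `= 100 + slope*deficit_macrophage + Normal(0,5)` for
  probands (uniform 10–40 mmol/L otherwise), FEV1
  `= 95 - slope*deficit_monocyte + Normal(0,5)` (around 95% predicted
  otherwise), slope 15 units per log2 unit.  Linking to the realized deficit
  makes Pearson sign recovery a well-posed target.

Mixture signal enters through the log-ratio of weights rather than linear
mixing, keeping the additive log2 model that the scoring stage assumes.

**Defaults** (all overridable): 14 trios + 18 HC (60 samples), 2000 genes,
10 subsets (5 lymphoid, 5 myeloid) × 20 markers + 3 decoy candidates each,
`a = 1`, `sigma = 0.3`, `tau = 0.6`, `delta = 0.8` log2 units, family-effect
genes = 30% of background, baselines `Normal(7, 1)`.  The Dirichlet
concentration is uniform `(8, ..., 8)`: every subset then has comparable
log-scale weight variability (sd(log2 w) ≈ 0.5), so pairwise marker
correlations clear the 0.50 selection gate with margin in all subsets while
group effects of 0.8 log2 units remain detectable at n = 14/18 — with
strongly unequal concentrations, rare subsets have log-weight variance so
large that a fixed suppression becomes undetectable, and abundant subsets
have so little that their markers fail selection.  The generator therefore
emulates the *statistical* structure of a mixture study, not literal PBMC
proportions.  A separate `layout_seed` lets several cellular models share
one gene universe with independent cohorts, which the cross-model input
gene set requires.

## What the synthetic validation does and does not show

Passing tests demonstrate that every stage recovers structure it is designed
for, at realistic sizes, with calibrated error control (null DEG fraction,
family-wise error of comparison families, chance-level family adjacency at
τ = 0).  They do not certify behaviour on real arrays: the generator has no
probe effects, batch structure, correlated gene-gene backbone beyond the
family effect, heavy-tailed noise, or compositional coupling between
suppression and the weights; counts reported by a real study (thousands of
DEGs, specific overlap sizes) depend on its data and are not reproduced
here.  Degenerate inputs are handled explicitly: zero-variance genes/samples
are dropped or named in errors, empty set-logic intermediates warn rather
than fail, and all randomness flows from a single integer seed
(byte-identical pipeline outputs across runs are asserted in the tests).
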