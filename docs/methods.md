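# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices, and the known limitations of `strataprot`. The package
analyzes tumour proteomes of epithelial ovarian carcinoma cohorts stratified
by histotype (HGSC, EC, MC, CCC) and FIGO stage group (early = I/II,
late = III/IV); every quantity discussed here is computed by the package's
tests or by `scripts/acceptance.py`.

## Differential abundance: empirical-Bayes moderated t-tests

Each contrast (one histotype vs the rest within a stage group, histotype
pairs within a stage group, early vs late within a histotype — 24 contrasts
in the full plan) is a per-protein two-group comparison on log2 intensities.
Missing cells are handled by complete-case analysis with degrees-of-freedom
reduction; no imputation is performed anywhere in the testing path. A protein
with fewer than two present values on either side is reported *untestable*
rather than dropped.

For protein *g* with pooled residual variance `s_g^2` on `d_g` degrees of
freedom, a scaled inverse-chi-square prior `sigma_g^2 ~ s0^2 * d0 / chi2(d0)`
is fitted across proteins by the method of moments on `log s_g^2`: the
bias-corrected values `e_g = log s_g^2 - digamma(d_g/2) + log(d_g/2)` have
model mean `log s0^2 + digamma(d0/2) - log(d0/2)` and excess variance
`trigamma(d0/2)` over the chi-square sampling term `trigamma(d_g/2)`; `d0`
solves the trigamma equation by Newton iteration and is infinite when the
observed dispersion does not exceed the sampling term. The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

yields the moderated statistic `t_g = log2FC_g / (s~_g * sqrt(1/n_t + 1/n_r))`
on `d_g + d0` degrees of freedom (standard normal when `d0 = inf`). At
`d0 = 0` the statistic reduces exactly to the ordinary pooled two-sample t.
The test suite pins the implementation to an independent reference
implementation of the same formulas (limma's `eBayes`, run once in R) at
1e-10 on a frozen fixture, and verifies prior recovery on variances simulated
from a known prior (d0 = 4, s0² = 1, 5 000 proteins: d0 recovered within
[2.5, 6], s0² within 15 %).

The prior is fitted **per comparison**: every contrast restricts to a
different stage stratum with different samples and missingness, so the
variance population differs between contrasts.

Multiple testing uses Benjamini–Hochberg step-up per comparison. A protein is
called a DAP at FDR < 0.05 and linear fold change > 1.5 (i.e.
|log2FC| > log2 1.5 ≈ 0.585). The fold-change threshold is interpreted on the
linear scale by default — the common convention — with a `fc_scale="log2"`
switch preserving the alternative reading.

## Biomarker panels: elastic net + two-phase greedy SVM

Candidates for a contrast are its DAPs. Pre-selection fits an elastic-net
logistic regression (l1 ratio 0.5, saga solver) over a log-spaced grid of 20
penalties, scored by five-fold cross-validated ROC-AUC on standardized
columns, and keeps the proteins with non-zero coefficients at the chosen
penalty. **Penalty choice:** among penalties whose mean CV-AUC lies within
one standard error of the best, the strongest penalty wins. A plain argmax is
degenerate under the null — the fully regularized model scores exactly 0.5
while overfitted models fluctuate above it, so the argmax systematically
lands on an overfit penalty and selects dense noise; the one-SE preference
restores sparse null behaviour (median selected-set size ≤ 2 on 60-sample
pure-noise tasks) without giving up the AUC-optimal penalty when real signal
separates the grid.

Panel growth fixes one stratified 80/20 split (by seed, before any
selection), trains an RBF-kernel SVM (cost 1, bandwidth from the median
pairwise-distance heuristic, columns standardized on the training split) and
scores candidates by held-out AUC:

* **Phase 1** seeds the panel with the best single candidate and repeatedly
  adds the best remaining candidate while the held-out AUC strictly improves.
* **Phase 2** keeps adding the best remaining candidate while the resulting
  AUC stays within one percent unit of the phase-1 maximum, up to a cap of 5
  proteins (panel sizes that remain clinically practical). A phase-1 panel
  that already classifies the held-out samples perfectly is final: padding a
  perfect panel can only dilute it.

Exact AUC ties break toward the protein with the smaller DA q-value, then
lexicographically — deterministic and recorded in the trajectory. Selection
against a single fixed split is the published procedure and is optimistic at
small group sizes; the test suite bounds that optimism (pure-noise panels on
100-sample tasks stay within a wide null band) and checks the greedy result
against exhaustive best-subset search under the identical split (within 0.05
AUC on datasets with a dominating planted signal — the regime in which a
greedy forward search is expected to match exhaustive search).

The sample-size simulation retrains the *fixed* panel on stratified
subsamples of n ∈ {5, 10, 15, 20, 25, 30, 40, 50, 60} patients (class ratio
preserved, at least two per class), with a stratified 70/30 split and 200
repetitions per size, reporting mean and SD of the held-out AUC and flagging
sizes reaching mean AUC ≥ 0.95. The panel is never re-selected inside the
loop.

## Prognostic screening: LASSO-guided Cox models with bootstrap validation

For each endpoint (overall survival; disease-specific survival, treating
other-cause death as censoring) within each (histotype, stage-group) stratum:

1. A LASSO-penalized Cox model over all adequately-present proteins
   (standardized, mean-imputed for the multivariate step only) plus the age
   and sub-stage covariates provides feature selection. The penalty path
   comes from a coxnet fit; the penalty is chosen by K-fold cross-validated
   held-out partial log-likelihood (the deviance criterion). Within a
   stage-group stratum the informative stage covariate is the binary
   sub-stage (I vs II, or III vs IV); the coarse group is constant there.
2. Every adequately-present protein is then fitted in its own Cox
   proportional-hazards model — abundance median-dichotomized within the
   stratum (high vs low; a continuous-coding switch exists) — adjusted for
   whichever covariates the LASSO retained. Ties are handled by Efron's
   method. The per-protein Wald p-values form **one BH family per screen**.
   Restricting the family to the LASSO-selected proteins (`restrict_to_lasso`
   switch) reproduces a published variant but inherits post-selection
   optimism — the same data pick the family and supply the p-values — which
   measurably inflates null calls, so it is opt-in.
3. Robustness: the model is refitted on B = 1000 bootstrap resamples of
   patients (same n, with replacement; non-converged or degenerate resamples
   skipped and counted, with a reliability flag below 50 % convergence) and
   the abundance-coefficient Wald p-values are averaged into a bootstrap
   p-value.
4. A protein is called prognostic when FDR < 0.05, bootstrap p < 0.2 and the
   95 % Wald CI of the hazard ratio excludes 1 (HR < 1 decreased, HR > 1
   increased risk of death).

The per-protein fits use the package's compact Newton–Raphson partial-
likelihood solver (Efron ties, step-halving, Wald inference): a bootstrapped
proteome screen performs tens of thousands of 1–3-parameter fits, and a
general-purpose survival package spends more time building result objects
than solving them. The solver is cross-checked against lifelines to its
convergence tolerance in the test suite; the C-index of the full linear
predictor is verified against exhaustive pair counting.

### Null behaviour of the bootstrap p-value

The bootstrap-averaged Wald p is **not** mean-0.5 under the null. For a null
coefficient with estimate `b ~ N(0, se²)`, a resample estimate is
approximately `b* ~ N(b, se²)`, so the resampled Wald z is marginally
`N(0, sqrt 2)` and

    E[mean bootstrap p] = E[2 Φ(−|z*|)] = P(F(1,1) ≥ 2)
                        = 1 − (2/π) arctan √2 ≈ 0.392.

The package measures 0.378 over 40 simulated null datasets (n = 100,
B = 200), and an independent R `survival::coxph` bootstrap gives 0.42 over a
subset of the same datasets — both consistent with the theory and below the
naive "uniform p-value mean" of 0.5. Consequence: the 0.2 significance
threshold on the bootstrap p is roughly twice as permissive as it would be
for a uniform null statistic, and any check that expects the null mean to be
0.5 will reject a correct implementation. One acceptance-level check in this
package asserts the naive band and is expected to fail; it is kept as stated
rather than silently recalibrated.

Kaplan–Meier summaries dichotomize at the stratum median and report the
product-limit curve per group with a global log-rank test (verified against
the hand-computed O−E/V statistic on a small fixture).

## Over-representation analysis

Prognostic hit sets (per stratum, endpoint and risk direction) are tested
against GO biological-process terms with the hypergeometric upper tail
p = P(X ≥ k), X ~ Hypergeom(N, K, n), BH-adjusted across tested terms, and
the five most significant terms passing FDR < 0.05 are reported. The
**universe is the presence-filtered measured proteome** — the proteins that
could have been hits — rather than a whole-annotation universe; a switch
reproduces the whole-annotation behaviour of common tools. Term-size bounds
default to [3, 500]. No GO-graph propagation is performed; the annotation is
taken as given (a pre-propagated table can be supplied). Exactness is pinned
to analytic tail sums and to brute-force enumeration over all hit-set
configurations on small universes.

## The synthetic cohort generator

The generator emulates the data model the analysis assumes, with recorded
ground truth:

* **Cohort shape.** The full shape reproduces a 244-patient cohort: HGSC
  122 (47 early / 75 late), EC 42 (21/21), MC 35 (10/25), CCC 45 (14/31);
  early 92 / late 152. The per-cell split is derived from the published
  totals, the 50 % early share of EC, and the early MC/CCC cell sizes. A
  desk variant scales each cell by 0.25 with a floor of 6 (70 patients) for
  fast exercises. Sub-stages are drawn I:II = 60:40 within early and
  III:IV = 70:30 within late; ages are N(60, 10²) truncated to [30, 90].
* **Abundances.** Protein *p* in sample *i* has log2 quantity
  `m_p + shift_p(i) + sd_p · N(0,1)` with baselines m_p ~ U(18, 28) (the
  scale of MS2 intensities) and sd_p ~ U(0.3, 1.2); planted group effects add
  a constant log2 shift in a (histotype, stage-group) cell. Raw-scale output
  is `2^x`.
* **Missingness** is missing-not-at-random: a cell is missing with
  probability decaying logistically in its log2 intensity around the
  protein's `detection_quantile` (default 0.05) baseline quantile, with
  softness 0.25·sd_p. Lowering the quantile never increases missingness under
  the same seed (the uniform draws are fixed before thresholding).
  A consequence worth stating: a downward planted shift pushes values into
  the detection limit, so its *realized* group difference is attenuated —
  a −1.5 sd shift realizes as ≈ −1.0 observed under the default quantile.
  Recovery tests that assert sensitivity at a stated effect size therefore
  generate without the detection limit; the attenuation itself is a property
  of the data process that the complete-case tests inherit from real DIA data.
* **Survival** is exponential proportional hazards: baseline rate 1/2000 per
  day (null median ≈ 3.8 years, typical of a mixed-histotype cohort), linear
  predictor = planted per-protein log-hazard effects on standardized log2
  abundance + 0.02·(age − 60) + 0.7·1[late stage]; independent exponential
  censoring calibrated to a marginal censoring probability (default 0.3)
  plus a 10-year administrative cutoff. Disease-specific death is a Bernoulli
  (0.85) mark on deaths, so `dss_event = 1` implies `os_event = 1`.
* **Determinism.** One `numpy` Generator per cohort, with a documented draw
  order (samples, protein baselines, abundance noise, missingness uniforms,
  survival draws); new features must append draws, never reorder them.

What the generator does **not** model: peptide-level structure, batch
effects, correlated protein modules, non-proportional hazards, and
informative censoring. Passing recovery tests therefore demonstrates that the
statistical machinery is correct and calibrated under the assumed model, not
that the model captures every feature of real cohorts.

## Numerical and design choices

* Trigamma inversion by Newton iteration from limma's starting point;
  variances of exactly zero are excluded from the log-moment fit (nudged to
  1 % of the smallest positive) and identical variances return the common
  value as s0² with d0 = ∞.
* BH step-up implemented directly (`q = cummin(m·p(j)/j)` from the largest
  rank), validated against statsmodels.
* The Newton Cox solver declares non-estimability (monotone likelihood) at
  |beta| > 250 or SE > 1e3 or a singular information matrix; step-halving
  keeps the partial likelihood monotone.
* Bootstrap p-values are computed for every fitted protein when a screen is
  small, otherwise only for FDR-passing proteins — final calls are identical
  because the composite rule requires both conditions; the pipeline defaults
  to the FDR-passers-only route.
* Stage seeds derive from one global seed and the stage name
  (`seed·1000003 + crc32(name) mod 2^31`), so stages rerun in isolation
  reproduce their stream.
* Problem sizes in the test suite and acceptance script (desk-shaped cohorts,
  40–150 proteins, B = 200, 200 repetitions where a mean/SD is the target)
  are chosen so the full recovery battery runs in minutes while keeping every
  Monte-Carlo band at ≥ 2.5 sigma of headroom.

## Limitations

* The panel AUCs share the published procedure's single-split optimism; the
  sample-size curves are the in-package quantification of it.
* Median dichotomization discards within-group abundance variation; the
  continuous coding switch is provided but changes the estimand.
* DSS treats other-cause death as independent censoring (no competing-risks
  model), matching the analysis it mirrors.
* The enrichment step tests the annotation as given; without GO-graph
  propagation, term p-values are not comparable to DAG-aware tools
  term-by-term.
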