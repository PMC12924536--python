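# strataprot

Histotype- and stage-stratified analysis of tumour proteomes — built for
data-independent-acquisition (DIA) protein quantity matrices from epithelial
ovarian carcinoma cohorts, where the four main histotypes (high-grade serous
HGSC, endometrioid EC, mucinous MC, clear-cell CCC) and the early (FIGO I/II)
vs late (III/IV) stage groups need separate answers to three questions:

1. **Which proteins distinguish a histotype at a given stage?**
   Empirical-Bayes moderated t-tests per contrast (one-vs-rest, all pairs,
   early-vs-late within histotype): per-protein pooled variances `s_g²` are
   shrunk toward a moment-fitted prior (d₀, s₀²),

   &nbsp;&nbsp;&nbsp;&nbsp;`s̃_g² = (d₀·s₀² + d_g·s_g²)/(d₀ + d_g)`,&nbsp;&nbsp;
   `t_g = log2FC_g / (s̃_g·√(1/n_t + 1/n_r))` on `d_g + d₀` df,

   with Benjamini–Hochberg correction; a differentially abundant protein
   (DAP) passes FDR < 0.05 and linear fold change > 1.5.
2. **Which small panels of DAPs classify the histotype?** Elastic-net
   (l1 ratio 0.5) pre-selection under five-fold cross-validated AUC, then a
   two-phase greedy RBF-SVM forward selection against a fixed stratified
   80/20 split — grow while the held-out AUC strictly improves, then pad
   within one percent unit of the maximum up to 5 proteins — plus a
   sample-size simulation (200 stratified 70/30 resamples per size,
   n = 5…60) that asks how many patients a fixed panel needs for stable
   AUC ≥ 0.95.
3. **Which proteins carry prognosis?** Per stratum and endpoint (overall /
   disease-specific survival), median-dichotomized Cox proportional-hazards
   models adjusted for LASSO-retained age/sub-stage covariates, BH-corrected
   Wald tests, a bootstrap p-value (mean Wald p over 1000 patient
   resamples), and the composite call FDR < 0.05 ∧ bootstrap p < 0.2 ∧
   95 % CI excluding HR = 1; GO biological-process over-representation
   (hypergeometric upper tail against the measured universe) summarizes the
   prognostic hit sets.

A synthetic-cohort generator with recorded ground truth (log-normal
intensities, planted fold changes, intensity-dependent missingness, an
exponential proportional-hazards survival model with planted protein and
covariate effects) reproduces the statistical shape of a 244-patient cohort
(HGSC 122, EC 42, MC 35, CCC 45; early 92 / late 152), so every stage of the
pipeline has a recovery test without external data. `docs/methods.md` has the
full model descriptions and numerical choices.

## Worked example

```python
import numpy as np
from strataprot import (desk_shape, generate_cohort, filter_by_group_presence,
                        log2_transform, run_comparison, build_panel)
from strataprot.synthetic_data import standard_planted_effects, SurvivalConfig
from strataprot.comparisons import one_vs_rest

da_eff, hz_eff = standard_planted_effects(120)
cfg = desk_shape(n_proteins=120, seed=42, planted_da=da_eff,
                 survival=SurvivalConfig(planted=hz_eff))
matrix, metadata, truth = generate_cohort(cfg)

filtered, report = filter_by_group_presence(matrix, metadata)   # >=70% in some histotype
log2m = log2_transform(filtered)

spec = one_vs_rest("MC", "early")
da = run_comparison(log2m, metadata, spec)
print(da[da["call"].isin(["up", "down"])][["protein_id", "log2fc", "q", "call"]])

panel = build_panel(log2m, metadata, spec, da, seed=0)
print(panel.selected, panel.auc, panel.sensitivity, panel.specificity)
```

prints

```
protein_id   log2fc            q call
    P00013 1.908652 6.940369e-09   up
    P00088 0.806299 3.172588e-02   up
['P00013']  held-out AUC=1.00 sens=1.00 spec=1.00
```

Reading the numbers: the generator planted a +2.0 log2-unit shift on protein
`P00013` in early-stage MC; the moderated test recovers it (observed
log2FC 1.91, q ≈ 7e-9) and the greedy SVM needs only that single protein to
classify the held-out samples perfectly. The planted +1.5 companion effect is
missed at this desk-scale cell size (6 early-MC patients), the planted −2.0
effect is attenuated by the detection limit (down-shifted values fall below
it and go missing), and `P00088` is a borderline false call at q = 0.03 —
small-stratum behaviour the full-size cohort shape does not share.

The same stages run from the shell:

```bash
strataprot simulate --out-dir sim --n-proteins 120 --seed 42
strataprot preprocess --matrix sim/matrix_raw.tsv --metadata sim/metadata.tsv --out pre
strataprot da --matrix pre/matrix_log2_filtered.tsv --metadata sim/metadata.tsv --out da
strataprot panels --matrix pre/matrix_log2_filtered.tsv --metadata sim/metadata.tsv \
    --da-dir da --comparison MC_early_vs_rest --out panels
strataprot run-all --out run   # whole pipeline, one seed, manifest.json
```

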