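# metapanel

Discriminant metabolite-panel discovery and longitudinal evaluation for
two-cohort metabolomics studies.

`metapanel` implements a complete analysis pipeline for studies that
compare a treated cohort against controls on a wide relative-abundance
table (samples × metabolites) and then follow the treated cohort over an
intervention.  The motivating design is a fecal-metabolomics study of
children with Autism Spectrum Disorder and GI symptoms (ASD, n = 18,
treated with Microbiota Transfer Therapy and sampled at weeks 0, 3, 10
and 18) versus typically developing controls (TD, n = 20, week 0 only),
with 669 metabolites measured.  Because participant-level data for such
studies are typically not deposited, the package includes a synthetic
study generator with planted ground truth so every stage is testable.

## Method

1. **Preprocessing** — missing (below-detection) cells are imputed as
   `min_observed/√2`; a metabolite is kept only if at least
   `floor(0.4·N)` of its N week-0 measurements are strictly above its
   detection limit (the minimum recorded value; 15 measurements at
   N = 38); every metabolite is scaled so its TD week-0 median is 1.0.
2. **Univariate screening** — per-metabolite orientation-free AUROC
   (rank-based, ties ½) for ASD vs TD at week 0; metabolites with
   AUROC > 0.6 become panel candidates.  Week 0 vs week 18 change is
   tested with a paired t-test or Wilcoxon signed-rank test, routed by
   Anderson–Darling normality at both time points, with a leave-n-out
   (n = 1, 2, 3) non-significance proportion as a stability statistic.
3. **Panel search** — for every 2-, 3- and 4-subset of the candidates a
   two-class Fisher discriminant is fitted: W ∝ S_W⁻¹(x̄_ASD − x̄_TD)
   maximizes J(W) = (WᵀS_BW)/(WᵀS_WW) with class-size-weighted scatter
   matrices.  Subsets are ranked by the empirical AUROC of their
   discriminant scores; the top 1000 four-metabolite panels are augmented
   by each remaining candidate to form five-metabolite panels.
4. **Cross-validation** — leave-one-out: each fold refits the
   discriminant and the Gaussian-KDE density of the ASD scores, places
   the threshold at the β-quantile of that density
   (β ∈ {0.01, 0.05, 0.1, 0.2}) and classifies the held-out sample
   (score ≥ threshold → ASD); panels are selected by balanced accuracy,
   preserving ties.
5. **Longitudinal evaluation** — with the panel and week-0 threshold
   frozen, each follow-up week's ASD scores are re-smoothed and the
   Type II error is that week's density mass below the threshold; a
   per-sample deviation score Σ_m |x_m − median_TD(m)|/σ_TD(m) tracks raw
   convergence toward the controls.

## Worked example

```python
from metapanel import (SimulationConfig, generate_study, preprocess,
                       screen_candidates, search_pipeline)

dataset, truth = generate_study(SimulationConfig(seed=1, n_metabolites=200))
scaled, stats, report = preprocess(dataset)
print(report.qualifying_count)                 # 15  (floor(0.4 * 38))
candidates = [r.metabolite for r in screen_candidates(scaled)][:40]
out = search_pipeline(scaled, candidates, ks=(2, 3, 4))
best = out["best"][0]
print(best.metabolites)
# ('M0072', 'M0135', 'M0152', 'M0189', 'M0192')
print(best.rates[0.05])
# {'tpr': 1.0, 'tnr': 1.0}
```

The qualifying count 15 is the detection-limit retention rule at the
38-sample design size; the selected panel contains three of the twenty
planted discriminating metabolites for this seed, and its leave-one-out
sensitivity/specificity at β = 0.05 are both 1.0 because the planted
effect cleanly separates the cohorts.

The same pipeline runs from the shell:

```bash
metapanel run --config config.yaml --seed 1 --out results/
```

writing the preprocessing report, univariate table, search rankings,
cross-validation table, trajectory report and a reproducibility manifest.

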