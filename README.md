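# hospitalome

Tools for longitudinal "hospitalome" datasets: dense time series of gut
microbiota compositions (16S ASV counts, qPCR total bacterial load) joined to
the clinical record — drug administrations, vitals, blood counts, blood
cultures — of hospitalized allogeneic hematopoietic cell transplantation
(allo-HCT) patients, on a deidentified integer day axis anchored to the day of
transplant.

The package is aimed at microbiome researchers who want to work with this
family of CSV deposits (or realistic synthetic stand-ins) and run two
quantitative analyses on them:

1. **Antibiotic impact on microbial growth rates.** Antibiotics are assumed to
   act additively on the exponential growth rate of each taxon *k*:

       d log N_k(t) / dt = g_k + Σ_j ε_{k,j} u_j(t)

   where N_k is absolute abundance (relative abundance × qPCR 16S load),
   g_k the drug-free growth rate, u_j(t) ∈ {0,1} the daily presence of
   antibiotic group *j* (grouped by antibacterial drug category, split by
   oral/intravenous route), and ε_{k,j} the susceptibility (1/day; negative =
   inhibition). Integrating between two consecutive stool samples of a pair
   *p* gives a linear model in the day gap Δt_p and the per-group exposure
   day-counts C_{p,j}; stacking all pairs (gap ≤ 3 days, qPCR at both
   endpoints, zero abundances discarded) yields one ridge regression per
   taxon,

       X̂_k = argmin ‖Y_k − D_k X_k‖² + λ‖X_k‖² ,

   with λ chosen by 3-fold cross-validation repeated over 10 random row
   partitions.

2. **Bloodstream-infection risk after intestinal domination.** Domination —
   a genus exceeding a relative-abundance threshold (30% classically) in
   stool — enters a Cox proportional-hazards model as an absorbing
   time-dependent covariate on counting-process rows (start, stop] restricted
   to days −15…+35 around HCT, with Efron tie handling and a Wald CI for the
   hazard ratio of a genus-matched positive blood culture.

A synthetic cohort generator runs the same forward model with known ground
truth and writes the exact deposit CSV layout, so every stage is testable
end-to-end without any download.

## Worked example

```python
from hospitalome import (SimConfig, generate_cohort,
                         AntibioticImpactModel, DominationRiskModel)

cohort, truth = generate_cohort(SimConfig(n_patients=300, seed=11))
risk = DominationRiskModel(cohort, "Enterococcus", threshold=0.30).fit()
print(risk.summary())
```

prints

```
Domination -> BSI risk: genus Enterococcus, threshold 0.3, window (-15, 35)
  HR 4.78 [2.21-10.36] 95% CI, p=7.19e-05 (beta=1.5650, se=0.3942; 32 events, 127 dominated of 300 patients)
```

i.e. on this simulated cohort (generated with a true domination hazard ratio
of 4), patients whose stool became dominated by *Enterococcus* had a 4.8-fold
(95% CI 2.2–10.4) higher daily hazard of an enterococcal bloodstream
infection; the Wald interval covers the simulated truth. The antibiotic-impact
side works the same way:

```python
res = AntibioticImpactModel(cohort).fit()
print(res.summary())            # taxa x (growth rate + per-group, per-route effects)
res.susceptibilities("oral")    # just the orally administered groups
```

The coefficient table's `growth_rate` column is g_k in 1/day and each
`<group> [<route>]` column is ε̂_{k,j}; on a 100-patient synthetic cohort the
fitted effects (e.g. `penicillins [intravenous]` = −0.88/day for ASV_0003
against a simulated −0.87/day) track the ground truth closely.

Loading a real deposit directory works the same way — `load_cohort(dir)`
validates the nine tables and the models accept the result directly.

A command-line umbrella covers the same ground:

```bash
hospitalome simulate --out cohort/ --seed 4 --n-patients 50
hospitalome validate --cohort cohort/
hospitalome timeline --cohort cohort/ --patient syn0001 --window -5:21 --out timeline.png
hospitalome embed    --cohort cohort/ --seed 1 --out map.png
hospitalome infer-abx --cohort cohort/ --out coefficients.csv
hospitalome bsi-risk  --cohort cohort/ --genus Enterococcus --out risk.csv
```

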