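# Methods

## Equilibrium binding model

Circulating 25OHD partitions between VDBP, albumin and a free pool. With
molar concentrations and association constants `K_DBP`, `K_alb`, the
default ("linear", binder-total) calculation is

```
D     = 1 + K_alb·[Alb] + K_DBP·[VDBP]
free  = total / D
frac  = { VDBP: K_DBP·[VDBP]/D,  albumin: K_alb·[Alb]/D,  free: 1/D }
bioavailable = free · (1 + K_alb·[Alb])
```

This treats the *total* binder concentrations as free binder — valid when
ligand is scarce relative to binder, which holds for physiologic serum
(25OHD ~50 nM vs VDBP ~4 µM). The exact solver
(`free_25ohd_exact`) instead solves the full mass-action balance

```
total = F·(1 + K_DBP·P_DBP/(1+K_DBP·F) + K_alb·P_alb/(1+K_alb·F))
```

for the free concentration `F` by bisection on `[0, total]` (relative
tolerance 1e-10, deterministic; the mass balance is strictly increasing in
`F`, so the bracket always holds). Binder depletion only lowers the free
binder pool, so `free_exact >= free_linear` everywhere. The first-order
relative gap is approximately (VDBP-bound share) × (ligand/binder), i.e.
~0.87 × total_molar/VDBP_molar at typical physiology: ~0.6 % at the
cohort-mean inputs, but above 2 % once total 25OHD exceeds ~2.3 % of VDBP
on the molar scale (e.g. 60 ng/mL total against 100 µg/mL VDBP gives a
~5.7 % gap). The linear form is the pipeline default because it is the
calculation tradition the clinical literature uses; the exact solver is an
opt-in mode (`binding.mode: exact`) and the validation oracle.

### Constants

All affinities and molar masses are configuration, not code:

| parameter | default | unit | note |
|---|---|---|---|
| `k_dbp_constant` | 0.7×10⁹ | M⁻¹ | genotype-constant VDBP affinity |
| `allele_k_dbp` Gc1f / Gc1s / Gc2 | 1.12 / 0.60 / 0.36 ×10⁹ | M⁻¹ | genotype-specific scheme; a diplotype uses the mean of its two alleles |
| `k_alb` | 6×10⁵ | M⁻¹ | albumin affinity |
| `mw_25ohd` | 400.64 | g/mol | |
| `mw_vdbp` | 58 000 | g/mol | absolute free levels scale with this choice |
| `mw_albumin` | 66 500 | g/mol | |

Reported units mirror clinical convention: free in pg/mL, total and
bioavailable in ng/mL (1 ng/mL = 1000 pg/mL).

## Derived indices

* **VMR** = 100 × 24,25(OH)₂D₃ / total 25OHD; undefined (missing, with a
  warning) at total = 0.
* **Deficiency**: total < 20 ng/mL, strict inequality.
* **BMI category**: percentile < 85 normal, 85–95 overweight, ≥ 95 obese;
  when only a BMI Z-score is available the percentile is the normal CDF of
  the Z.
* **DRI adequacy**: vitamin D 200 IU/day ≤ 11 y, 400 IU/day 12–18 y;
  calcium 700 (6–8 y), 800 (9–11 y), 1000/900 boys/girls (12–14 y). Age is
  floored to whole years, so ages in (11, 12) fall in the ≤ 11 band. Ages
  below 6 or above 14 are outside the calcium bands and map to the nearest
  band with a logged warning.
* **Regular activity**: ≥ 60 min/day on ≥ 3 days/week.
* **DXA Z-scores**: (measured − age/sex reference mean)/reference SD,
  linear interpolation in age. **BMD_TBLH** = Σ BMC / Σ area over trunk +
  upper + lower limbs (head excluded by construction).
* Missing inputs propagate to the affected outputs only; there is no
  imputation, and every statistical stage is complete-case on the columns
  it uses, reporting its n.

### Reference table

The packaged `reference_synthetic.csv` is a *synthetic* normative table
(ages 5–13.5 y, both sexes, smooth mildly convex growth trends with
constant CVs). Real normative tables are licensed publications; any CSV
with the same schema can be swapped in (`reference_table` config key or
`--reference`). Z-scores computed against the synthetic reference are
internally consistent (the generator inverts the same table) but are not
population-calibrated.

## Synthetic cohort generator

The generator emulates the structure of a cross-sectional pediatric cohort
(n = 146 by default, 75 boys / 71 girls, 79 summer / 67 winter, 28.8 %
pubertal, six Gc diplotypes at frequencies 46/29/29/15/13/14 of 146).

* **Total 25OHD** is log-normal. Winter, puberty and overweight/obese
  status act additively on the log scale; each effect is the log-ratio of
  its two stratum-mean targets (summer 22.7 / winter 16.3; prepubertal
  20.9 / pubertal 17.1; normal-weight 21.1 / overweight-obese 15.9 ng/mL),
  and the intercept is set so the summer stratum mean is exact given
  independent indicators. Residual log-SD 0.28. The published stratum
  means are identified by the *category* contrast, so the weight effect is
  keyed to the overweight/obese indicator rather than continuous BMI-Z.
* **24,25(OH)₂D₃** = total × VMR/100 with VMR drawn independently per
  subject, N(5.6, 2.0) truncated at 0 — encoding the observed lack of VMR
  association with clinical factors.
* **iPTH** ~ N(22.8, 10.6) with a negative loading on total sized for
  r ≈ −0.35.
* **Measured free 25OHD** = 0.55 × calculated constant-scheme free + noise,
  encoding that direct immunoassay reads systematically lower than the
  calculation; the noise SD is chosen at run time so corr(measured, total)
  ≈ 0.655. Hitting that correlation with the 0.55 attenuation implies a
  marginal SD (~1.9 pg/mL) somewhat above the observed 1.3; the
  correlation, being the validated property, takes priority.
* **VDBP** ~ N(226.5, 37.8) µg/mL with a −30 µg/mL shift for Gc2/Gc2 (the
  base mean is raised so the cohort mean stays on target); albumin
  ~ N(4.3, 0.25) g/dL.
* **Bone Z-scores** are linear in total 25OHD (slope +0.030 per ng/mL for
  BMC_TB in normal-weight children, −0.030 in overweight/obese; smaller
  slopes for the BMD outcomes), with FM_Z (+0.15) and LM_Z (+0.35)
  loadings, small age and sex terms, and Gaussian residuals (SD 0.61,
  sized for adjusted R² ≈ 0.6 on BMC_TB_Z). Raw DXA values are obtained by
  inverting the reference table, and the regional BMC/area split is
  constructed to reproduce the generated BMD_TBLH exactly.
* **Missingness** is applied at the study's per-variable rates (intakes
  32/146 and 40/146, activity/daylight 30/146, chemistry 3/146).
* One `numpy` Generator per call, seeded explicitly; identical params +
  seed give byte-identical CSVs.

What the generator does **not** emulate: between-stratum dependence beyond
the age–puberty link (season, puberty and weight status are sampled
independently, so joint-stratum margins are products), assay
nonlinearities, family structure or Hardy–Weinberg allele sampling, and
any real-population calibration of the synthetic DXA reference. Passing
tests therefore demonstrate internal correctness and recovery of injected
structure — not external validity on a real cohort.

## Statistical pipeline

* **Normality gate**: Shapiro–Wilk at α = 0.05 on the full analyzed sample
  (not per stratum); a failing, strictly positive variable is
  ln-transformed and re-tested. Gate decisions are recorded downstream.
* **Two-group tests**: t-test when the gate passes (on logs if
  transformed), otherwise Mann–Whitney U; chi-squared for categoricals.
  All p two-sided.
* **Diplotype groups**: Kruskal–Wallis omnibus across the six diplotypes
  (each requiring n ≥ 2), then all 15 pairwise Mann–Whitney tests flagged
  at the Bonferroni threshold 0.05/15 = 0.0033.
* **Correlations**: pairwise-complete Pearson, ln-transforms per a
  variable map.
* **Interaction scan**: OLS of a bone Z on metabolite × weight-group
  (normal vs overweight-or-obese) with main effects and covariates (age,
  sex, FM_Z, LM_Z); the product term's p-value is the heterogeneity test.
* **Adjusted regressions**: OLS with the same covariates; variance
  inflation factors computed for every predictor, flagged at VIF ≥ 3.

## Problem sizes used in validation

Calibration and recovery checks run at n = 5000 (Monte-Carlo SEs small
enough to separate the injected effects from noise); type-I calibration
runs 1000 null replicates at the study size n = 146 with slopes equalized
and the Gc2/Gc2 VDBP shift removed. The binding-model grid check covers
total 5–60 ng/mL × VDBP 100–400 µg/mL × albumin 3–5.5 g/dL.

## Known limitations

* Absolute free/bioavailable levels depend on unprintable-in-practice
  constants (affinities, VDBP molar mass); agreement with published cohort
  means is approximate (~2–5 %) by nature of that uncertainty.
* The linear calculation's 2 % agreement with the exact solver fails where
  ligand exceeds ~2.3 % of binder (high total 25OHD with low VDBP); use
  `mode: exact` there.
* The ln-or-raw choice for footnoted variables entering two-group tests,
  and the post-hoc pairwise test after Kruskal–Wallis, are conventions
  exposed in config rather than uniquely determined choices.
* The generator's independence assumptions mean not every printed marginal
  can be reproduced simultaneously.
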