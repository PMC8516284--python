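# vitdfree

Equilibrium free-hormone calculations for 25-hydroxyvitamin D (25OHD) and a
fully runnable pediatric cohort analysis built on top of them.

## The problem

Most circulating 25OHD rides on vitamin D-binding protein (VDBP, the Gc
globulin; ~85–90 %) or albumin (~10–15 %); well under 0.1 % is free. Under
the free-hormone hypothesis, the free — or "bioavailable" (free +
albumin-bound) — pool is the biologically active one, and it is not
measured directly in routine practice but *calculated* from total 25OHD,
VDBP and albumin by mass action:

```
Free  = Total / (1 + K_alb·[Alb] + K_DBP·[VDBP])        (molar units)
BioA  = Free · (1 + K_alb·[Alb])
```

Whether the VDBP association constant `K_DBP` should be one number for
everyone ("constant" scheme, default 0.7×10⁹ M⁻¹) or the mean of the two
Gc-allele affinities of a subject's diplotype ("specific" scheme; Gc1f
1.12×10⁹, Gc1s 0.60×10⁹, Gc2 0.36×10⁹ M⁻¹) is contested in the literature —
and the choice changes the calculated free level by up to ~2.6-fold across
the six diplotypes. This package implements both schemes, an exact
(binder-depletion-corrected) solver as a numerical oracle, the derived
clinical indices (vitamin D metabolite ratio VMR = 100·24,25(OH)₂D₃/25OHD,
deficiency < 20 ng/mL, DXA Z-scores, BMI/DRI/activity categories), a
calibrated synthetic cohort generator, and the statistical pipeline that
compares the schemes against clinical and bone outcomes in children.

Because no subject-level cohort is bundled, the `cohort` module generates
synthetic cohorts whose printed moments and effect structure (seasonal and
developmental gradients of 25OHD, iPTH coupling, diplotype frequencies,
BMI-dependent bone-Z slopes) match the study conditions the pipeline is
validated against; see `docs/methods.md`.

## Worked example

```python
from vitdfree import BindingConfig, ConcentrationPanel, free_25ohd, specific_scheme

cfg = BindingConfig()                       # default affinities & molar masses
con = cfg.constant_scheme()
panel = ConcentrationPanel(total_25ohd=19.8,  # ng/mL
                           vdbp=226.5,        # ug/mL
                           albumin=4.3)       # g/dL

r = free_25ohd(panel, con)
print(round(r.free_25ohd, 2), round(r.bioavailable_25ohd, 2))
# 6.34 2.47    -> free 6.34 pg/mL, bioavailable 2.47 ng/mL

spe = specific_scheme("Gc2/Gc2", cfg.allele_k_dbp, con)
print(round(free_25ohd(panel, spe).free_25ohd, 2))
# 11.04        -> the low-affinity Gc2/Gc2 diplotype frees ~70 % more 25OHD
```

At these cohort-mean inputs the model places 87.5 % of 25OHD on VDBP,
12.4 % on albumin and 0.032 % free — inside the canonical 85–90 % /
10–15 % / <0.1 % physiologic bands. The VDBP molar mass (default 58 kDa)
materially shifts absolute free values; it is a config value
(`binding.mw_vdbp`), not a constant in code.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study flow and write their
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # n=146 synthetic cohort -> cohort.csv
python analysis/02_derive_panel.py      # free/bioavailable, VMR, Z-scores, flags
python analysis/03_group_comparisons.py # two-group tests, correlations, diplotype tests
python analysis/04_bone_recovery.py     # stratified regressions + interaction scan
```

The same stages are exposed as a CLI (`vitdfree simulate|derive|analyze|report`)
and, underneath, as plain functions in `vitdfree.binding`, `.indices`,
`.cohort`, `.stats`, `.io`. On the default seed the suite reproduces the
expected qualitative pattern: the genotype-specific free/bioavailable
levels differ strongly across the six diplotypes (Kruskal–Wallis p < 0.001,
Bonferroni-corrected pairwise threshold 0.05/15 = 0.0033) while the
constant-scheme, total and directly measured levels do not; total 25OHD is
higher in summer than winter; all 25OHD measures correlate negatively with
iPTH; and the adjusted regression of total-body BMC Z on total 25OHD
recovers the injected slope 0.030 (95 % CI [0.029, 0.035] at n = 5000) in
normal-weight children with an opposite-signed slope in overweight/obese
children (interaction p ≪ 0.001).

## Layout

```
src/vitdfree/      library: binding model, indices, generator, stats, io, cli
analysis/          numbered narrative drivers (simulate -> derive -> analyze)
scripts/           acceptance recomputation
tests/             pytest suite (unit, property, calibration, acceptance)
docs/methods.md    model assumptions, calibration and limitations
```
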