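# sglt2mbma

Model-based meta-analysis (MBMA) of SGLT2 inhibitors: a sequential
PK → biomarker → FPG → HbA1c modelling pipeline for summary-level
(arm-mean) clinical trial data.

SGLT2 inhibitors (dapagliflozin, canagliflozin, empagliflozin, and newer
same-in-class drugs) lower blood glucose by blocking renal glucose
reabsorption, so their pharmacology is naturally read off the urine: the
package centres on the translational biomarker

    ΔUGEc = (UGE − UGE_baseline) / FPG_baseline        [g/(mg/dL)]

— the change in 24-hour urinary glucose excretion from baseline, normalized
by baseline fasting plasma glucose.  Because the normalization accounts for
the different filtered glucose loads of healthy subjects and T2DM patients,
one exposure–response curve serves both populations, which is what lets
early healthy-volunteer data predict late-stage patient endpoints.

The model chain, in the field's standard notation:

1. **PK** — per drug, a two-compartment disposition model with first-order
   elimination and a transit-compartment absorption chain (2 transit
   compartments for dapagliflozin/empagliflozin, 4 for canagliflozin; a food
   covariate on the absorption rate constant for dapagliflozin).  Steady-state
   24-h exposure is AUC_ss = dose/CL.
2. **PK/PD** — a hyperbolic Emax model,
   ΔUGEc = Emax·AUC/(EC50 + AUC), with one Emax (0.606 g/(mg/dL)) shared by
   all drugs in the class and a drug-specific EC50.
3. **FPG** — placebo response + disease progression + drug effect:
   FPG(t) = FPG_b + P_fmax·(1 − e^(−K_fp·t)) + DIS_fp·t + SLOPE_fd·ΔUGEc,
   with the placebo maximum P_fmax stratified by treatment type
   (naive / non-naive / add-on / mixed).
4. **HbA1c** — an empirical placebo curve of the same form plus an
   indirect-response (turnover) component driven by the FPG ratio to
   baseline: dH/dt = (FPG/FPG_b)·K_in + K_in2 − K_out·H, with
   K_in = K_out·HbA1c_b − K_in2 so that baseline is a steady state.

Every fitting stage weights arm means by the square root of the arm sample
size (residual SD ∝ 1/√n), the MBMA convention for pooling studies of very
different sizes.  Who this is for: pharmacometricians and biostatisticians
doing dose selection or early efficacy prediction for SGLT2 inhibitors, and
anyone who needs a tested, seedable simulator of summary-level PK/PD/endpoint
meta-datasets.

## Worked example

Predict what a 10 mg once-daily dapagliflozin regimen does to a naive-therapy
T2DM population (baseline FPG 160 mg/dL, HbA1c 7.92 %):

```python
import numpy as np
from sglt2mbma import (default_truth, DoseRegimen, auc_ss_24,
                       predict_delta_uge_c, fpg_on_drug, hba1c_total)

truth = default_truth()                      # published estimates
dapa = truth.pk["dapagliflozin"]
auc = auc_ss_24(dapa, DoseRegimen(dose=10.0))
duge = predict_delta_uge_c(auc, truth.biomarker, "dapagliflozin")
fpg24 = fpg_on_drug(24.0, truth.endpoints, "naive", 160.0, duge)
hba = hba1c_total(np.array([0., 4., 8., 12., 24.]),
                  truth.endpoints, "naive", 160.0, 7.92, duge)
```

which prints

```
steady-state AUC0-24  :    512.8 ng/mL*h
predicted dUGEc       :    0.546 g/(mg/dL)
FPG at 24 weeks       :    138.6 mg/dL
HbA1c trajectory (%)  : [7.92 7.37 7.14 7.04 7.  ]
```

Read: 10 mg/day at a clearance of 19.5 L/h gives a steady-state exposure of
513 ng/mL·h — about 9× the dapagliflozin EC50, so the biomarker sits near
90 % of the class-shared maximum.  That extra ~0.55 g of urinary glucose per
mg/dL of FPG pulls fasting glucose down by ~24 mg/dL (placebo and
progression included), and the slower HbA1c turnover (half-life
ln2/K_out ≈ 3.5 weeks) carries the drop through to a ~0.9 percentage-point
HbA1c reduction approaching steady state by 24 weeks.

## Command line

```bash
sglt2-mbma simulate-data --scenario paper-like --seed 7 --out-dir data/
sglt2-mbma fit --stage pk --data data/concentrations.csv --drug dapagliflozin --seed 1 --out pk.json
sglt2-mbma fit --stage pkpd --data data/uge.csv --seed 1 --out pkpd.json
sglt2-mbma fit --stage endpoint-placebo --data data/endpoints.csv --seed 1 --out pbo.json
sglt2-mbma fit --stage endpoint-drug --data data/endpoints.csv --placebo-fit pbo.json --seed 1 --out drug.json
sglt2-mbma vpc --data data/endpoints.csv --seed 5 --out-dir vpc/
sglt2-mbma predict --new-drug newdrug.yaml --seed 3 --out-dir pred/
```

Each command writes a JSON run manifest (seed, config hash, input digests)
next to its outputs.  Exit codes: 0 success, 2 validation error,
3 convergence failure.

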