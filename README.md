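# pkpdkit

Translational PK-PD modelling of a bispecific HER2xHER3 therapeutic
antibody, from preclinical data to a first-in-human dose proposal.

Antibody programs routinely face this chain of questions before a Phase I
trial: the drug's pharmacokinetics have been characterized in cynomolgus
monkey, its anti-tumor effect in a mouse xenograft, and a starting dose and
an efficacious dose must be proposed for humans who have never received it.
`pkpdkit` implements that chain for pharmacometricians and preclinical
modellers:

- **Disposition model** — two-compartment kinetics with parallel linear and
  Michaelis-Menten (saturable, target-mediated) clearance:
  `dA1/dt = -(CL/V1)A1 - Vmax*C1/(Km+C1) - (Q/V1)A1 + (Q/V2)A2`,
  simulated under arbitrary bolus regimens.
- **Allometric scaling** — flows by `(W/70)^0.75`, volumes by `W/70`, Km
  fixed across species, projecting the monkey-derived 70 kg anchor to a
  0.02 kg mouse or back.
- **Population layer and estimation** — lognormal between-subject
  variability (`P_i = P_pop*exp(eta_i)`), proportional + additive residual
  error, LLOQ/2 imputation of below-quantification points, and
  maximum-likelihood fitting (iteratively reweighted GLS with a Laplace
  marginal-likelihood path) behind scikit-learn-style estimators.
- **Dose selection** — AUC_0-inf, Cmax/Cave/Ctrough, receptor occupancy
  `%RO = 100*C/(Km+C)`, safety margins against the 193 g.h/L monkey NOAEL
  exposure, and a Km sensitivity sweep.
- **Tumor growth inhibition** — an indirect-response model on a zero-order
  growth rate plus an Emax-stimulated first-order kill, driven by the
  mouse-scaled PK, with tumor-stasis evaluation and AUC-matched
  cross-species dose translation.
- **Synthetic studies** — generators that emulate the monkey toxicity
  designs and the JIMT-1 xenograft design (including euthanasia dropout at
  800 mm^3), so the whole chain is testable without animal data.

See `docs/methods.md` for the model equations, assumptions, estimation
details and known limitations.

## Worked example

Receptor occupancy and safety margins for candidate flat doses given once
every three weeks:

```python
from pkpdkit import human_default_params, exposure_table

rows = exposure_table(human_default_params(), [80, 360, 480])
for r in rows:
    print(f"{r.dose:5.0f} mg  AUC {r.auc_inf:6.3g} g.h/L  margin {round(r.safety_margin):3d}  "
          f"RO {r.ro_cmax:.1f}/{r.ro_cave:.1f}/{r.ro_ctrough:.1f} %")
```

```
   80 mg  AUC      1 g.h/L  margin 193  RO 99.1/90.1/0.9 %
  360 mg  AUC   10.4 g.h/L  margin  19  RO 99.8/98.9/23.8 %
  480 mg  AUC     16 g.h/L  margin  12  RO 99.9/99.3/75.7 %
```

Reading: a 480 mg flat dose yields a predicted exposure 12-fold below the
highest exposure tolerated without adverse effect in monkey, while already
holding the target more than 99% occupied at peak and on average over the
cycle — the window in which a dose is both safe to start with and
plausibly pharmacologically active.  The trough occupancy column shows the
receptor pool desaturating by cycle end below ~900 mg.

The mouse side of the chain, exposure-matched to a 360 mg human dose:

```python
from pkpdkit import (mouse_default_params, pd_default_params, Regimen,
                     simulate_tumor, stasis_metric, auc_matched_mouse_dose)
import numpy as np

mgkg = auc_matched_mouse_dose(360.0)          # ~9.7 mg/kg weekly x3
regimen = Regimen.weekly(mgkg * 0.02, 3, route="ip_bolus")
course = simulate_tumor(pd_default_params(), mouse_default_params(),
                        regimen, np.linspace(0, 600, 80))
res = stasis_metric(course, day=21.0)
print(f"{mgkg:.2f} mg/kg weekly x3: T21/T0 = {res.ratio:.3f} -> {res.classification}")
```

```
9.74 mg/kg weekly x3: T21/T0 = 0.493 -> stasis or regression
```

A weekly mouse regimen carrying the same total exposure as the proposed
human dose halves the tumor volume by day 21, versus a 2.2-fold increase
for vehicle.

A command-line interface covers the same stages
(`pkpdkit exposure-table`, `pkpdkit generate-data`, `pkpdkit fit-pk`,
`pkpdkit fit-pd`, `pkpdkit simulate-tumor`, `pkpdkit fig5`,
`pkpdkit run-all --outdir reports/`).

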