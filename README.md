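# immunejm

Joint models for immune-cell kinetics and competing clinical events after
T-cell-depleted allogeneic stem-cell transplantation (alloSCT) and donor
lymphocyte infusion (DLI).

## The problem

After a T-cell-depleted alloSCT, circulating T-cell and NK-cell counts
recover from near zero over the first six months, and a prophylactic
low-dose DLI given around month three can boost that recovery.  The same
donor T-cells that drive the graft-versus-leukemia effect (preventing
relapse) also drive graft-versus-host disease (GvHD).  Relating the cell
count *trajectory* to the hazards of GvHD, relapse and other failure is
statistically awkward: counts are measured with error at irregular visits,
trajectories differ strongly between patients, and the very events of
interest terminate the measurement series (informative dropout).

The shared-parameter joint model handles all three at once.  For subject
*i* with log cell count y and latent trajectory m:

```
y_ij = m_i(t_ij) + e_ij,  m_i(t) = x_i(t)'β + z_i(t)'b_i,
e_ij ~ N(0, σ²),  b_i ~ N(0, D)
h_ik(t) = h_0k(t) exp(γ_k' w_ik + α_k m_i(t) [+ η_k m_i'(t)])
```

The longitudinal submodel is a linear mixed model with a restricted cubic
spline of time and covariate-by-time interactions (disease-risk group ×
donor type × time, plus a CMV-serostatus level shift).  The time-to-event
submodel is a set of cause-specific proportional hazards (piecewise-constant
baselines) sharing the subject's random effects through the *current value*
m_i(t) — and optionally the *current slope* m_i'(t) — of the latent log
count.  exp(α_k) is the hazard ratio of cause k per unit increase in the
log count.  Two variants are built in: model I starts at transplant
(six-month horizon; GvHD, relapse, other failure), model II at the early
low-dose DLI (three-month horizon; GvHD vs a composite of relapse and other
failure).

Because the patient data are not public, the package ships a calibrated
synthetic-cohort generator that emulates the study's structure: 166
subjects, 62/166 high risk, 51/166 CMV −/− pairs, a 0.5×10⁶/L detection
floor, a median of 6 measurements per subject, and event rates in the
study's regime (six-month GvHD incidence ≈26% in the high-risk group vs
≈5% otherwise).  Every stage of the pipeline is tested against this
generator.

## Worked example

```python
import numpy as np
from immunejm import CohortSimulator, JointModel, model_i_spec, default_true_params

tp = default_true_params()                       # calibrated generative truth
cohort = CohortSimulator(n_subjects=166, random_state=1).sample()

spec = model_i_spec(marker="CD4", basis=tp.basis,
                    random_effects="intercept_linear",
                    baseline_cuts=tp.baseline_cuts)
fit = JointModel(spec=spec, gh_order=7, gl_order=9).fit(cohort)
print(fit.hazard_ratios().to_string(index=False, float_format="%.2f"))
```

which prints (seed 1; the `current_value` rows are the associations per
unit log CD4 count):

```
        cause          term  estimate   se   HR  lo95  hi95
         GvHD  donor_UD_ATG      0.66 0.58 1.93  0.62  6.04
         GvHD     risk_high      1.69 0.50 5.40  2.01 14.53
         GvHD current_value      0.41 0.20 1.51  1.03  2.22
      relapse  donor_UD_ATG     -1.06 0.48 0.35  0.14  0.89
      relapse     risk_high      1.66 0.49 5.26  2.03 13.62
      relapse current_value     -0.54 0.17 0.58  0.42  0.82
other_failure  donor_UD_ATG      0.94 0.54 2.57  0.90  7.36
other_failure current_value     -0.39 0.12 0.68  0.54  0.86
```

Read: in this simulated cohort a one-unit-higher log CD4 count multiplies
the GvHD hazard by 1.51 (95% CI 1.03–2.22) and the relapse hazard by 0.58
(0.42–0.82); high-risk patients (scheduled for early DLI) have a ~5-fold
GvHD hazard.  At the study's size single-cohort estimates scatter around
the generative coefficients exp(0.89)=2.44 and exp(−0.43)=0.65; a 50-replicate
recovery study (in the test suite) shows the estimator is unbiased.

The same estimator exposes dropout-corrected trajectories
(`fit.predict_mean_trajectory`, `fit.subject_trajectory`), the slope
extension (`association="current_value_plus_slope"` plus
`test_slope_association`), Kaplan–Meier / Aalen–Johansen curves
(`immunejm.nonparametric`) and time-dependent-covariate cause-specific Cox
models (`immunejm.coxtd`).

A CLI covers the whole flow:

```
immunejm simulate --seed 1 --out cohort/
immunejm validate cohort/
immunejm cif cohort/
immunejm fit-joint cohort/ --marker CD4
immunejm report cohort/ --markers CD4 --out results/
```

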