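# neutroforecast

Simulation and model-based forecasting of chemotherapy-induced neutropenia
from frequent neutrophil monitoring.

Cytotoxic chemotherapy suppresses the bone marrow; for drugs like docetaxel
the absolute neutrophil count (ANC) routinely falls into Grade 4
neutropenia (ANC < 0.5 ×10⁹ cells/L), exposing patients to febrile
neutropenia and forcing cycle delays. Home self-testing devices make
frequent ANC monitoring feasible — but how much does each extra measurement
buy, if the data are run through a population model to forecast the rest of
the cycle? This package answers that question *in silico* for
pharmacometricians and clinical-pharmacology methodologists: it simulates
virtual docetaxel cohorts from a semi-mechanistic myelosuppression model,
forecasts each patient's ANC time-course by MAP ("Bayesian feedback")
estimation from truncated monitoring data, and quantifies how forecast
accuracy, summary-variable precision and severe-neutropenia classification
improve with monitoring frequency and duration.

## The model

Granulopoiesis is a transit chain — proliferating progenitors `Prol`, three
maturation compartments, circulating pool `Circ` — with a feedback loop and
a linear drug effect:

    dProl/dt = k_prol·Prol·(1 − Slope·Conc(t))·(Circ₀/Circ)^γ − k_tr·Prol
    dTᵢ/dt   = k_tr·(Tᵢ₋₁ − Tᵢ)                    i = 1..3
    dCirc/dt = k_tr·T₃ − k_circ·Circ

with `k_prol = k_tr = k_circ = 4/MTT`. Population parameters (docetaxel):
ANC₀ = 5.22 ×10⁹/L, MTT = 84.2 h, γ = 0.145, Slope = 15.6 L/µmol, log-normal
IIV (25/14/36 % on ANC₀/MTT/Slope), 42.4 % residual error on log ANC, and
covariate effects of AAG, sex, performance status and previous chemotherapy
on ANC₀ and Slope. Individual random effects η are estimated per patient by
minimising the MAP objective

    J(η) = Σⱼ (log yⱼ − log f(tⱼ; η))²/σ² + Σₖ ηₖ²/ωₖ²

with population parameters fixed. Exposure comes from a surrogate
three-compartment docetaxel model (1-h infusion, 75/100 mg/m²) whose global
scale is calibrated so that 68 % of the virtual cohort experiences Grade 4
neutropenia — the stand-in for the original unpublished per-patient
concentration profiles. See `docs/methods.md` for the full account.

## Worked example

```python
from neutroforecast import (PopulationModel, PKConfig, Scenario, IndividualMAP,
                            simulate_trial, restrict_observations,
                            calibrate_exposure)

pop = PopulationModel()                              # reported estimates
scale = calibrate_exposure(pop, n=600, seed=2017)    # -> 1.024
patients = simulate_trial(pop, 200, seed=2018,
                          pk_config=PKConfig(exposure_scale=scale))

p = patients[0]
obs = restrict_observations(p, Scenario("daily", 7))  # monitored to day 7
res = IndividualMAP(obs, pop, p.covariates, p.conc).fit()
print(res.summary())
print(f"day-21 accuracy ratio (pred/true): {res.accuracy_ratio(p, 21.0):.3f}")
```

prints

```
calibrated exposure scale: 1.024
Individual MAP fit (myelosuppression model)
====================================================
scenario: daily:7   n_obs: 6   converged: True
objective: 5.80549
----------------------------------------------------
effect        estimate    post. SD    prior SD
eta_anc0       -0.1271      0.1958      0.2500
eta_mtt        -0.0712      0.1259      0.1400
eta_slope      -0.3694      0.2285      0.3600
----------------------------------------------------
ANC0_i    5.087 x10^9/L   MTT_i    78.4 h   Slope_i    9.56 L/umol
day-21 accuracy ratio (pred/true): 0.945
```

The calibrated exposure scale of ~1.02 means the literature disposition
model needs essentially no adjustment to reproduce the 68 % Grade 4
incidence. The posterior SDs show what six early observations buy: the
baseline effect is still prior-dominated while the drug-effect slope is
already substantially sharpened (0.23 vs the prior 0.36). The accuracy
ratio 0.945 says the two-week forecast of this patient's day-21 ANC is 5 %
low. Full studies — every monitoring scenario, summary-variable RMSEs,
sensitivity/specificity — run through `run_study(StudyConfig(...))` or the
CLI:

```bash
neutroforecast run --config study.yaml --out results/
```

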