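# Methods

## The model

`nanopbpk` implements a whole-body physiologically based pharmacokinetic
(PBPK) model of intravenously administered polymer nanoparticles (NPs) in
the mouse.  Eight organ compartments (lung, liver, spleen, kidney, heart,
bone, brain, "other tissues") are connected by the circulation: the
venous pool feeds the lung, which receives the entire cardiac output in
series; oxygenated blood collects in an arterial pool that perfuses the
remaining organs in parallel; splenic venous outflow drains through the
liver (portal convention).  Each organ holds three NP mass pools —
intravascular `M_vasc`, extravascular tissue `M_extra`, and, in the
organs of the mononuclear phagocyte system (lung, liver, spleen, kidney),
an intracellular phagocytic pool `M_phago`:

    dM_vasc/dt  = Q (M_in/V_in − M_vasc/V_vasc)
                  − PA (M_vasc/V_vasc − M_extra/(P·V_extra)) + R_rel − R_up
    dM_extra/dt = PA (M_vasc/V_vasc − M_extra/(P·V_extra)) − R_elim
    dM_phago/dt = R_up − R_rel

with

    R_up   = K_max · t^n_H / (K_50^n_H + t^n_H) · M_vasc     (Hill uptake)
    R_rel  = K_rel · M_phago
    R_elim = K_elim · M_extra / V_extra

`PA` is the permeability–flow product (mL/h), `P` the tissue:plasma
distribution coefficient, `K_max` (1/h) the maximum phagocytosis rate,
`K_50` (h) the time to the half-maximal uptake rate, `n_H` the Hill
coefficient, `K_rel` (1/h) the phagocytic release rate.  `K_elim` is
nonzero only for the liver (biliary clearance, `K_bile`) and kidney
(urinary clearance, `K_urine`); as written it multiplies a concentration,
so its units are mL/h.  Biliary and urinary losses accumulate in
absorbing sinks `X_bile`, `X_urine` — there is no gastrointestinal
compartment.  Blood concentration is reported as pooled
`(M_art + M_ven)/(V_art + V_ven)` because tail-vein samples cannot
distinguish the arterial from the venous pool.

Two structural facts matter for everything downstream:

* **Mass conservation.**  The system is closed except for the two sinks,
  so total mass + excreted equals the administered dose identically; the
  solver preserves this to better than 1e-6 relative (tested).
* **Linearity in dose.**  Every rate is linear in NP mass (the Hill
  factor depends on time, not mass), so trajectories scale exactly with
  the dose.  Fitting exploits this: each parameter draw is simulated once
  at a reference dose and rescaled to the other doses; organ/liver ratios
  are dose-invariant.  A non-modeled consequence, deliberate here: the
  model cannot produce the dose-dependent half-life that saturable
  (capacity-limited) phagocytosis would give — there is no saturable
  uptake in this model by design.

Edge conventions: `K_50 = 0` means immediate progression to the maximum
phagocytosis rate — the Hill factor is `K_max` for any `t > 0` and 0 at
`t = 0` (right-limit convention).  `P = 0` with `PA > 0` is rejected
(division by `P`).  Solver-noise negatives are clamped to zero after
integration.

## Parameters and physiology

Mouse physiology (blood flows, compartment volumes) ships as an editable
CSV (`data/mouse_physiology.csv`): cardiac output 600 mL/h (10 mL/min),
total blood ≈ 2.2 mL with 0.35 mL arterial / 0.70 mL venous, and a
pulmonary blood pool of 0.30 mL lumped into lung `V_vasc`.  Values are
literature-typical for a ~25 g mouse; every analysis is
physiology-configurable.  The vascular volumes were chosen so that the
fastest convective rate constants (Q/V ≈ 2000/h) remain well inside the
stability region of a fixed-step 4th-order integrator at dt = 0.001 h,
which the test suite uses as an independent oracle for the adaptive
solver.

The reference kinetic parameterization (`data/reference_parameters.csv`)
describes a long-circulating PEGylated polymer NP: `K_urine = 0` (bile is
the sole elimination route), near-immediate phagocytosis onset in liver
and spleen (`K_50 = 0.01 h`), a 125 h half-maximum time in the kidney,
and `K_rel > K_max` everywhere except the liver.  It was calibrated once
so the simulated blood kinetics fall in the experimentally observed
regime — a one-phase-decay half-life of ≈ 26 h (observed range across
doses: ~23–90 h) with liver-dominant organ uptake and ≈ 21% of the dose
excreted in bile by 48 h — and is not adjusted anywhere else.

Integration uses LSODA with rtol 1e-8 / atol 1e-10 μg on a default
0–48 h grid at 0.1 h.  The fitting loop relaxes to rtol 1e-6 / atol 1e-9
(three orders of magnitude below any data feature).

## Monte Carlo importance sampling (MCIS)

Parameters are estimated as probability distributions in three serial
stages.  Each stage samples `n` joint parameter draws, simulates each,
scores it against the data with

    d = Σ ((model − observed) / SEM_observed)²

(blood on the log10 concentration scale, since concentrations span
orders of magnitude; organ data on the relative-to-liver scale), converts
scores to normalized importance weights `w ∝ exp(−d/2)` (a Gaussian
pseudo-likelihood; the minimum d is subtracted before exponentiating,
which changes nothing after normalization but prevents underflow), and
re-expresses each parameter's distribution from the weighted mean and
weighted SD of the draws.

* Stage 1 samples log-uniformly over `base·10^[−6, +2]` — an
  order-of-magnitude search around a donor parameterization.
* Stage 2 samples uniformly within ±50% of the stage-1 weighted means.
* Stage 3 samples zero-truncated normals with the stage-2 weighted
  mean/SD; its weighted moments are the reported posterior.  A
  moment-matched gamma re-expression is available
  (`ParameterDistribution.as_gamma`).

Fitting data: blood concentration at 0.03, 1, 8, 24, 48 h at all five
study doses, plus non-liver organ biodistribution relative to liver at 3
and 48 h at the endpoint dose.  The default fitted set is the three
systemic parameters the blood data identify — `K_bile`, liver `K_max`
and liver `PA` — with everything else held at the base values.  This is
a deliberate identifiability decision: with 10³–10⁴ draws per stage, a
stage-1 search over 8 decades is only reliable in low dimension, and the
weighted update degenerates towards the single best draw when the
discrepancy surface is sharp (the effective sample size is reported, and
a warning is recorded below ESS 10).  Wider sets can be requested via
`fit_params`.  Fitting all five doses rather than one is likewise an
identifiability matter: with one dose, `K_bile` trades off against liver
`PA` (distribution–clearance confounding) and recovery degrades roughly
threefold.

Posterior-predictive bands run the model 100 times with parameters drawn
from the fitted distributions and report the mean ± SEM envelope.

## Sensitivity and validation

The normalized sensitivity coefficient of a parameter is
`NSC = ((AUC − AUC0)/AUC0) / ((P − P0)/P0)` from a single one-sided +1%
perturbation at a 0.5 mg dose with the AUC of blood concentration over
0–48 h.  A central-difference estimate is kept in the tests as an
independent oracle.  Because the model is dose-linear, NSC is invariant
to the dose used.  The complementary coefficient of variation (CV =
SD/mean of a fitted distribution) measures how tightly the data
constrain each parameter.

Validation against held-out conditions uses the two-sample Z score
`Z = (x̄_mod − x̄_exp)/√(σ²_mod/n_mod + σ²_exp/n_exp)` with
`n_mod = 100` posterior-predictive runs, at the conventional threshold
|Z| < 20, alongside the PBPK factor-of-two rule (model mean within
50–200% of the experimental mean, bounds inclusive).  The default twelve
conditions are blood at 2 and 10 h at the fitted dose plus five
non-liver organs at 6 and 24 h.  σ_exp is the SD across animals (not the
SEM-derived value).  R²/RMSE (`fit_metrics`) summarize overall agreement;
`anova_r2_from_f` and `pooled_t_df` cover the endpoint-statistics
identities used in reporting.

## Synthetic data

The generator reproduces the study design: 5 dose groups (0.1, 0.5, 2.0,
2.5, 3.5 mg/animal), 3 mice per group per time point, blood samples at
2 min–48 h (11 points), biodistribution at 3, 6, 24, 48 h as noisy
per-animal organ/liver tissue-concentration ratios at the 0.5 mg
endpoint dose.  Measurement noise is multiplicative lognormal with
σ = 0.10 (≈10% CV) — appropriate for fluorescence measurements on a
positive scale with roughly constant relative error.  Everything is
deterministic for a fixed seed.

What the generator does *not* emulate: fluorescence-to-mass
miscalibration of the liver normalizer (which in real data propagates
multiplicatively into every organ ratio), inter-animal physiological
variability (noise is i.i.d. per observation), dose-dependent clearance
saturation, and plate-position or imaging artifacts beyond additive
Gaussian intensity noise.  Passing tests therefore demonstrate that the
estimation machinery is correct and calibrated under the assumed noise
model, not that the model is adequate for any particular real dataset.

The plate generator emits 9 images per well for standards (serial
dilutions 0–250 μg/mL, two replicates) and for a one-phase-decay blood
series; per-image pixel sums follow `slope·conc + intercept` plus
Gaussian noise.  The quantification chain mirrors the laboratory
procedure: per-image pixel sums, background = mean summed intensity of
the blood-only (0 μg/mL) wells, OLS standard curve, inversion (clamped
at zero, flagged outside the fitted range), and a one-phase decay
`C(t) = C0·e^{−kt}` with the plateau constrained to zero, initialized
from a log-linear regression and fitted by unweighted nonlinear least
squares (xtol 1e-10); `t½ = ln 2/k`.  Decay fits pool all animals of a
group by default (group-level reporting), with per-animal fits as an
option.

## Numerical and design choices

* Stage ranges (log10 [−6, +2]; ±50%; normal) and the discrepancy form
  are declared defaults exposed in configuration.
* Per-stage RNG substreams derive deterministically from the single run
  seed (`SeedSequence.spawn`), so runs are bitwise reproducible.
* A draw whose simulation produces a non-finite score receives an
  effectively zero weight; a stage in which *all* draws are non-finite
  aborts with an error naming the stage.
* `blood_auc` is the trapezoidal integral on the stored grid with linear
  interpolation at the requested endpoint; a single-point grid yields 0.
* Dose→particle-count conversion treats particles as spheres:
  `count = mass/(ρ·π/6·d³)`; 0.1 mg of 180 nm, 1 g/mL particles is
  ≈3.3×10¹⁰.
* Test and acceptance profiles run MCIS at 10³ draws/stage (the
  study-scale default is 10⁴) and score 10 random parameter sets in the
  solver cross-checks; these sizes are the package's desk-scale defaults
  and are configurable.

## Known limitations

* No saturable/capacity-limited phagocytosis, no decoy co-administration
  mechanism, no inter-species scaling: out of scope by design.
* The reference parameterization is a plausible stand-in calibrated to
  the observed kinetic regime, not a transcription of a fitted table.
* Parameters outside the default fitted set are not updated by MCIS;
  their posterior uncertainty is not quantified unless they are added to
  `fit_params` (with a correspondingly larger draw budget).
* The importance-sampling update collapses toward the best draw when
  data are informative (low ESS); the stage structure compensates in low
  dimension but is not a substitute for MCMC in high dimension.
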