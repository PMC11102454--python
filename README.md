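# nanopbpk

Whole-body PBPK modelling of polymer nanoparticle (NP) biodistribution in
mice, with probabilistic parameterization by Monte Carlo importance
sampling (MCIS), sensitivity and validation statistics, and the
quantitative-microscopy blood-concentration / half-life pipeline.

## Who this is for

Groups studying the physiological fate of intravenously dosed polymer
nanocarriers (circulation half-life, organ tropism, phagocyte-mediated
clearance) who want a tested, reusable implementation of the standard
analysis chain: a mechanistic organ-compartment model, data-driven
re-parameterization, sensitivity and posterior-predictive validation,
and the fluorescence-plate quantification used to measure blood NP
concentrations in the first place.  Everything runs end-to-end on
synthetic data with the study's design (5 dose groups of 0.1–3.5
mg/animal, n = 3 mice per group per time point, blood sampling 2 min–48
h, endpoint biodistribution relative to liver).

## The model

Each organ holds intravascular, extravascular and (lung, liver, spleen,
kidney) phagocytic NP pools:

    dM_vasc/dt  = Q (M_in/V_in − M_vasc/V_vasc) − PA (M_vasc/V_vasc − M_extra/(P·V_extra)) + R_rel − R_up
    dM_extra/dt = PA (M_vasc/V_vasc − M_extra/(P·V_extra)) − R_elim
    dM_phago/dt = R_up − R_rel

with Hill-kinetic, time-dependent phagocytic uptake
R_up = K_max·t^n_H/(K_50^n_H + t^n_H)·M_vasc, first-order release
R_rel = K_rel·M_phago, and elimination R_elim = K_elim·M_extra/V_extra
into bile (liver) or urine (kidney).  The venous pool feeds the lung in
series; all other organs are perfused in parallel from the arterial
pool; splenic outflow drains through the liver.  Parameters are
estimated as probability distributions by three-stage MCIS (log-uniform
order-of-magnitude search → ±50% uniform fine-tuning → truncated
normals), weighting each simulated draw by exp(−d/2) where d is the
SEM-standardized squared misfit.  Validation uses the two-sample Z score
and the PBPK factor-of-two convention.  See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from nanopbpk import (
    PhysiologyTable, PBPKParameters, DoseSchedule, StudyDesign,
    simulate, np_count_from_dose, fit_one_phase_decay,
    generate_from_model, FittingData, nsc,
)
from nanopbpk.mcis import fit_three_stage

phys, params = PhysiologyTable.default(), PBPKParameters.reference()

# a 0.5 mg dose of 180 nm, 1 g/mL particles is ~160 billion NPs
print(f"{np_count_from_dose(0.5):.3g}")            # 1.64e+11

# forward-simulate at the study's sampling times and fit a one-phase decay
design = StudyDesign()
times = np.asarray(design.blood_times)
sim = simulate(params, phys, DoseSchedule.from_mg(0.5), t_grid=np.r_[0.0, times])
print(f"t1/2 = {fit_one_phase_decay(times, sim.blood_concentration[1:]).t_half:.1f} h")
# t1/2 = 26.4 h

# blood exposure is most sensitive to the biliary excretion rate
print(f"NSC(K_bile) = {nsc(params, phys, 'liver.K_elim').NSC:.3f}")  # -0.124

# recover parameters from synthetic study data (truth = params)
blood, biodist = generate_from_model(params, phys, design, seed=42)
data = FittingData.from_datasets(blood, biodist)
result = fit_three_stage(params, data, phys, n_sims_per_stage=1000, seed=42)
k_bile = result.posterior_params.get_value("liver.K_elim")
print(f"K_bile: truth 0.100, posterior mean {k_bile:.3f}")  # 0.081
```

The particle count follows from treating NPs as spheres
(mass/(ρ·π/6·d³)); the 26.4 h half-life is the reference
parameterization's blood kinetics, inside the experimentally observed
23–90 h band; the negative NSC says that increasing biliary excretion
lowers the blood AUC — the model's single most influential parameter;
and the three-stage MCIS posterior mean lands within ~20% of the known
generating value under 10% measurement noise.

The same stages are available from the shell:

```
nanopbpk synth --seed 42 --out runs/demo          # synthetic study data
nanopbpk fit --seed 42 --out runs/demo            # three-stage MCIS
nanopbpk sensitivity --out runs/demo              # NSC table
nanopbpk validate --seed 42 --out runs/demo       # 12-condition Z tests
```

Each run writes a `manifest.json` with the seed, inputs and SHA-256
hashes of every output.

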