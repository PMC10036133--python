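# allocart

Mechanistic population PK/PD modelling of **allogeneic CAR-T cell
kinetics under lymphodepletion**: a tested simulator and censored-data
inference pipeline for the interplay between the UCART19 anti-CD19
product, the host immune system (NK and T lymphocytes), IL-7, and the
lymphodepleting agents fludarabine, cyclophosphamide (FC) and
alemtuzumab.

It is aimed at pharmacometricians and quantitative systems
pharmacologists who want to simulate virtual trials of allogeneic CAR-T
products, explore alternative lymphodepletion regimens, or fit the
model's individual parameters to long-format concentration/count data
with below-LOQ censoring.

## The model

All state variables evolve as coupled ODEs over days relative to the
CAR-T infusion (day 0):

* **Alemtuzumab** — linear two-compartment PK (CL, V1, V2, Q), used as a
  forcing function via its bi-exponential closed form.
* **FC** — a kinetic-pharmacodynamic (KPD) virtual compartment: the
  individual F and C totals normalised to the study medians (165 and
  2,670 mg), dosed at day −7 and decaying at `kDE`.
* **Host NK / T lymphocytes** — per cell type, a tissue→blood maturation
  chain with a feedback term `(ref(t)/blood)^γ` on production
  (haematotoxicity-model structure). FC kills in tissue only;
  alemtuzumab kills in tissue and blood. The feedback reference moves
  from the pre-treatment baseline to a distinct post-recovery level. A
  transient "expanding" lymphocyte pool reproduces the peak observed
  around the CAR-T expansion.
* **IL-7** — turnover model `dIL7/dt = k_in·(1 + IncrMax·(LDP−1)/(LDP50
  + (LDP−1))) − k_out·IL7`, where LDP is the host-T lymphodepletion
  ratio (baseline over current blood count, clamped at 1).
* **UCART19** — three memory subpopulations (T_SCM, T_CM, T_EM) in blood
  and tissue with homing/egress, progressive differentiation
  (SCM→CM→EM), a time-limited tissue expansion potentiated by IL-7
  through a Hill term (with a capacity safeguard), host-T-mediated
  allogeneic elimination (off for persistent sets), and an optional
  blood-only truncation elimination.

The population layer draws individuals as `θ_i = θ_typ·exp(η_i)`,
`η ~ N(0, Ω)` (51 population parameters, 18 freely estimated, 23 with
inter-individual variability), simulates a 26-set virtual trial, and
runs a **numerical predictive check**: the distribution over replicate
trials of the fraction of sets whose blood UCART19 exceeds the 0.001 G/L
flow-cytometry LOQ, overall and stratified by total alemtuzumab dose.
Inference uses the Beal **M3** censored likelihood and per-individual
maximum-likelihood/MAP fits in log-parameter space.

## Worked example

Simulate the three observed kinetic archetypes under a 40 mg
alemtuzumab FCA regimen and classify expansion on the flow-cytometry
sampling schedule:

```python
import numpy as np
from allocart import classify_expansion, simulate_subject
from allocart.synthetic import archetype_profiles, archetype_regimen

regimen = archetype_regimen(alem_total_mg=40.0)
for name, subject in archetype_profiles().items():
    traj = simulate_subject(subject, regimen)
    call = classify_expansion(traj)
    day84 = np.interp(84.0, traj.times, traj.ucart_blood)
    print(f"{name:<13} expanded={call.expanded!s:<5} "
          f"Cmax={call.cmax:9.4f} G/L  Tmax=day {call.tmax:4.0f}  "
          f"day-84={day84:.2e} G/L")
```

```
persistence   expanded=True  Cmax=   2.3559 G/L  Tmax=day   14  day-84=1.82e-01 G/L
transient     expanded=True  Cmax=   0.2939 G/L  Tmax=day   14  day-84=4.27e-14 G/L
no_expansion  expanded=False Cmax=   0.0000 G/L  Tmax=day    3  day-84=4.23e-15 G/L
```

The persistent subject (no allogeneic elimination) stays above the LOQ
through day 84; the transient subject peaks near day 11–14 and is then
rejected by recovering host T cells; the weakly lymphodepleted subject
never expands above the LOQ.

A command-line interface mirrors the library:

```bash
allocart generate --seed 7 --out study/          # virtual 26-set trial (CSV)
allocart npc --regimens study/dosing.csv --covariates study/covariates.csv \
             --reps 500 --seed 7 --out npc.json  # numerical predictive check
allocart fit --data study/observations.csv --regimens study/dosing.csv \
             --covariates study/covariates.csv --free CL --free V1 \
             --out fits.json                     # per-set censored ML fits
```

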