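# Methods

This note documents the model equations as implemented, the parameter
choices and their provenance, what the virtual-study generator does and
does not emulate, the numerical choices, and the known limitations.

## Model structure

Time is in days relative to the UCART19 infusion (day 0); the
simulation window is day −7 to day 84. The state vector holds, in
order: host NK tissue and blood, host T tissue and blood, IL-7, and the
six UCART19 compartments (T_SCM, T_CM, T_EM, each in blood and tissue).
Drug exposures are forcing functions, not states.

### Drug exposures

Alemtuzumab follows a linear two-compartment model. Inside the coupled
system it is evaluated through the bi-exponential closed form
(superposition over bolus doses); the public `alem_concentration`
integrates the ODE system instead, and the two routes are cross-checked
against each other in the tests to 1e-6 relative. Infusions are treated
as boluses (durations are well under a day).

Fludarabine and cyclophosphamide have no concentration data, so they
act through a KPD virtual compartment. The dimensionless FC dose is the
mean of the two per-drug totals normalised to the study medians
(165 mg F, 2,670 mg C) — symmetric, unity at the medians, linear in
each drug — administered at day −7 and decaying at `kDE = 0.2/day`, so
exposure persists through the expansion window but is mostly gone after
two weeks. `kDE` is not identifiable from anything in scope and is
flagged fixed.

### Host lymphocytes

Per cell type X ∈ {NK, T}:

    d(tissue)/dt = k_trX·tissue·(ref(t)/blood)^γX − k_trX·tissue
                   − k_effFChostX·FC(t)·tissue − k_effAlhostX·Alem(t)·tissue
    d(blood)/dt  = k_trX·tissue − k_trX·blood − k_effAlhostX·Alem(t)·blood

The feedback reference `ref(t)` interpolates logistically from the
pre-treatment baseline (`refHostX`, a per-set data input, never
estimated) to the post-recovery level (`refHostXlast`, estimated), with
midpoint `t_ref_switch = 28 d` and scale `tau_ref = 5 d`; recovered
counts differ substantially from pre-treatment counts, and the logistic
is the simplest smooth monotone bridge.

The transient lymphocyte peak seen around the CAR-T expansion is a
separate blood pool per cell type: zero before its window, exponential
growth from a seed of 1e-4 G/L to `xfold_X` times the seed over the
window (default days 8–18, straddling the observed UCART19 Tmax median
of day 11), then first-order decay at `k_elimHostX`. The pool depends
only on time, so it is evaluated in closed form. Expanding pools are
not targets of the drug kill terms (the lymphodepleting exposure has
largely decayed by their window).

Observed blood counts are chain blood plus pool. Total lymphocytes are
host T + host NK + UCART19 in blood.

### IL-7

Indirect response with production stimulated by host-T lymphodepletion:

    dIL7/dt = k_in·(1 + IncrMax·(LDP−1)/(LDP50 + (LDP−1))) − k_out·IL7

`LDP` is the pre-treatment host-T baseline over the current observed
blood host-T count, clamped at 1 so the stimulus vanishes at baseline.
The baseline (static) reference is used in the ratio, not the
time-dependent one. IL-7 initialises at `k_in/k_out` (3 pg/mL with the
defaults, inside physiologic ranges). `IncrMax = 9.7` and `LDP50 = 10`
are study estimates; `k_out = 0.5/day` is a fixed design value.

### UCART19

Each subpopulation exchanges between blood and tissue
(`k_homingX`, `k_egressX`), is eliminated physiologically in tissue
(`k_elimX`, with EM elimination faster than CM so T_CM controls the
persistence phase), and differentiates progressively: SCM→CM at a
constant `k_SCMCM`, CM→EM at a rate that is high during and shortly
after the expansion and drops to a basal level at `t_persist` (smoothed
step, ~1 day wide) — this switch creates the contraction-to-persistence
transition.

Expansion acts in tissue inside a fixed window (start day 4, duration
7 days, so the blood Tmax lands near day 11):

    SCMexp = ln( xfold_pre · (1 + Emax·IL7^h/(IL7_50^h + IL7^h)) ) / T_exp

CM and EM expand at fixed shares (<1) of SCMexp. All expansion rates
are multiplied by a linear capacity brake `(1 − total/K_safeguard)⁺`
(`K_safeguard = 100 G/L`), preventing supraphysiologic counts.

Allogeneic elimination is second-order mass action between each UCART19
compartment and the *observed blood* host-T concentration (chain plus
expanding pool), applied in blood and tissue, switched off for the
persistent sets. The blood pairing is used on both sides because the
feedback loop holds the tissue host-T chain near its reference even
while blood is suppressed — tissue host T is unobservable and its
near-constancy there is a model artefact, whereas blood host-T exposure
is the clinical correlate of expansion failure. Host T cells are not
consumed by the killing (one-way interaction).

The truncation elimination (two sets) is blood-only at
`k_trunc = 6/day` over the window `[T_exp_start, T_exp_start+T_exp+3]`.
Covering the expansion window is what produces the observed delay
between the end of expansion and Cmax: blood is suppressed while the
tissue system expands almost unaffected, and the circulating peak
appears several days after release. A truncation that only starts when
expansion ends cannot delay the peak, because the pre-truncation blood
peak always exceeds the later rebound. `k_trunc` must exceed the homing
rate to suppress blood meaningfully.

The infused dose is always the nominal 6e6 cells (the lowest study dose
level) split over the three subpopulations by the product composition
and converted to G/L over a 5 L blood volume: the observed absence of
dose-proportionality is deliberately not modelled mechanistically.

## Population model and calibration

The registry declares 51 population parameters: 18 freely estimated and
23 carrying lognormal inter-individual variability (IIV, specified as
% CV and converted by `ω = sqrt(ln(1+(CV/100)²))`). Study-reported
values are used verbatim: alemtuzumab CL/V1/V2/Q = 0.96/3.74/6.01/3.51
(IIV 130/48/71/3858%), FC kill rates 2 and 0.75 /day/FC (NK/T, fixed),
alemtuzumab kill rates 0.334 (IIV 90%) and 1.253 (IIV 66%) mL/µg/day,
IL7IncrMax 9.7 (IIV 42%), hostTLDP50 10 (fixed, IIV 66%), final
baselines with IIV 1800% and NK-pool magnitude with IIV 1945%. A
parameter flagged "fixed" still receives its η when it has variability
(hostTLDP50 is the printed example of exactly that combination).

Everything not reported is a package calibration, chosen once so that
the simulator reproduces the observed behaviour taxonomy and the
study-level expansion fractions, and frozen:

* `γ_T = 1.0`, `k_trT = 0.1/day`: under alemtuzumab the host-T blood
  level settles where feedback production balances drug kill,
  `b ≈ k_trT·ref/kill`, i.e. at depletion ratios of ~10–100. That is
  exactly the range where the IL-7 stimulus (half-effect at LDP−1 = 10)
  is still graded, so depletion depth — and with it IL-7 — responds to
  the alemtuzumab dose. Much smaller exponents drive every treated
  subject to the same saturated depth and erase the dose-response.
* `IL7_50 = 19 pg/mL`, `h = 8`, `IL7effMax = 28000`, `xfold_pre = 30`:
  the expansion gate. The window IL-7 concentration of a typical
  treated subject sits near `IL7_50`, and the steep Hill term turns the
  between-subject spread of IL-7 (baseline production IIV 40%, IncrMax
  IIV 42%, depletion-depth variability) into a near-bimodal expansion
  outcome. Most of the achievable expansion fold is IL-7-driven, which
  is consistent with the multi-decade contribution of IL-7 to Cmax seen
  in the study's individual decompositions; without IL-7 the intrinsic
  30-fold expansion never outruns elimination.
* `k_allo = 8 (G/L)⁻¹day⁻¹`: small enough not to mask the IL-7 gate
  during deep depletion, large enough that the ~0.1–0.5 G/L of host T
  remaining after an FC-only protocol removes the graft — no-alemtuzumab
  subjects essentially never expand (~1% of draws, vs 0/2 observed).
* Differentiation/elimination: `k_SCMCM = 0.2`, `k_CMEM_high = 0.3`,
  `k_CMEM_basal = 0.01`, `k_elim(SCM/CM/EM) = 0.01/0.02/0.2` per day,
  `t_persist = 25 d`: contraction ~0.3/day, persistence slope
  ~0.03/day (half-life ~3 weeks).
* Homing/egress 2.0 and 0.35 /day for all subpopulations (blood holds
  ~15% of cells at exchange equilibrium).

With this configuration the numerical predictive check over a 26-set
virtual trial yields a mean expansion fraction of ~0.56–0.57 with the
observed 0.61 inside the CI90, ~0.50–0.55 in the 40 mg stratum,
~0.65–0.70 at ≥60 mg, and ~0.01 without alemtuzumab (the replicate
seeds move these by a few points).

## Virtual-study generator

`generate_study` reproduces the trial structure exactly: 26 sets; dose
bands 6e6 (n=6), 6–8e7 (n=12), 1.8–2.4e8 (n=8) cells (uniform within a
band); three F doses on days −7..−5 totalling U(120, 275) mg and three
C doses on days −4..−2 totalling U(2010, 4802) mg; alemtuzumab 40 mg
(n=8), 60 mg (n=5), 1 mg/kg (n=11) in five daily doses from day −7, or
none (n=2); body weight U(50, 100) kg. Five sets lack allogeneic
elimination, two of which are truncated; both flags land only on
alemtuzumab-receiving sets, matching the observed composition. Product
composition is Dirichlet(8, 8, 4) (mean 0.4/0.4/0.2 SCM/CM/EM);
baselines are lognormal around 0.2 (NK) and 0.8 (T) G/L with ω = 0.6.

Sampling schedules are idealisations (the real per-set times are
unavailable): 11 alemtuzumab samples over days −7..14, and cells/IL-7
at baseline, day 0, twice weekly to day 28, then weekly to day 84.
Observations get the residual error of their type (proportional 15% for
alemtuzumab, 25% for cell counts; combined 0.5 pg/mL + 15% for IL-7)
and are censored at the LOQ (0.001 G/L flow cytometry, 0.01 µg/mL
alemtuzumab): below-LOQ rows carry DV = LOQ and CENS = 1.

The generator emulates the *structure* and the model's own stochastic
assumptions, not real-data features such as missed visits, assay
batch effects, site-dependent LOQs, or model misspecification; passing
tests therefore demonstrate internal consistency of the pipeline, not
fidelity to any particular patient.

## Inference

The M3 likelihood gives uncensored rows a Normal log-density and
censored rows log Φ((LOQ − prediction)/SD). Residual SDs are computed
from the observed value (LOQ for censored rows) rather than the
prediction: prediction-weighted SDs make the likelihood of noise-free
data peak away from the generating parameters, because shrinking a
prediction also shrinks its SD.

Individual fits maximise this likelihood (plus optional lognormal
priors, i.e. MAP) over log-parameters with ±4 log-unit box bounds,
L-BFGS-B, and three deterministically jittered starts. The
finite-difference step is 1e-4 in log space — large enough to sit above
the ODE-solver noise floor, which otherwise corrupts the gradient. The
sequential strategy mirrors the study: alemtuzumab PK is fitted per
subject on PK data alone (closed-form fast path), frozen, then the
host/IL-7/UCART19 blocks. Population (SAEM-type) estimation is out of
scope.

Identifiability: CL and V1 are well determined by the 11-sample design;
V2 and Q are weakly identified (about 2.4 terminal half-lives of
sampling, and Q's printed IIV of 3858% reflects the same flatness), so
single-fit recovery of V2/Q can miss by ~50% on unlucky noise draws
while the bias over replicate subjects stays within ±25%.

`sensitivity_rank` perturbs each population parameter one at a time by
a relative step (default ±5%) on the typical subject and ranks by
|Δlog Cmax| + |Δlog AUC| of blood UCART19. The alemtuzumab-PK and FC
blocks are excluded by default: they are fitted sequentially upstream
and would otherwise trivially dominate through exposure. Host-T and
IL-7 parameters dominate the ranking, but the expansion-window
parameters `T_exp` (and at times `T_exp_start`) also rank in the top
ten: with the expansion rate defined as ln(fold)/T_exp, a ±5% duration
change rescales the whole expansion log-gain (≥ ~10 natural-log units
for an observable expansion) by ∓5%, giving `T_exp` an irreducible
sensitivity of order 1. This is a structural property of the chosen
expansion parameterisation, not a calibration accident.

## Numerical choices

* LSODA, `rtol = 1e-7`, `atol = 1e-12`, integrated piecewise between
  forcing discontinuities (dose times, window edges); the segment
  endpoint is always part of `t_eval` so no segment starts from a stale
  state. The UCART19 dose is a state jump at day 0.
* The host production term is floored (`max(tissue, 1e-12)`): under
  deep depletion the states underflow the absolute tolerance, and
  integration noise can otherwise seed a spurious negative branch that
  the feedback amplifies exponentially. Host-T concentrations entering
  the IL-7 ratio and the allogeneic kill are clamped at zero for the
  same reason, and the depletion ratio floors blood at 1e-6 G/L.
* Solved trajectories are clipped at zero before being exposed
  (round-off-scale negatives only).
* Expansion classification uses the scheduled sampling times, not the
  dense solver grid — what flow cytometry could have observed — with a
  strict `> LOQ` rule.
* Problem sizes: the test suite runs the predictive check at 100
  replicates and the monotonicity scans at 8–12 replicates;
  `scripts/acceptance.py` uses 400 replicates. These sizes keep
  Monte-Carlo error on the expansion fraction near ±0.02–0.04 while a
  full run stays in the minutes range; the study-scale reference is
  2,000 replicates and changes the means by less than the replicate
  spread.

## Limitations

* Everything not printed in the main study text is a calibration of
  this package; the true estimated values (supplementary material) may
  differ substantially even where study-level behaviour matches.
* No IL-15, no tumour burden or efficacy coupling, no GvHD, no TMDD for
  alemtuzumab, no effector subpopulation, no covariate effects;
  redosing is handled by treating each infusion as an independent set.
* The numerical predictive check keeps each set's structural flags
  (allogeneic elimination, truncation) fixed at their observed pattern
  by default; resampling them from the mixture is available as an
  option.
* Per-individual MAP is a surrogate for population estimation: shrinkage
  toward typical values biases individual estimates for sparse or
  heavily censored sets.
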