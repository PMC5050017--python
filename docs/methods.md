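# Methods

This note documents the models implemented in `pumpdecay`, the parameter
choices and numerical methods behind them, and what the synthetic-data
generator does and does not emulate.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Reduced models of pump-current decay

All simulations are at 0 mV (the experimental clamp potential); no voltage
dependence is modelled anywhere.

### Peak current

Peak pump current follows simultaneous Na binding to three cytoplasmic
sites, two with equal affinity:

    I_peak(Na) = Imax · (Na/(Na+Kn1))² · (Na/(Na+Kn2))

with Kn1 = 0.5 mM and Kn2 = 4.0 mM.  `Imax` is a free scale (default
1.6 pA/pF, a representative 23 °C value); the binding constants, not the
scale, carry the model content, so tests of the equations never pin
`Imax`.

### Restricted-space depletion

Steady state balances pump efflux against diffusion through a single
barrier of conductance Kdiff (default 0.06 pA·pF⁻¹·mM⁻¹):

    I_peak(Na_ss) = (Na_B − Na_ss)·Kdiff

The root Na_ss ∈ (0, Na_B] is found by Newton iteration with the analytic
derivative, safeguarded by bisection on [0, Na_B]; the residual is strictly
monotone in Na_ss so the bracket is guaranteed.  The default residual
tolerance (1e-12·max(1, Imax), with an x-width fallback at float precision
for extreme barrier conductances) keeps the root accurate to well below
1e-9 relative across three decades of each parameter, which the test suite
verifies against an independent interval-bisection oracle.

The steady-state balance says nothing about kinetics, so the transient
extension adds two pieces of plumbing: a submembrane mixing volume
`v_ss` (default 2 pL, about 10 % of a murine myocyte's cytoplasmic volume
and consistent with the ~2 pL apparent mixing volumes the decay analysis
itself produces) and the cell capacitance `Cm` (default 150 pF).  The
submembrane concentration then obeys

    dNa_ss/dt = kex·(Na_B − Na_ss) − 3000·i(Na_ss)·Cm/(F·v_ss)    [mM/s]

with current density `i` in pA/pF and the barrier exchange rate fixed by
requiring the fixed point to coincide with the steady-state root:
`kex = 3000·Kdiff·Cm/(F·v_ss)`.  With the defaults kex ≈ 0.14 s⁻¹
(τ ≈ 7 s), a multi-second relaxation in the observed range.  During K-free
epochs the pump term vanishes and Na_ss relaxes back to Na_B through the
same barrier.  Integration uses LSODA at rtol 1e-10; the long-time current
equals the steady-state solution to better than 1e-6 relative (tested for
random parameter sets).

### E1-state inactivation

The fraction of pumps whose Na-selective site is vacant is
`Fo = Kn2/(Kn2+Na)`.  Pumps inactivate at `ki·Fo` (ki = 1 s⁻¹) and recover
at `kr_cycling` = 0.3 s⁻¹ while cycling, so availability obeys

    da/dt = kr_cycling·(1 − a) − ki·m(t)·Fo·a        (K present)
    da/dt = kr_rest·(1 − a)                          (K absent)

and the emitted current is `I_peak(Na_i)·a(t)`.  The steady-state ratio
`I_ss/I_peak = kr/(kr + ki·Fo)` reduces to `0.3/(Fo + 0.3)` at the default
rates.  `kr_rest` (default 0.05 s⁻¹) is separate plumbing: the cycling
recovery rate of 0.3 s⁻¹ is inconsistent with the ~20 s recovery of
current availability and capacitance observed after K removal, so rest
recovery gets its own configurable constant.

**Ca modulation.**  A transient cytoplasmic Ca elevation multiplies the
inactivation rate scale by

    m(t) = 1 + (m_min − 1)·exp(−(t − t_Ca)/τ_Ca),     τ_Ca = 150 s

from the end of the Ca episode, and optionally resets availability to
`a_reset` (default 1) at that moment.  One multiplicative mechanism thus
produces both post-Ca signatures — the enhanced peak (via the reset) and
the attenuated decay (via the depressed ki) — and their joint reversal on
the ~150 s time scale of the observed relaxation.  Setting `m_min = 1`
with `a_reset = None` makes the Ca episode a no-op, which the tests use as
the null control.

**Integration.**  Within any span where the coefficients are constant the
solution is a single exponential, and the integrator uses exactly that
propagator (vectorised per epoch), so it agrees with the closed form to
machine precision.  When the Ca modifier is active, the integrator steps
sample by sample with the modifier frozen at each step midpoint; since
τ_Ca ≫ dt the committed error is far below the 1e-6 contract that the
tests enforce on constant-coefficient epochs.

### Coupled pump/exchanger pool model

A deliberately conservative bookkeeping model for pump/exchanger
cross-talk: one well-mixed cytoplasmic pool of volume V_cyto (default
3 pL), a pump with hyperbolic Na dependence `Imax_abs·Na/(Na + K50)`
(K50 = 5 mM), and a Na/Ca exchanger delivering 3 Na per elementary charge
at a fixed current equal to 30 % of the pump current at the initial pool
Na.  The pool evolves as

    dNa/dt = 1000·3·(I_ncx·on − I_pump(Na))/(F·V_cyto) + k_pip·(Na_pip − Na)

with currents in pA and volume in pL.  The exchanger reference current is
evaluated at the initial pool Na before integration: a literal
"first-K-epoch peak" definition would be circular whenever the exchanger
pre-loading epoch precedes the first K epoch, which is exactly the
schedule of interest.  The pipette source term defaults to off
(k_pip = 0).  The model's qualitative prediction — exchanger pre-loading
must raise the subsequent K-evoked peak if both transporters share the
pool — is what the experiments contradict, and the simulation exists to
make that prediction explicit.

## Post-Albers cycle simulator

The cycle is reduced to five kinetic states plus the inactive pool:
E1 → E1P(Na3) → E2P → E2P·K2 → E2(K2) → E1, with E1 ↔ Inactive as a side
branch.  Design choices:

- **Rapid-equilibrium binding.**  Na and K binding are occupancy factors,
  not states: cytoplasmic Na enters through the three-site product and the
  vacant-site fraction Fo; extracellular K through a two-site occupancy
  with K_K = 1.5 mM, competitively inhibited by extracellular Na with
  Kd = 2.3 mM (the rescue constant measured for pump-current restoration
  by low extracellular Na).  No binding kinetics are available to
  constrain explicit states, and the reduction keeps the generator 6×6.
- **Electrogenic step.**  The charge-carrying transition is the
  E1P(Na3) ↔ E2P deocclusion; the emitted current is `i_unit` times that
  step's net flux.  At a fixed 0 mV the current must be proportional to
  one step's net flux, and deocclusion to the outside is the natural
  assignment.
- **Reverse limb gating.**  E2P → E1P requires extracellular Na to reload
  the sites (third-power occupancy, Kd 40 mM) *and* ADP occupancy
  (Kd 0.5 mM) for the subsequent dephosphorylation reversal; with ADP = 0
  the reverse limb is off.  This is what lets an extracellular-Na
  pre-pulse drive pumps into E1 — and therefore into the inactive pool —
  only under ADP-generating conditions, reproducing the reduced K-evoked
  peak after Na pre-incubation (the ratio is ~0.8 with the defaults;
  the check is sign-only).
- **Contaminating K.**  Nominally K-free solutions carry 10 µM K
  (configurable); this sustains the slow cycling that lets pumps
  inactivate in Na-free, K-free solutions.
- **Ouabain** blocks the extracellular K-binding step bidirectionally,
  which removes the only cycle through the network, so the steady-state
  flux is exactly zero.
- **Default rates** (80, 600, 2000, 1000, 800 s⁻¹ forward; 500, 600, 50,
  0.05, 1 s⁻¹ backward; entry ki = 1 s⁻¹·Fo, recovery 0.3 s⁻¹) are a
  documented tuning, not a fit: they give ~51 s⁻¹ turnover at saturating
  ligands (target range 50–300 s⁻¹), current activation within ~10 ms of
  K application, a ~2.5 s decay time constant at 25 mM cytoplasmic Na,
  E2P accumulation (>95 %) in K-free solution, and steady availability
  within 10 % of the reduced inactivation model when the entry/recovery
  rates coincide.  Making the E1 → E1P step rate-limiting is what keeps
  the cycling pool concentrated in E1, so that entry into the inactive
  pool approximates the reduced model's ki·Fo.
- **Thermodynamic consistency.**  `with_detailed_balance()` rescales the
  reverse dephosphorylation rate so the Kolmogorov loop criterion holds at
  a collapsed-gradient reference condition (Na_i = Na_o, K present,
  ATP = ADP); the steady-state cycle flux then vanishes there, which the
  suite verifies.  The default table is used for phenotype simulations;
  the balanced table exists to demonstrate the construction.
- **Integration** is per-epoch matrix exponentials (the generator is
  constant within an epoch), so occupancy conservation holds to ~1e-12
  over 100 s simulations against a 1e-8 contract.
- Entry from E2 states is not modelled (no rates are known for it), and
  Na-assisted recovery from the inactive pool is an optional switch,
  default off.

## Trace model and feature extraction

Traces are uniform-dt series of capacitance-normalised current (pA/pF)
with an optional capacitance column; CSV files carry metadata as
`# key=value` comment lines with JSON-encoded values and round-trip
bitwise.

Per K epoch the extractor measures, with configurable windows:

- baseline: mean over the 1 s preceding the epoch;
- peak: maximum baseline-subtracted current in the first 0.5 s (currents
  activate within solution-switch times, so the peak sits at the front;
  no published extraction windows exist, so these are declared defaults);
- plateau: 0.5 s mean centred on `t_plateau` (default 10 s) — a window,
  not a point sample, for noise robustness;
- fractional decay `F_decay = 1 − I_plateau/I_peak`;
- a single-exponential fit `I_inf + (I_0 − I_inf)·e^(−t/τ)` from the
  detected peak to the epoch end, asymptote bounded ≥ 0;
- initial fractional decay rate `k_init = (I_0 − I_inf)/(τ·I_0)`.

Epochs with no measurable current yield features flagged undefined rather
than exceptions, so batch analyses survive flat or ouabain-blocked
records.

## Fitting and statistics

Hill fits (`y_max·Na^h/(Na^h + K50^h)`) are least squares in linear
response space with non-negative bounds — matching how
concentration-response data are usually presented, with no weighting
scheme to justify anything else.  Standard errors come from the fit
covariance; aggregation across cells is the caller's responsibility.  The
fractional-decay hyperbola `Kd/(Kd + Na)` is the one-site vacancy
description; fitting it to the three-site inactivation model's predictions
yields a well-defined Kd with systematic residuals, which is reported, not
hidden.  The two-point rescue hyperbola is solved exactly:
`Kd = Na₁Na₂(y₂ − y₁)/(y₁Na₂ − y₂Na₁)` for baseline-subtracted currents,
symmetric in the points, with domain errors for flat or non-saturating
configurations.  The outlier rule removes values more than two sample
standard deviations from the mean in a single pass (mean and SD computed
once on the full set; no iteration is specified, so none is done).

## Bookkeeping

Fixed constants: e = 1.602176634e-19 C, N_A = 6.02214076e23 /mol,
F = e·N_A.  The four operations are pure unit-explicit functions:

- mixing volume `V = 3·h·I/(F·k_init·Na)` (nA, mM, s⁻¹ → pL), with `h`
  the local log-slope of the Na-current relation (~2 in the relevant
  range; caller-supplied);
- ATP per liter `I·t/(F·V)` (one ATP per elementary charge per cycle);
- ion totals `stoich·∫|I|dt/(F·V)`;
- pump density `i_area/(turnover·e)` with
  `i_area = current density × specific capacitance` (default 1 µF/cm²,
  which the source text never states), plus the circular-footprint area
  fraction.

With 4 pA/pF, 300 s⁻¹ and 1 µF/cm² the density computes to ≈832 µm⁻²
(0.8 % area fraction at 3.5 nm diameter), not the ">2000 µm⁻²" sometimes
quoted; reproducing that figure requires an unstated specific capacitance
or active fraction, so the operation reports the computed value and this
note records the discrepancy.

The mixing-volume/transient round trip (simulate a depletion transient at
known v_ss, extract k_init, invert) recovers the volume within 10 % only
in the small-depletion regime; at strong depletion the decay is visibly
non-exponential (the local Hill slope steepens as Na falls), the fitted
rate overestimates the initial rate, and the volume is underestimated.
The tests therefore probe the regime the formula is derived for
(Imax = 0.8 pA/pF, Na_B = 40 mM, ~8 % decay), where recovery is ≈6 % low.

## Buffers and dye calibration

Free Ca in EGTA/Ca mixes is the exact positive root of the 1:1 binding
quadratic (numerically stable form), valid also for over-titrated mixes.
The apparent Kd is caller-supplied (default 0.15 µM at pH 7.4): the two
printed recipe/free-Ca pairs (25/6 mM → ~0.2 µM; 50/35 mM → 0.5 µM) imply
*different* apparent constants, so no single default can reproduce both
and no Mg/H multi-equilibrium engine could be verified against the
available numbers — a deliberate scope cut.

The dye model is minimal 1:1 binding with zero Ca-free fluorescence:
`F/F0` saturates at `(Ca_rest + Kd)/Ca_rest` = 3.3077 with Kd = 0.3 µM
and resting Ca = 0.13 µM.  A reported 3.7-fold fluorescence rise exceeds
that bound, so inverting it *must* fail, and the inversion raises an
explicit saturation error naming the bound rather than silently producing
a peak-Ca value; whatever formula produced the published 2.7 µM peak was
not the single-site model, and the package does not guess at it.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:
square solution-switch protocols; peak-then-exponential-decay currents
whose fractional decay depends on cytoplasmic Na; slow availability
recovery after K removal; capacitance steps of ~−0.7 % during K
application, a coupling of capacitance to availability (so its recovery is
an affine image of the availability time course), and a +4 % post-Ca rise
relaxing over 150 s; additive white Gaussian current noise; and optionally
a relative hydrophobic-ion probe signal tracking availability.  Trace
metadata always embeds the full generating truth, and tests compare
against metadata, never against re-typed numbers.

It does **not** emulate: coloured noise or line interference, seal and
leak drift, series-resistance and filtering artifacts, cell-to-cell
parameter scatter, Ca-wave spatial dynamics, or exchanger regulatory
kinetics.  Passing recovery tests therefore demonstrates correctness of
the pipeline under the stated noise model, not robustness to every
pathology of real recordings.

Titration noise is multiplicative (each sample scaled by
`1 + 0.05·N(0,1)` at the 5 % setting), replicating roughly
current-proportional scatter; because the peak is a windowed maximum, this
inflates all peaks by a common factor and leaves K50 and h recovery
unbiased, which the recovery tests confirm (median K50 within 10 %, h
within 20 %, over 100 seeded replicates).

**Solution-switch filtering.**  Protocols carry a switch time constant
(0.1 s) as metadata, but the generator emits unfiltered model currents by
default: a 0.1 s low-pass distorts the extracted peak of a τ ≈ 2 s decay
by far more than the declared recovery tolerances, and the recordings
being emulated activate within the switch time.  The filter is applied
where it matters physically — suppressing the sub-switch-time
state-redistribution spike of the cycle simulator in the Na-pre-pulse
comparison — and is available as an explicit option elsewhere.

**Control-row preset.**  The Ca-elevation preset is derived, not fitted,
from the control-row pattern of the standard protocol (pre peak 100,
10 s 35; post peak 154, 10 s 111, at 25 mM Na): the post/pre peak ratio
fixes the pre-epoch availability a₀ = 0.65 with a post-Ca reset to 1; the
pre fractional decay 0.65 then gives ki = kr·(1 − 0.2275)/(0.2275·Fo) =
7.385 s⁻¹; and the modifier floor m_min is calibrated by bisection on the
noiseless forward model so the extracted post-epoch decay equals 0.279,
because the modifier relaxes appreciably (τ = 150 s) between the Ca
episode and the 10 s measurement and plain steady-state algebra would
overstate its effect.  The preset protocol uses a 5 s gap between the Ca
episode and the post pulse so that a sub-unity modifier floor exists; all
three printed observables (0.65, 0.28, 154 %) are then reproduced through
the full extraction pipeline.  These numbers are a fixture derivation, not
a mechanistic claim.

## Model comparison

`compare_models` fits each candidate's free parameters — (Imax, Kdiff) for
depletion, (Imax, ki) for inactivation, binding constants fixed at the
shared defaults — jointly to peak and plateau currents over a Na grid by
equally weighted least squares, and ranks by AIC = n·ln(RSS/n) + 2k.  AIC
rather than BIC: the candidate set is tiny and the fits continuous, and
both criteria rank identically in the self-consistency tests (each model
wins on features it generated, both directions).  Equal peak/plateau
weights are declared, not derived; no weighting guidance exists.

## Problem sizes

Defaults keep everything light: dt = 10 ms for reduced-model traces, 5 ms
for the cycle; 100 replicates × 8 concentrations (dt = 20 ms) for the
recovery studies; a 27-point, three-decade grid for the solver/oracle
comparison.  The full test suite runs in well under a minute and the
acceptance script in a few seconds on one CPU.

## Known limitations

- No temperature model: 23 °C vs 37 °C are separate parameter sets, not an
  Arrhenius law.
- No E2-state inactivation pathway and no stochastic single-pump
  simulation.
- The cycle rate table is illustrative; absolute rate constants were never
  fitted to data and only the documented qualitative targets are defended.
- The buffer model is single-ligand; pH/Mg/ATP speciation is out of scope.
- Hydrophobic-ion probe coupling in the generator is phenomenology only.
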