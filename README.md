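# pumpdecay

Quantitative models and analysis tools for the decay of cardiac Na/K-pump
current during extracellular K application.

## The problem

In whole-cell patch-clamped cardiac myocytes at submaximal cytoplasmic Na,
the outward Na/K-pump current evoked by extracellular K peaks and then
decays by more than half within seconds, recovering only slowly after K
removal.  Two mechanisms can produce this pattern:

1. **Restricted-space Na depletion** — pumping drains Na from a small
   subsarcolemmal ("fuzzy") compartment faster than diffusion from the bulk
   refills it;
2. **E1-state inactivation** — pumps whose Na-selective third binding site
   is vacant enter a long-lived non-cycling pool, and cytoplasmic Ca
   transients modulate that entry.

This package implements both models side by side, together with everything
needed to confront them with patch-clamp data: a Post-Albers cycle
simulator with an inactive pool, trace feature extraction (peak, plateau,
fractional decay, decay kinetics), Hill/hyperbola fitting, charge and mass
bookkeeping, Ca-EGTA buffer and Fluo-4 dye calibration, and a seeded
synthetic-trace generator so every pipeline stage is testable without raw
recordings.  It is aimed at electrophysiologists analysing pump-current
records and at modellers comparing transporter-inactivation hypotheses.

## The models

Peak current follows simultaneous Na binding to three cytoplasmic sites,
two of equal affinity:

    I_peak(Na) = Imax · (Na/(Na+Kn1))² · (Na/(Na+Kn2)),   Kn1 = 0.5 mM, Kn2 = 4 mM

**Depletion.**  At steady state the pump flux through the membrane equals
the diffusive flux through a single barrier of conductance
Kdiff (0.06 pA·pF⁻¹·mM⁻¹):

    I_peak(Na_ss) = (Na_B − Na_ss) · Kdiff

solved for the submembrane concentration Na_ss by safeguarded Newton
iteration.  A time-dependent extension with an explicit mixing volume v_ss
shares the same fixed point.

**Inactivation.**  The vacant-site fraction is Fo = Kn2/(Kn2+Na); pumps
inactivate at ki·Fo (ki = 1 s⁻¹) and recover at kr = 0.3 s⁻¹ while
cycling, so availability relaxes to kr/(kr + ki·Fo) and

    I_ss / I_peak = 0.3 / (Fo + 0.3)

A transient Ca elevation multiplies ki by a factor that relaxes back to 1
over ~150 s, reproducing both the enhanced peak and the attenuated decay
seen after Ca-influx episodes.

## Worked example

Generate a noisy synthetic K-pulse recording at 25 mM cytoplasmic Na,
extract its features, and let both models compete on a Na titration:

```python
from pumpdecay import *

proto = make_protocol("standard_k_pulse")           # 10 s Na -> 12 s K -> 10 s Na
cfg = SynthConfig(model="inactivation", seed=42, na_i_mM=25.0, noise_sd=0.05)
trace = synth_trace(cfg)
feats = extract_features(trace, proto, t_plateau=10.0).epochs[0]
print(f"peak current      : {feats.I_peak:.3f} pA/pF")
print(f"10 s plateau      : {feats.I_plateau:.3f} pA/pF")
print(f"fractional decay  : {feats.F_decay:.3f}")
print(f"decay tau         : {feats.exp_fit.tau_s:.2f} s")

fo, a_ss, ratio = inactivation_steady_state(25.0, InactivationParams())
print(f"model prediction  : Fo={fo:.3f}, steady/peak={ratio:.3f}, F_decay={1-ratio:.3f}")

df = synth_na_titration("inactivation", [2.5, 5, 10, 15, 20, 25, 30, 40],
                        reps=1, seed=7)
report = compare_models(df)
print("model ranking     :", report.ranking)
```

prints

```
peak current      : 1.373 pA/pF
10 s plateau      : 0.911 pA/pF
fractional decay  : 0.337
decay tau         : 2.31 s
model prediction  : Fo=0.138, steady/peak=0.685, F_decay=0.315
model ranking     : ['inactivation', 'depletion']
```

The extracted fractional decay (0.337 under 5% noise) scatters around the
closed-form prediction 0.315; the exponential time constant matches the
model's 1/(kr + ki·Fo) = 2.28 s; and on features it generated itself, the
inactivation model wins the AIC ranking over the depletion model — the
self-consistency check the comparison driver is built around.

The same operations are available from a shell:

```sh
pumpdecay simulate --model inactivation --seed 7 --out trace.csv
pumpdecay analyze --in trace.csv --plateau 10
pumpdecay metrics atp --i-pA 300 --duration-s 10 --vol-pL 20
pumpdecay calib free-ca --egta-mM 50 --ca-mM 35 --kd-uM 0.21
```

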