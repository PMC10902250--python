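# ldp-insilico

An in silico clinical trial of **lung- and diaphragm-protective (LDP)
ventilation** in acute respiratory failure, for researchers studying
patient-ventilator interaction, ventilation/sedation titration strategies,
and patient selection for extracorporeal CO2 removal (ECCO2R).

Mechanical ventilation can injure both the lung (excessive distending
pressure) and the diaphragm (over- or under-assistance). The LDP strategy
targets, jointly,

- dynamic transpulmonary driving pressure ΔP_L,dyn < 15 cmH2O,
- esophageal pressure swing |ΔPes| between 3 and 8 cmH2O, and
- pH > 7.25.

Whether these targets are jointly achievable — and for whom only with
extracorporeal help — is hard to study in patients. This package answers it
in silico: thousands of virtual patients, each a steady-state physiological
model, are pushed through a pre-defined titration algorithm in different
ventilation modes, with or without ECCO2R.

## The model in brief

Each virtual patient closes a feedback loop solved by bisection for its
unique operating point P_mus*:

    P_mus  →  Vt = (P_vent + max(0, P_mus − PEEPi)) / E_dyn        (mechanics)
    Vt     →  V̇A = RR·max(0, Vt(1 − f_ADS) − V_Danat)             (dead space)
    V̇A    →  PaCO2 = 0.863·V̇CO2·(1 − φ)/V̇A                      (CO2 balance)
    PaCO2  →  P_mus = max( m·G·(PaCO2 − B),  wakefulness demand )  (drive)

with E_dyn the elastance augmented by a breath-averaged resistive load,
P_vent the mode-dependent assistance (fixed PS in PSV; a fraction k of
elastic recoil in PAV+), m the propofol Hill attenuation, φ the fraction of
V̇CO2 removed extracorporeally, and pH from PaCO2 and the strong ion
difference by a Stewart physicochemical balance. Populations are sampled
from published cohort distributions; the two unobservable controller
parameters (chemoreflex gain G, apneic threshold B) are calibrated so the
simulated baseline means reproduce the cohort's computed row. See
`docs/methods.md` for the full model, parameters, and design choices.

## Worked example

```python
from ldp_insilico import sample_population, solve_steady_state, run_titration
from ldp_insilico.titration import initial_settings

patient = sample_population(n=40, seed=42)[19]
state = solve_steady_state(patient, initial_settings("psv"))
print(f"baseline: Vt {1000*state.vt:.0f} mL, PaCO2 {state.paco2:.1f} mmHg, "
      f"pH {state.ph:.2f}, |dPes| {state.dpes:.1f}, dPL,dyn {state.dpl_dyn:.1f} cmH2O")

result = run_titration(patient, initial_settings("psv"))
print(f"{result.status} after {result.iterations_used} iterations at "
      f"PS {result.final_settings.ps:.0f} cmH2O, "
      f"propofol {result.final_settings.propofol:.0f} mcg/kg/min")
final = result.final_state
print(f"final: |dPes| {final.dpes:.1f}, dPL,dyn {final.dpl_dyn:.1f} cmH2O, "
      f"pH {final.ph:.2f}")
```

prints

```
baseline: Vt 505 mL, PaCO2 35.6 mmHg, pH 7.45, |dPes| 5.9, dPL,dyn 15.9 cmH2O
treatment_success after 5 iterations at PS 8 cmH2O, propofol 40 mcg/kg/min
final: |dPes| 6.9, dPL,dyn 14.9 cmH2O, pH 7.39
```

This patient breathes comfortably at baseline (effort in the 3–8 cmH2O
band, pH fine) but the lung-distending pressure is just above the 15 cmH2O
limit, so the algorithm trades support down and sedation up until all three
targets hold — a "treatment success". Patients in-target at baseline are
"primary successes"; patients still failing after 20 iterations are
candidates for escalating ECCO2R.

The full trial, from a shell:

```bash
ldp-insilico run --config cfg.yml --out results/   # 5 arms × replicates
ldp-insilico sample --n 5000 --seed 1 --out population.csv
ldp-insilico analyze --patients results/patients.csv \
    --population results/population.csv --out analysis/
```

`run` writes per-arm and per-replicate success proportions with Wilson 95%
CIs, arm odds-ratio contrasts, and the per-patient outcome table; `analyze`
writes the random-forest variable importances, the three-variable logistic
model, ROC points, and success stratified by the ECCO2R score (normalised
respiratory-system elastance + ventilatory ratio).

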