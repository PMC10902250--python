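# Methods

`ldp-insilico` simulates an in silico clinical trial of lung- and
diaphragm-protective (LDP) ventilation in acute respiratory failure. Every
virtual patient is a steady-state model of patient-ventilator interaction;
the trial layer titrates ventilator support and sedation against the three
LDP targets, escalates extracorporeal CO2 removal (ECCO2R) in failures, and
the statistical layer asks which patient characteristics predict success.

## The patient model

Each patient is a closed feedback loop solved at its operating point. All
quantities are breath-averaged steady-state amplitudes; there is no
intra-breath waveform, no PEEP titration, no hypoxic drive, and respiratory
rate is fixed per patient.

**Mechanics.** Muscle pressure in excess of intrinsic PEEP (a threshold
load) plus ventilator pressure drives tidal volume against the dynamic
elastance

    E_dyn = E_rs + R_rs * RR / (60 * f_insp),    E_rs = E_lung + E_cw,

where the second term is the breath-averaged resistive load: with mean
inspiratory flow Vt / (f_insp * 60/RR), resistive pressure is proportional
to Vt and folds into an elastance. `f_insp` (default 2/3) is the effective
mean-flow fraction of the breath. Setting `R_rs = 0` recovers the purely
quasi-static model.

- PSV: `Vt = (PS + max(0, Pmus - PEEPi)) / E_dyn`, airway swing
  `dPaw = PS`.
- PAV+: the ventilator delivers the fraction `k` of the elastic recoil,
  `dPaw = k * E_rs * Vt`, while the patient carries the resistive load:
  `Vt = max(0, Pmus - PEEPi) / (E_dyn - k * E_rs)`. In the resistance-free
  limit this is the familiar 1/(1-k) amplification of patient pressure.

The esophageal swing magnitude is `|dPes| = max(0, Pmus - E_cw * Vt)` and
the dynamic transpulmonary driving pressure is `dPL,dyn = dPaw + |dPes|`
(resistive component included, matching the clinical "dynamic" definition).

**Gas exchange.** The alveolar dead-space fraction wastes that share of
each breath and the anatomical dead space is lost per breath:

    VA = RR * max(0, Vt * (1 - f_ADS) - VD_anat),
    PaCO2 = 0.863 * VCO2 * (1 - phi) / VA,

capped at 150 mmHg when VA cannot clear the dead space. ECCO2R removes the
fraction `phi` (up to 0.9) of metabolic CO2 production before the lungs see
it. The fraction-of-Vt dead-space convention was chosen because it is the
only one consistent with the target cohort's paired minute ventilation
(15.6 L/min) and PaCO2 (35 mmHg), which imply a total dead-space fraction
near 65%.

**Acid-base.** A simplified Stewart (physicochemical) balance with fixed
total weak acid (Atot = 12 mEq/L, pKa 6.65 — a hypoalbuminemic ICU
default): electroneutrality `SID = [HCO3-] + [A-]` with
`[HCO3-] = 0.0301 * PaCO2 * 10^(pH - 6.1)`. The residual is strictly
decreasing in pH, so bisection on [6.5, 7.9] finds the unique root to
1e-6; roots outside the bracket return the boundary with a flag.

**Control of breathing.** Demanded muscle pressure is the larger of

- the linear chemoreflex `m * G * (PaCO2 - B)`, with per-patient gain `G`
  and apneic threshold `B`, attenuated by the sedation multiplier `m`, and
- the wakefulness drive: an awake subject demands a minimum tidal volume
  (4.6 mL/kg predicted body weight, below the normal resting 6-8 mL/kg),
  converted into the muscle pressure needed for that volume under the
  current assistance and scaled by the same sedation multiplier,

clamped to [2, 50] cmH2O. The volume-demand form of wakefulness matters in
the unsupported (awake ECCO2R) arm: patients with stiff respiratory systems
or large dead space must generate large pressures for even minimal
ventilation, no matter how much CO2 the circuit removes, while the
assistance term lets ventilated arms off-load that demand.

**Sedation.** Propofol at a steady infusion reaches an effect-site
concentration `Ce = rate * weight / CL` (CL = 1800 mL/min) and attenuates
drive by a Hill curve `m = 1 / (1 + (Ce/C50)^2)`. C50 = 1.5 mcg/mL, on the
scale of published ventilatory-depression potencies; the baseline cohort
row cannot identify C50 because the initial 20 mcg/kg/min barely attenuates
drive at any plausible value, so C50 is pinned rather than searched by
default.

**Steady state.** The loop residual `f(Pmus) = Pmus - drive(PaCO2(Pmus))`
is strictly increasing and brackets zero by construction, so bisection
always converges (tolerance 1e-4 cmH2O, uniqueness property-tested and
cross-checked against a damped Picard iteration).

## Virtual population

Fourteen patient-level parameters are sampled independently (the source
cohort reported no correlations) by inverse-CDF transforms of one seeded
uniform stream: truncated normals at the published mean/SD with bounds
mean ± 3 SD clipped to physical floors, except chest wall compliance
(mean 125, SD 180 mL/cmH2O forces skew), which uses a moment-matched
lognormal truncated to [40, 600] mL/cmH2O — truncation raises its realised
mean ~15% above the nominal; the realised moments are asserted in tests.
Sex is Bernoulli(0.49 female); predicted body weight is Devine from sex
and height, floored at 30 kg; PaO2 and age are sampled but unused by the
model (no hypoxic drive term).

Two controller parameters are not observable and not in the published
table: chemoreflex gain (lognormal, geometric SD 1.6, bounds [0.3, 8]
cmH2O/mmHg) and apneic threshold (normal, SD 4, bounds [25, 45] mmHg).
Their location parameters are free and set by calibration:
`calibrate_constants` grid-searches (gain median in 2.4-4.0, threshold mean
in 22-30 mmHg) minimising the summed squared relative error of the
simulated population means (PaCO2 35 mmHg, Vt 568 mL, |dPes| 9 cmH2O,
pH 7.44, dPL,dyn 18 cmH2O) on baseline pressure support (PS 10, propofol
20). Each patient's controller values are relocated along their own
marginal quantiles, so the search introduces no new randomness and is
deterministic. The optimum is interior to the grid and achieves all five
means within ~6%.

## Titration algorithm

Targets: dPL,dyn < 15 cmH2O (strict), |dPes| in [3, 8] cmH2O (inclusive),
pH > 7.25 (strict). Patients in-target on initial settings (PSV 10 cmH2O
or PAV+ 50%, propofol 20 mcg/kg/min) are primary successes. Otherwise one
lever moves per iteration, first matching rule wins (priority acidosis >
high effort > low effort > high lung pressure):

| condition | move | fallback at lever bound |
|---|---|---|
| acidosis and low effort | propofol -10 | none |
| acidosis | support +step | none |
| high effort and high lung pressure | propofol +10 | none |
| high effort | support +step | propofol +10 |
| low effort | support -step | propofol -10 |
| high lung pressure | support -step | propofol +10 |

Steps: PS 2 cmH2O on [0, 20]; PAV+ gain 0.1 on [0.2, 0.8]; propofol
10 mcg/kg/min on [0, 80]. Success after >= 1 move is a treatment success;
failure is declared after 20 iterations or as soon as every indicated move
is bound-blocked (no-move). For failures, ECCO2R escalates in steps of 10%
of VCO2 up to 90%, restarting the titration from the initial settings at
each level and halting at the first success. The awake-ECCO2R protocol
fixes PS = 0 and propofol = 0, applies no titration, and sweeps the removal
fraction 0-90%.

## Trial and statistics

A replicate samples a fresh population (per-replicate seeds spawned from
the master seed via `SeedSequence`) and pushes the same population through
all five arms; escalation arms reuse the plain arm's results and
re-simulate only its failures (identical by determinism). Proportions carry
Wilson score intervals (better near 0/1 than Wald, which is also reported);
across-replicate variability uses a t-interval on replicate proportions;
arm contrasts are odds ratios with Woolf CIs (0.5 continuity correction on
zero cells), which coincide with exponentiated two-arm logistic
coefficients (tested).

Determinants of success (label: success in the plain PSV arm) are ranked by
random-forest permutation importance — 500 trees, default depth, fit on a
seeded half of the table and scored by accuracy drop on the held-out half
(held-out scoring keeps uninformative features at zero importance). The
feature set is the bedside-measurable characteristics plus baseline
ventilatory ratio; latent controller parameters and the two dead-space
parameters are excluded (the latter are clinically unmeasured and enter
practice only through the ventilatory ratio). The top three feed a
maximum-likelihood logistic model (perfect separation flagged and refit
with an L2 penalty); discrimination is the C-statistic computed by the
Mann-Whitney midrank identity. The ECCO2R score is normalised elastance
plus ventilatory ratio, `E_rs * PBW / 1000 + VR`; the per-mL/kg-PBW
normalisation puts elastance on the same ~1-4 numeric scale as VR so the
unweighted sum keeps both terms influential. Success with and without
ECCO2R rescue is stratified by score bins (default width 0.5; empty bins
are reported missing, not zero).

## Numerical and design notes

- Problem sizes: the acceptance script calibrates on 2000 patients and
  runs 5000 patients through all arms (~1 minute single-core); the test
  suite's trial-level checks use an 800-patient calibration sample and a
  2000-patient trial.
- Tolerances: pH bisection 1e-6; effort bisection 1e-4 cmH2O; PaCO2 cap
  150 mmHg and Pmus cap 50 cmH2O bound degenerate patients.
- Known limitations: no intra-breath dynamics, trigger/cycling asynchrony,
  PEEP effects, O2 transport, CO2 stores, or transient propofol kinetics;
  fixed respiratory rate overestimates required tidal volume when demand
  rises; parameters are sampled independently, so real-world correlations
  (e.g. dead space with mechanics) are absent. The generator reproduces the
  published cohort's marginal moments, not any joint structure, so passing
  tests certify the model under independence, not on real patients.
- In this reconstruction, respiratory rate and strong ion difference are
  statistically tied as the third-ranked determinant of success behind lung
  compliance and ventilatory ratio; the rate's influence flows through both
  alveolar ventilation and the rate-dependent resistive load.
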