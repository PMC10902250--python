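"""Steady-state physiology of patient-ventilator interaction.

The model closes a single feedback loop per patient: respiratory muscle
pressure (Pmus) generates tidal volume through quasi-static mechanics and
the ventilator's assistance; tidal volume sets alveolar ventilation after
anatomical and alveolar dead space; alveolar ventilation sets PaCO2 through
a CO2 mass balance (with any extracorporeal removal subtracted from
metabolic CO2 production); and PaCO2 drives Pmus through a linear
chemoreflex attenuated by propofol sedation and floored by the wakefulness
drive.  The operating point is the unique root of this loop, found by
bisection.  Acid-base status follows from PaCO2 and the strong ion
difference via a simplified Stewart (physicochemical) equilibrium.

All quantities are steady-state, breath-averaged amplitudes: there is no
intra-breath waveform, no PEEP titration, and respiratory rate is fixed per
patient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

from .errors import ConfigurationError, ValidationError
from .population import PatientParameters

__all__ = [
    "ModelConstants",
    "VentilatorSettings",
    "PatientState",
    "sedation_effect",
    "chemoreflex_drive",
    "dynamic_elastance",
    "wakefulness_floor",
    "tidal_and_pressures",
    "alveolar_gas",
    "stewart_ph",
    "ventilatory_ratio",
    "solve_steady_state",
    "calibrate_constants",
    "CalibrationResult",
    "TABLE1_BASELINE_TARGETS",
]


@dataclass(frozen=True)
class ModelConstants:
    """Model-level constants (patient-independent).

    k_gas       gas-exchange constant, mmHg * L/min per mL/min CO2 (0.863)
    atot        total weak acid concentration, mEq/L (hypoalbuminemic ICU default)
    pka_a       effective weak-acid pKa
    pk_hh       Henderson-Hasselbalch pK for the CO2/bicarbonate pair
    s_co2       CO2 solubility, mmol/(L * mmHg)
    cl_prop     propofol clearance, mL/min
    c50         effect-site propofol concentration halving drive, mcg/mL
    gamma       Hill exponent of the sedation-inhibition curve
    pmus_min    absolute floor of muscle pressure, cmH2O
    pmus_max    physiological ceiling of muscle pressure, cmH2O
    paco2_cap   PaCO2 ceiling for degenerate (zero alveolar ventilation) states
    insp_frac   effective mean-flow fraction of the breath used to convert
                tidal volume into a breath-averaged resistive pressure
    wake_vt_ml_kg  minimum tidal volume (mL per kg predicted body weight)
                demanded by the wakefulness drive regardless of CO2 stimuli
    """

    k_gas: float = 0.863
    atot: float = 12.0
    pka_a: float = 6.65
    pk_hh: float = 6.1
    s_co2: float = 0.0301
    cl_prop: float = 1800.0
    c50: float = 1.5
    gamma: float = 2.0
    pmus_min: float = 2.0
    pmus_max: float = 50.0
    paco2_cap: float = 150.0
    insp_frac: float = 2.0 / 3.0
    wake_vt_ml_kg: float = 4.6

    def validate(self) -> None:
        for name in ("k_gas", "atot", "s_co2", "cl_prop", "c50",
                     "pmus_min", "pmus_max", "paco2_cap", "insp_frac",
                     "wake_vt_ml_kg"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"constant {name} must be > 0")
        if self.gamma < 1:
            raise ConfigurationError("Hill exponent gamma must be >= 1")
        if self.pmus_min >= self.pmus_max:
            raise ConfigurationError("pmus_min must be < pmus_max")


@dataclass(frozen=True)
class VentilatorSettings:
    """Ventilator mode, support level, sedation, and extracorporeal removal.

    mode 'psv': ``ps`` is inspiratory pressure support above PEEP (cmH2O).
    mode 'pav': ``gain`` is the proportional-assist fraction k in [0, 1).
    ``ecco2r_frac`` is the fraction of metabolic VCO2 removed extracorporeally.
    """

    mode: str                   # "psv" | "pav"
    ps: float = 0.0             # cmH2O (PSV)
    gain: float = 0.0           # fraction (PAV+)
    propofol: float = 0.0       # mcg/kg/min
    ecco2r_frac: float = 0.0    # fraction of VCO2, <= 0.9

    def __post_init__(self) -> None:
        if self.mode not in ("psv", "pav"):
            raise ConfigurationError(f"unknown ventilator mode {self.mode!r}")
        if self.mode == "pav" and not 0.0 <= self.gain < 1.0:
            raise ConfigurationError("PAV gain must lie in [0, 1) (runaway support)")
        if self.ps < 0 or self.propofol < 0:
            raise ConfigurationError("support and propofol must be >= 0")
        if not 0.0 <= self.ecco2r_frac <= 0.9:
            raise ConfigurationError("ecco2r_frac must lie in [0, 0.9]")

    @property
    def support(self) -> float:
        return self.ps if self.mode == "psv" else self.gain

    def with_support(self, value: float) -> "VentilatorSettings":
        if self.mode == "psv":
            return replace(self, ps=value)
        return replace(self, gain=value)

    def with_propofol(self, value: float) -> "VentilatorSettings":
        return replace(self, propofol=value)


@dataclass(frozen=True)
class PatientState:
    """Converged steady-state operating point of one patient."""

    pmus: float          # inspiratory muscle pressure amplitude, cmH2O
    vt: float            # tidal volume, L
    ve: float            # minute ventilation, L/min
    va: float            # alveolar ventilation, L/min
    paco2: float         # mmHg
    hco3: float          # mmol/L
    ph: float
    dpes: float          # esophageal swing magnitude |dPes|, cmH2O
    dpaw: float          # airway pressure swing, cmH2O
    dpl_dyn: float       # dynamic transpulmonary driving pressure, cmH2O
    vr: float            # ventilatory ratio
    ecco2r_rate: float   # extracorporeal CO2 removal, mL/min
    drive_saturated: bool = False   # chemoreflex pinned at its floor/ceiling
    ph_flagged: bool = False        # acid-base root returned at a bracket edge


# ---------------------------------------------------------------------------
# constituent relations


def sedation_effect(propofol: float, weight: float, constants: ModelConstants) -> float:
    """Multiplicative drive attenuation by a steady propofol infusion.

    Steady-state effect-site concentration Ce = rate * weight / clearance
    (mcg/mL); inhibition follows a Hill curve, m = 1 / (1 + (Ce/C50)^gamma),
    so m = 1 without drug and m = 0.5 at Ce = C50.
    """
    if propofol < 0:
        raise ValidationError("propofol rate must be >= 0")
    ce = propofol * weight / constants.cl_prop
    return 1.0 / (1.0 + (ce / constants.c50) ** constants.gamma)


def chemoreflex_drive(paco2: float, m: float, patient: PatientParameters,
                      constants: ModelConstants) -> float:
    """Muscle pressure demanded by the CO2 chemoreflex.

    Linear above the apneic threshold, scaled by the sedation multiplier,
    clamped between the wakefulness floor and a physiological ceiling.
    """
    raw = m * patient.g_chemo * (paco2 - patient.b_apnea)
    return min(max(raw, constants.pmus_min), constants.pmus_max)


def dynamic_elastance(e_rs: float, r_rs: float, rr: float,
                      insp_frac: float = 2.0 / 3.0) -> float:
    """Effective elastance including the breath-averaged resistive load.

    With mean inspiratory flow vt / (insp_frac * 60 / rr), the resistive
    pressure r * flow is proportional to vt, so resistance enters the
    pressure balance as an additional elastance r * rr / (60 * insp_frac).
    With r_rs = 0 this reduces to the static elastance.
    """
    return e_rs + r_rs * rr / (60.0 * insp_frac)


def tidal_and_pressures(
    pmus: float, settings: VentilatorSettings, e_rs: float, e_cw: float,
    peep_i: float, r_rs: float = 0.0, rr: float = 0.0,
    insp_frac: float = 2.0 / 3.0,
) -> tuple[float, float, float, float]:
    """Breath-averaged tidal volume and pressure swings for a given effort.

    Intrinsic PEEP is a threshold load: only muscle pressure in excess of it
    generates volume.  The total load per litre is the dynamic elastance
    (static elastance plus the breath-averaged resistive load; the r_rs = 0
    limit is the purely quasi-static model).  PSV adds a fixed ``ps`` to the
    effective muscle pressure; PAV+ delivers the fraction k of the total
    dynamic pressure, amplifying the patient's own contribution by 1/(1-k).

    Returns (vt [L], dpaw, dpes, dpl_dyn [cmH2O]).
    """
    if pmus < 0:
        raise ValidationError("pmus must be >= 0")
    e_dyn = dynamic_elastance(e_rs, r_rs, rr, insp_frac)
    p_eff = max(0.0, pmus - peep_i)
    if settings.mode == "psv":
        vt = (settings.ps + p_eff) / e_dyn
        dpaw = settings.ps
    else:
        if settings.gain >= 1.0:
            raise ConfigurationError("PAV gain >= 1 implies runaway support")
        vt = p_eff / (e_dyn - settings.gain * e_rs)
        dpaw = settings.gain * e_rs * vt
    dpes = max(0.0, pmus - vt * e_cw)
    dpl_dyn = dpaw + dpes
    return vt, dpaw, dpes, dpl_dyn


def alveolar_gas(
    vt: float, rr: float, vd_anat: float, f_alv_ds: float, vco2: float,
    ecco2r_frac: float, constants: ModelConstants,
) -> tuple[float, float, float]:
    """Alveolar ventilation and PaCO2 from the steady CO2 mass balance.

    The alveolar dead-space fraction wastes that share of each tidal volume
    and the anatomical dead space (mL) is lost per breath, so
    va = rr * (vt * (1 - f_alv_ds) - vd_anat / 1000).  Extracorporeal
    removal of a fraction phi of VCO2 lowers the CO2 load the lungs must
    clear.  PaCO2 = k_gas * VCO2_eff / VA, capped for degenerate states in
    which tidal volume cannot clear the dead space.

    Returns (va [L/min], paco2 [mmHg], ecco2r_rate [mL/min]).
    """
    if not 0.0 <= ecco2r_frac <= 0.9:
        raise ValidationError("ecco2r_frac must lie in [0, 0.9]")
    va = rr * max(0.0, vt * (1.0 - f_alv_ds) - vd_anat / 1000.0)
    vco2_eff = vco2 * (1.0 - ecco2r_frac)
    ecco2r_rate = vco2 * ecco2r_frac
    if va <= 0.0:
        return 0.0, constants.paco2_cap, ecco2r_rate
    paco2 = min(constants.paco2_cap, constants.k_gas * vco2_eff / va)
    return va, paco2, ecco2r_rate


def wakefulness_floor(settings: VentilatorSettings, e_dyn: float,
                      peep_i: float, pbw: float,
                      constants: ModelConstants, e_rs: float | None = None) -> float:
    """Muscle pressure demanded by the wakefulness drive.

    An awake subject demands a minimum tidal volume (wake_vt_ml_kg per kg
    predicted body weight) regardless of chemical stimuli; the floor is the
    muscle pressure needed to realise that volume given the current
    ventilator assistance, but never less than the absolute pmus_min.
    """
    vt_min = constants.wake_vt_ml_kg * pbw / 1000.0
    if settings.mode == "psv":
        p_need = peep_i + max(0.0, e_dyn * vt_min - settings.ps)
    else:
        e_assist = e_rs if e_rs is not None else e_dyn
        p_need = peep_i + (e_dyn - settings.gain * e_assist) * vt_min
    return max(constants.pmus_min, p_need)


def stewart_ph(paco2: float, sid: float,
               constants: ModelConstants) -> tuple[float, float, bool]:
    """Plasma pH and bicarbonate from the Stewart physicochemical balance.

    Electroneutrality: SID = [HCO3-] + [A-], with
    [HCO3-] = S * PaCO2 * 10^(pH - pK) and [A-] = Atot / (1 + 10^(pKa - pH)).
    The residual is strictly decreasing in pH, so the root in [6.5, 7.9] is
    unique; bisection runs to |dpH| < 1e-6.  If the bracket contains no sign
    change the nearer boundary is returned with ``flagged`` set.
    """
    if not 0.0 < paco2 <= constants.paco2_cap:
        raise ValidationError("paco2 must lie in (0, paco2_cap]")
    if not 10.0 <= sid <= 70.0:
        raise ValidationError("sid must lie in [10, 70]")

    def resid(ph: float) -> float:
        hco3 = constants.s_co2 * paco2 * 10.0 ** (ph - constants.pk_hh)
        a_minus = constants.atot / (1.0 + 10.0 ** (constants.pka_a - ph))
        return sid - hco3 - a_minus

    lo, hi = 6.5, 7.9
    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo <= 0.0:        # already too acidic for the bracket
        ph = lo
        flagged = True
    elif f_hi >= 0.0:      # alkalotic beyond the bracket
        ph = hi
        flagged = True
    else:
        for _ in range(64):
            mid = 0.5 * (lo + hi)
            if resid(mid) > 0.0:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-7:
                break
        ph = 0.5 * (lo + hi)
        flagged = False
    hco3 = constants.s_co2 * paco2 * 10.0 ** (ph - constants.pk_hh)
    return ph, hco3, flagged


def ventilatory_ratio(ve: float, paco2: float, pbw: float) -> float:
    """Ventilatory ratio: measured VE*PaCO2 over the predicted product.

    VR = (VE[mL/min] * PaCO2) / (PBW * 100 * 37.5); a dead-space surrogate
    equal to 1 for ideal ventilation at a normal PaCO2.
    """
    if ve <= 0 or paco2 <= 0 or pbw <= 0:
        raise ValidationError("ve, paco2, pbw must all be > 0")
    return (ve * 1000.0 * paco2) / (pbw * 100.0 * 37.5)


# ---------------------------------------------------------------------------
# closed-loop steady state


def _paco2_at(pmus: float, patient: PatientParameters, settings: VentilatorSettings,
              e_rs: float, e_cw: float, constants: ModelConstants) -> float:
    vt, _, _, _ = tidal_and_pressures(pmus, settings, e_rs, e_cw, patient.peep_i,
                                      patient.r_rs, patient.rr,
                                      constants.insp_frac)
    _, paco2, _ = alveolar_gas(vt, patient.rr, patient.vd_anat, patient.f_alv_ds,
                               patient.vco2, settings.ecco2r_frac, constants)
    return paco2


def solve_steady_state(
    patient: PatientParameters,
    settings: VentilatorSettings,
    constants: ModelConstants = ModelConstants(),
) -> PatientState:
    """Find the closed-loop operating point of one patient.

    The drive is the larger of the (sedation-attenuated) chemoreflex and the
    wakefulness minimum-volume demand.  The residual
    f(Pmus) = Pmus - drive(PaCO2(Pmus)) is strictly increasing (more effort
    -> more ventilation -> lower PaCO2 -> no more drive), and the clamped
    drive guarantees f <= 0 at the floor and f >= 0 at the ceiling, so
    bisection always brackets the unique root.  Converges to
    |dPmus| < 1e-4 cmH2O.
    """
    m = sedation_effect(settings.propofol, patient.weight, constants)
    e_cw = patient.e_cw
    e_rs = patient.e_rs
    e_dyn = dynamic_elastance(e_rs, patient.r_rs, patient.rr,
                              constants.insp_frac)
    # wakefulness demand scales with the same sedation multiplier
    wake = wakefulness_floor(settings, e_dyn, patient.peep_i, patient.pbw,
                             constants, e_rs=e_rs)
    floor = min(constants.pmus_max,
                max(constants.pmus_min,
                    constants.pmus_min + m * (wake - constants.pmus_min)))

    def f(p: float) -> float:
        paco2 = _paco2_at(p, patient, settings, e_rs, e_cw, constants)
        return p - max(chemoreflex_drive(paco2, m, patient, constants), floor)

    lo, hi = floor, constants.pmus_max
    if f(lo) >= 0.0:
        pmus = lo
    elif f(hi) <= 0.0:
        pmus = hi
    else:
        while hi - lo > 1e-5:
            mid = 0.5 * (lo + hi)
            if f(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        pmus = 0.5 * (lo + hi)

    vt, dpaw, dpes, dpl_dyn = tidal_and_pressures(pmus, settings, e_rs, e_cw,
                                                  patient.peep_i, patient.r_rs,
                                                  patient.rr,
                                                  constants.insp_frac)
    va, paco2, ecco2r_rate = alveolar_gas(
        vt, patient.rr, patient.vd_anat, patient.f_alv_ds, patient.vco2,
        settings.ecco2r_frac, constants,
    )
    ph, hco3, ph_flagged = stewart_ph(paco2, patient.sid, constants)
    ve = patient.rr * vt
    vr = ventilatory_ratio(ve, paco2, patient.pbw) if ve > 0 else 0.0
    saturated = (pmus <= floor + 1e-4) or \
                (pmus >= constants.pmus_max - 1e-4)
    return PatientState(
        pmus=pmus, vt=vt, ve=ve, va=va, paco2=paco2, hco3=hco3, ph=ph,
        dpes=dpes, dpaw=dpaw, dpl_dyn=dpl_dyn, vr=vr,
        ecco2r_rate=ecco2r_rate, drive_saturated=saturated,
        ph_flagged=ph_flagged,
    )


# ---------------------------------------------------------------------------
# calibration of the free reconstruction constants

#: Population-mean goals of the computed baseline row on PSV 10 / propofol 20.
TABLE1_BASELINE_TARGETS: dict[str, float] = {
    "paco2": 35.0,    # mmHg
    "vt": 0.568,      # L
    "dpes": 9.0,      # cmH2O
    "ph": 7.44,
    "dpl_dyn": 18.0,  # cmH2O
}

#: Pre-registered coarse grid (chemoreflex gain median, apneic threshold
#: mean, propofol C50) searched by :func:`calibrate_constants`.
DEFAULT_CALIBRATION_GRID: dict[str, tuple[float, ...]] = {
    "g_chemo_median": (2.4, 2.8, 3.2, 3.6, 4.0),
    "b_apnea_mean": (22.0, 24.0, 26.0, 28.0, 30.0),
    "c50": (1.5,),
}


@dataclass(frozen=True)
class CalibrationResult:
    constants: ModelConstants
    g_chemo_median: float
    b_apnea_mean: float
    achieved: dict[str, float]       # simulated population means
    errors: dict[str, float]         # relative error per target
    objective: float                 # sum of squared relative errors
    warning: bool                    # no grid point within 25% on all targets


def calibrate_constants(
    population: Sequence[PatientParameters],
    targets: dict[str, float] | None = None,
    grid: dict[str, Sequence[float]] | None = None,
    constants: ModelConstants = ModelConstants(),
    settings: VentilatorSettings | None = None,
) -> CalibrationResult:
    """Anchor the free controller constants to the computed baseline row.

    Grid-searches (chemoreflex gain median, apneic threshold mean, C50)
    minimising the sum of squared relative errors between simulated
    population means and the target means on baseline PSV settings.  The
    per-patient gain and threshold are relocated along their own marginal
    distributions (same quantile, shifted location), so no new randomness
    enters and the search is deterministic.
    """
    from .population import default_population_specs

    if targets is None:
        targets = dict(TABLE1_BASELINE_TARGETS)
    if grid is None:
        grid = {k: list(v) for k, v in DEFAULT_CALIBRATION_GRID.items()}
    if settings is None:
        settings = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0)
    for key in ("g_chemo_median", "b_apnea_mean", "c50"):
        if not grid.get(key):
            raise ConfigurationError(f"calibration grid for {key} is empty")

    base_specs = default_population_specs()
    # per-patient quantiles of the controller parameters under the defaults
    import numpy as np

    g0 = np.array([p.g_chemo for p in population])
    b0 = np.array([p.b_apnea for p in population])
    u_g = base_specs["g_chemo"].cdf(g0)
    u_b = base_specs["b_apnea"].cdf(b0)
    u_g = np.clip(u_g, 1e-9, 1.0 - 1e-9)
    u_b = np.clip(u_b, 1e-9, 1.0 - 1e-9)

    best = None
    for g_med in grid["g_chemo_median"]:
        for b_mean in grid["b_apnea_mean"]:
            specs = default_population_specs(g_chemo_median=g_med,
                                             b_apnea_mean=b_mean)
            g_new = specs["g_chemo"].ppf(u_g)
            b_new = specs["b_apnea"].ppf(u_b)
            for c50 in grid["c50"]:
                cand = replace(constants, c50=c50)
                sums = {k: 0.0 for k in targets}
                for i, p in enumerate(population):
                    q = replace(p, g_chemo=float(g_new[i]),
                                b_apnea=float(b_new[i]))
                    st = solve_steady_state(q, settings, cand)
                    for k in sums:
                        sums[k] += getattr(st, k)
                n = len(population)
                achieved = {k: s / n for k, s in sums.items()}
                errors = {k: (achieved[k] - targets[k]) / targets[k]
                          for k in targets}
                obj = sum(e * e for e in errors.values())
                if best is None or obj < best[0]:
                    best = (obj, g_med, b_mean, c50, achieved, errors)

    obj, g_med, b_mean, c50, achieved, errors = best
    warning = any(abs(e) > 0.25 for e in errors.values())
    return CalibrationResult(
        constants=replace(constants, c50=c50),
        g_chemo_median=g_med, b_apnea_mean=b_mean,
        achieved=achieved, errors=errors, objective=obj, warning=warning,
    )
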