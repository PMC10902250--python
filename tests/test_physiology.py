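"""Physiology: constituent relations, the Stewart solver, and the
closed-loop steady state."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldp_insilico.errors import ConfigurationError, ValidationError
from ldp_insilico.physiology import (
    ModelConstants,
    VentilatorSettings,
    alveolar_gas,
    calibrate_constants,
    chemoreflex_drive,
    dynamic_elastance,
    sedation_effect,
    solve_steady_state,
    stewart_ph,
    tidal_and_pressures,
    ventilatory_ratio,
    wakefulness_floor,
)
from ldp_insilico.population import sample_population

from conftest import make_patient

CONST = ModelConstants()


# ---------------------------------------------------------------------------
# sedation


def test_sedation_no_drug_is_identity():
    assert sedation_effect(0.0, 85.0, CONST) == 1.0


def test_sedation_effect_site_hand_value():
    # Ce = 20 * 85 / 1800 = 0.944 mcg/mL; Hill with C50 6, gamma 2
    const = replace(CONST, c50=6.0, gamma=2.0)
    ce = 20.0 * 85.0 / 1800.0
    assert ce == pytest.approx(0.9444, abs=1e-4)
    assert sedation_effect(20.0, 85.0, const) == pytest.approx(0.9758, abs=1e-3)


def test_sedation_half_effect_at_c50():
    # infusion chosen so Ce == C50 exactly
    rate = CONST.c50 * CONST.cl_prop / 85.0
    assert sedation_effect(rate, 85.0, CONST) == pytest.approx(0.5)


def test_sedation_strictly_decreasing():
    rates = np.linspace(0.0, 80.0, 30)
    effects = [sedation_effect(r, 85.0, CONST) for r in rates]
    assert all(a > b for a, b in zip(effects, effects[1:]))


# ---------------------------------------------------------------------------
# chemoreflex


def test_chemoreflex_below_threshold_floors():
    p = make_patient(g_chemo=2.0, b_apnea=34.0)
    assert chemoreflex_drive(30.0, 1.0, p, CONST) == CONST.pmus_min


@pytest.mark.parametrize("m, expected", [(1.0, 16.0), (0.5, 8.0)])
def test_chemoreflex_linear_hand_values(m, expected):
    p = make_patient(g_chemo=2.0, b_apnea=34.0)
    assert chemoreflex_drive(42.0, m, p, CONST) == pytest.approx(expected)


def test_chemoreflex_monotone_and_capped():
    p = make_patient(g_chemo=2.0, b_apnea=34.0)
    drives = [chemoreflex_drive(x, 1.0, p, CONST) for x in np.linspace(20, 140, 50)]
    assert all(b >= a for a, b in zip(drives, drives[1:]))
    assert drives[-1] == CONST.pmus_max


# ---------------------------------------------------------------------------
# mechanics


def test_apneic_unsupported_no_volume():
    s = VentilatorSettings(mode="psv", ps=0.0)
    vt, dpaw, dpes, dpl = tidal_and_pressures(0.0, s, 29.3, 8.0, 0.0)
    assert (vt, dpaw, dpes, dpl) == (0.0, 0.0, 0.0, 0.0)


def test_psv_hand_value_static_limit():
    # r_rs = 0 limit: vt = (ps + pmus - peep_i) / e_rs
    s = VentilatorSettings(mode="psv", ps=10.0)
    vt, dpaw, dpes, dpl = tidal_and_pressures(13.5, s, 29.3, 8.0, 1.5)
    assert vt == pytest.approx(22.0 / 29.3, abs=1e-4)       # 0.751 L
    assert dpaw == 10.0
    assert dpes == pytest.approx(13.5 - vt * 8.0, abs=1e-6)  # 7.49
    assert dpl == pytest.approx(dpaw + dpes)


def test_pav_hand_value_static_limit():
    # r_rs = 0: gain 0.5 doubles the patient's effective pressure
    s = VentilatorSettings(mode="pav", gain=0.5)
    vt, dpaw, dpes, dpl = tidal_and_pressures(13.5, s, 29.3, 8.0, 1.5)
    assert vt == pytest.approx(24.0 / 29.3, abs=1e-4)        # 0.819 L
    assert dpaw == pytest.approx(12.0, abs=1e-6)
    assert dpl == pytest.approx(dpaw + dpes)


def test_resistive_load_raises_pressure_cost():
    # same effort yields less volume once the resistive load is carried
    s = VentilatorSettings(mode="psv", ps=10.0)
    vt0, *_ = tidal_and_pressures(13.5, s, 29.3, 8.0, 1.5)
    vt1, _, dpes1, _ = tidal_and_pressures(13.5, s, 29.3, 8.0, 1.5,
                                           r_rs=11.0, rr=28.0)
    assert vt1 < vt0
    assert dpes1 > 13.5 - vt0 * 8.0
    e_dyn = dynamic_elastance(29.3, 11.0, 28.0)
    assert vt1 == pytest.approx(22.0 / e_dyn, abs=1e-6)


def test_pav_runaway_gain_rejected():
    with pytest.raises(ConfigurationError):
        VentilatorSettings(mode="pav", gain=1.0)


def test_intrinsic_peep_threshold_load():
    s = VentilatorSettings(mode="psv", ps=0.0)
    vt_low, *_ = tidal_and_pressures(3.0, s, 29.3, 8.0, 4.0)
    assert vt_low == 0.0  # pmus below the threshold produces no volume


# ---------------------------------------------------------------------------
# gas exchange


def test_alveolar_gas_hand_value():
    # va = rr * (vt*(1-fads) - vd/1000); paco2 = k * vco2 / va
    va, paco2, rate = alveolar_gas(0.568, 28.0, 128.0, 0.37, 223.0, 0.0, CONST)
    assert va == pytest.approx(6.4355, abs=1e-3)
    assert paco2 == pytest.approx(29.90, abs=0.02)
    assert rate == 0.0


def test_alveolar_gas_degenerate_dead_space():
    va, paco2, _ = alveolar_gas(0.15, 28.0, 128.0, 0.37, 223.0, 0.0, CONST)
    assert va == 0.0
    assert paco2 == CONST.paco2_cap


def test_ecco2r_linear_in_removed_fraction():
    va0, paco2_0, _ = alveolar_gas(0.568, 28.0, 128.0, 0.37, 223.0, 0.0, CONST)
    va1, paco2_1, rate = alveolar_gas(0.568, 28.0, 128.0, 0.37, 223.0, 0.5, CONST)
    assert va1 == va0
    assert paco2_1 == pytest.approx(paco2_0 / 2.0)
    assert rate == pytest.approx(111.5)


# ---------------------------------------------------------------------------
# Stewart acid-base


def _stewart_grid_oracle(paco2, sid, constants=CONST, n=100_001):
    grid = np.linspace(6.5, 7.9, n)
    hco3 = constants.s_co2 * paco2 * 10 ** (grid - constants.pk_hh)
    a_minus = constants.atot / (1 + 10 ** (constants.pka_a - grid))
    return grid[np.argmin(np.abs(sid - hco3 - a_minus))]


@pytest.mark.parametrize("paco2, sid", [(35, 34), (40, 30), (60, 34), (25, 40)])
def test_stewart_root_matches_dense_grid(paco2, sid):
    ph, hco3, flagged = stewart_ph(paco2, sid, CONST)
    assert not flagged
    assert ph == pytest.approx(_stewart_grid_oracle(paco2, sid), abs=2e-5)
    assert hco3 == pytest.approx(CONST.s_co2 * paco2 * 10 ** (ph - CONST.pk_hh))


def test_stewart_reference_point():
    # cohort means: PaCO2 35, SID 34 sit at the printed pH ~7.44-7.45
    ph, hco3, _ = stewart_ph(35.0, 34.0, CONST)
    assert ph == pytest.approx(7.451, abs=2e-3)
    assert hco3 == pytest.approx(23.64, abs=0.05)


def test_stewart_atot_zero_closed_form():
    const = replace(CONST, atot=1e-12)
    for paco2, sid in ((35, 34), (50, 28), (30, 45)):
        expected = const.pk_hh + math.log10(sid / (const.s_co2 * paco2))
        ph, _, flagged = stewart_ph(paco2, sid, const)
        if 6.5 < expected < 7.9:
            assert not flagged
            assert ph == pytest.approx(expected, abs=1e-5)


def test_stewart_out_of_bracket_flagged():
    # extreme acidosis: root below 6.5 -> boundary value, flagged
    ph, _, flagged = stewart_ph(150.0, 15.0, CONST)
    assert flagged and ph == 6.5


@settings(max_examples=50, deadline=None)
@given(paco2=st.floats(15.0, 120.0), sid=st.floats(18.0, 55.0))
def test_stewart_residual_strictly_decreasing_in_ph(paco2, sid):
    ph = np.linspace(6.5, 7.9, 200)
    resid = (sid - CONST.s_co2 * paco2 * 10 ** (ph - CONST.pk_hh)
             - CONST.atot / (1 + 10 ** (CONST.pka_a - ph)))
    assert np.all(np.diff(resid) < 0)


# ---------------------------------------------------------------------------
# ventilatory ratio


def test_ventilatory_ratio_hand_value():
    assert ventilatory_ratio(10.0, 40.0, 70.0) == pytest.approx(1.5238, abs=1e-3)


def test_ventilatory_ratio_normalization_point():
    pbw = 70.0
    ve = pbw * 100.0 * 37.5 / (1000.0 * 40.0)
    assert ventilatory_ratio(ve, 40.0, pbw) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# closed-loop steady state


def _damped_fixed_point(patient, settings, constants, alpha=0.5, iters=20000):
    """Independent solver: damped Picard iteration on the drive loop."""
    from ldp_insilico.physiology import (
        _paco2_at, chemoreflex_drive, dynamic_elastance, sedation_effect,
        wakefulness_floor,
    )
    m = sedation_effect(settings.propofol, patient.weight, constants)
    e_dyn = dynamic_elastance(patient.e_rs, patient.r_rs, patient.rr,
                              constants.insp_frac)
    wake = wakefulness_floor(settings, e_dyn, patient.peep_i, patient.pbw,
                             constants, e_rs=patient.e_rs)
    floor = min(constants.pmus_max,
                max(constants.pmus_min,
                    constants.pmus_min + m * (wake - constants.pmus_min)))
    p = 0.5 * (floor + constants.pmus_max)
    prev_resid = None
    for _ in range(iters):
        paco2 = _paco2_at(p, patient, settings, patient.e_rs, patient.e_cw,
                          constants)
        target = max(chemoreflex_drive(paco2, m, patient, constants), floor)
        target = min(target, constants.pmus_max)
        resid = target - p
        if abs(resid) < 1e-9:
            break
        if prev_resid is not None and resid * prev_resid < 0:
            alpha *= 0.5          # oscillation: damp harder
        prev_resid = resid
        p = p + alpha * resid
    return p


def test_bisection_agrees_with_damped_fixed_point_oracle():
    pop = sample_population(n=1000, seed=17)
    settings_pool = [
        VentilatorSettings(mode="psv", ps=10.0, propofol=20.0),
        VentilatorSettings(mode="psv", ps=0.0, propofol=0.0, ecco2r_frac=0.3),
        VentilatorSettings(mode="pav", gain=0.5, propofol=20.0),
        VentilatorSettings(mode="pav", gain=0.7, propofol=40.0,
                           ecco2r_frac=0.2),
    ]
    worst = 0.0
    for i, p in enumerate(pop):
        s = settings_pool[i % len(settings_pool)]
        st_ = solve_steady_state(p, s, CONST)
        oracle = _damped_fixed_point(p, s, CONST)
        worst = max(worst, abs(st_.pmus - oracle))
    assert worst < 1e-3


def test_co2_balance_closes_at_steady_state(small_population):
    s = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0)
    for p in small_population:
        st_ = solve_steady_state(p, s, CONST)
        if st_.paco2 < CONST.paco2_cap:
            lhs = CONST.k_gas * p.vco2 * (1 - s.ecco2r_frac)
            rhs = st_.paco2 * st_.va
            assert abs(lhs - rhs) / lhs < 1e-6


def test_state_fields_consistent(reference_patient):
    s = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0)
    st_ = solve_steady_state(reference_patient, s, CONST)
    assert st_.ve == pytest.approx(reference_patient.rr * st_.vt)
    assert st_.dpl_dyn == pytest.approx(st_.dpaw + st_.dpes)
    assert st_.dpl_dyn >= st_.dpaw >= 0.0
    assert 6.5 <= st_.ph <= 7.9
    assert st_.vr == pytest.approx(
        ventilatory_ratio(st_.ve, st_.paco2, reference_patient.pbw))


def test_support_increase_weakly_reduces_effort(small_population):
    for p in small_population[:60]:
        prev = None
        for ps in (0.0, 5.0, 10.0, 15.0, 20.0):
            s = VentilatorSettings(mode="psv", ps=ps, propofol=20.0)
            dpes = solve_steady_state(p, s, CONST).dpes
            if prev is not None:
                assert dpes <= prev + 1e-6
            prev = dpes


def test_pav_gain_increase_weakly_reduces_effort(small_population):
    for p in small_population[:40]:
        prev = None
        for k in (0.2, 0.4, 0.6, 0.8):
            s = VentilatorSettings(mode="pav", gain=k, propofol=20.0)
            dpes = solve_steady_state(p, s, CONST).dpes
            if prev is not None:
                assert dpes <= prev + 1e-6
            prev = dpes


def test_ecco2r_weakly_reduces_paco2_and_effort(small_population):
    for p in small_population[:60]:
        prev_pc, prev_dpes = None, None
        floored = False
        for phi in (0.0, 0.3, 0.6, 0.9):
            s = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0,
                                   ecco2r_frac=phi)
            st_ = solve_steady_state(p, s, CONST)
            if prev_pc is not None:
                assert st_.paco2 <= prev_pc + 1e-6
                if not floored:
                    assert st_.dpes <= prev_dpes + 1e-6
            floored = floored or st_.drive_saturated
            prev_pc, prev_dpes = st_.paco2, st_.dpes


def test_full_ecco2r_floors_drive(reference_patient):
    s = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0,
                           ecco2r_frac=0.9)
    st_ = solve_steady_state(reference_patient, s, CONST)
    assert st_.drive_saturated


def test_drive_residual_single_sign_change(small_population):
    """The loop residual crosses zero at most once (uniqueness bracket scan)."""
    from ldp_insilico.physiology import _paco2_at, sedation_effect

    for i, p in enumerate(small_population):
        s = VentilatorSettings(mode="psv", ps=float(i % 3) * 7.0,
                               propofol=float(i % 5) * 15.0)
        m = sedation_effect(s.propofol, p.weight, CONST)
        grid = np.linspace(CONST.pmus_min, CONST.pmus_max, 60)
        resid = [
            g - chemoreflex_drive(
                _paco2_at(g, p, s, p.e_rs, p.e_cw, CONST), m, p, CONST)
            for g in grid
        ]
        signs = np.sign(resid)
        changes = np.sum(np.abs(np.diff(signs)) > 1)
        assert changes <= 1


# ---------------------------------------------------------------------------
# calibration


def test_calibration_recovers_achievable_targets(small_population):
    """Self-consistency: targets generated by a grid point are recovered."""
    from dataclasses import replace as drep

    from ldp_insilico.population import default_population_specs

    grid = {"g_chemo_median": (2.4, 3.2), "b_apnea_mean": (24.0, 28.0),
            "c50": (1.5,)}
    # synthesise targets from one grid point
    specs = default_population_specs(g_chemo_median=3.2, b_apnea_mean=28.0)
    import numpy as np
    base = default_population_specs()
    u_g = base["g_chemo"].cdf(np.array([p.g_chemo for p in small_population]))
    u_b = base["b_apnea"].cdf(np.array([p.b_apnea for p in small_population]))
    g_new = specs["g_chemo"].ppf(np.clip(u_g, 1e-9, 1 - 1e-9))
    b_new = specs["b_apnea"].ppf(np.clip(u_b, 1e-9, 1 - 1e-9))
    s = VentilatorSettings(mode="psv", ps=10.0, propofol=20.0)
    sums = {k: 0.0 for k in ("paco2", "vt", "dpes", "ph", "dpl_dyn")}
    for i, p in enumerate(small_population):
        q = drep(p, g_chemo=float(g_new[i]), b_apnea=float(b_new[i]))
        st_ = solve_steady_state(q, s, CONST)
        for k in sums:
            sums[k] += getattr(st_, k)
    targets = {k: v / len(small_population) for k, v in sums.items()}

    result = calibrate_constants(small_population, targets=targets, grid=grid)
    assert result.g_chemo_median == 3.2
    assert result.b_apnea_mean == 28.0
    assert not result.warning
    assert result.objective < 1e-12


def test_calibration_empty_grid_rejected(small_population):
    with pytest.raises(ConfigurationError):
        calibrate_constants(small_population,
                            grid={"g_chemo_median": (), "b_apnea_mean": (24.0,),
                                  "c50": (1.5,)})


def test_calibration_effort_near_cohort_mean(calibration):
    # achieved mean esophageal swing within +/- 2 cmH2O of the printed 9
    assert abs(calibration.achieved["dpes"] - 9.0) <= 2.0
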