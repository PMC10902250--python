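"""LDP target assessment and the ventilation/sedation titration algorithm.

The lung- and diaphragm-protective (LDP) joint target is: dynamic
transpulmonary driving pressure below 15 cmH2O, esophageal swing magnitude
within 3-8 cmH2O, and pH above 7.25.  Patients meeting all three on the
initial ventilator settings are primary successes; otherwise support and
sedation are adjusted by a fixed rule table, re-solving the steady state
after every move, for at most 20 iterations.  Patients who still fail may
receive extracorporeal CO2 removal at escalating levels, the titration
being restarted from the initial settings at each level, or be simulated
on extracorporeal removal alone with zero support and zero sedation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError, ValidationError
from .physiology import (
    ModelConstants,
    PatientState,
    VentilatorSettings,
    solve_steady_state,
)
from .population import PatientParameters

__all__ = [
    "LDP_TARGETS",
    "TargetAssessment",
    "TitrationPolicy",
    "TitrationResult",
    "assess_targets",
    "titration_step",
    "run_titration",
    "escalate_ecco2r",
    "awake_ecco2r",
    "initial_settings",
]

#: The three LDP targets (strict bound for lung pressure and pH; inclusive
#: band for effort).
LDP_TARGETS = {"dpl_dyn_max": 15.0, "dpes_min": 3.0, "dpes_max": 8.0,
               "ph_min": 7.25}


@dataclass(frozen=True)
class TargetAssessment:
    lung_ok: bool     # dpl_dyn < 15 cmH2O (strict)
    effort_ok: bool   # 3 <= |dPes| <= 8 cmH2O (inclusive)
    ph_ok: bool       # pH > 7.25 (strict)
    violations: tuple[str, ...]   # subset of the four violation labels,
                                  # in priority order

    @property
    def all_ok(self) -> bool:
        return not self.violations


def assess_targets(state: PatientState) -> TargetAssessment:
    """Evaluate the three LDP targets on a solved steady state.

    Violations are listed in the fixed priority order used by the titration
    rule table: acidosis, effort_high, effort_low, lung_high.
    """
    lung_ok = state.dpl_dyn < LDP_TARGETS["dpl_dyn_max"]
    effort_low = state.dpes < LDP_TARGETS["dpes_min"]
    effort_high = state.dpes > LDP_TARGETS["dpes_max"]
    ph_ok = state.ph > LDP_TARGETS["ph_min"]
    violations = []
    if not ph_ok:
        violations.append("acidosis")
    if effort_high:
        violations.append("effort_high")
    if effort_low:
        violations.append("effort_low")
    if not lung_ok:
        violations.append("lung_high")
    return TargetAssessment(
        lung_ok=lung_ok, effort_ok=not (effort_low or effort_high),
        ph_ok=ph_ok, violations=tuple(violations),
    )


@dataclass(frozen=True)
class TitrationPolicy:
    """Step sizes and bounds of the titration levers."""

    ps_step: float = 2.0
    ps_min: float = 0.0
    ps_max: float = 20.0
    gain_step: float = 0.1
    gain_min: float = 0.2
    gain_max: float = 0.8
    propofol_step: float = 10.0
    propofol_min: float = 0.0
    propofol_max: float = 80.0
    max_iter: int = 20
    ecco2r_step: float = 0.10
    ecco2r_max: float = 0.90

    def __post_init__(self) -> None:
        for name in ("ps_step", "gain_step", "propofol_step", "ecco2r_step"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"policy {name} must be > 0")
        for lo, hi in (("ps_min", "ps_max"), ("gain_min", "gain_max"),
                       ("propofol_min", "propofol_max")):
            if not getattr(self, lo) < getattr(self, hi):
                raise ConfigurationError(f"policy requires {lo} < {hi}")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")

    def support_bounds(self, mode: str) -> tuple[float, float, float]:
        if mode == "psv":
            return self.ps_min, self.ps_max, self.ps_step
        return self.gain_min, self.gain_max, self.gain_step


@dataclass
class TitrationResult:
    status: str                     # primary_success | treatment_success | failure
    iterations_used: int
    final_settings: VentilatorSettings
    final_state: PatientState
    ecco2r_frac: float = 0.0        # fraction of VCO2 at success (0 if none)
    trajectory: list[tuple[VentilatorSettings, PatientState, TargetAssessment]] = \
        field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.status in ("primary_success", "treatment_success")


_EPS = 1e-9


def _clamped_move(value: float, delta: float, lo: float, hi: float) -> Optional[float]:
    """Move by delta within [lo, hi]; None if already pinned at the bound."""
    if delta > 0 and value >= hi - _EPS:
        return None
    if delta < 0 and value <= lo + _EPS:
        return None
    return min(max(value + delta, lo), hi)


def titration_step(
    assessment: TargetAssessment,
    settings: VentilatorSettings,
    policy: TitrationPolicy,
) -> Optional[VentilatorSettings]:
    """Apply the first matching titration rule; None means no move possible.

    Rules, in priority order (support = pressure support in PSV, gain in PAV+):
      R1 acidosis with low effort        -> lighten sedation
      R2 acidosis (otherwise)            -> raise support
      R3 high effort with high lung P    -> deepen sedation
      R4 high effort                     -> raise support, else deepen sedation
      R5 low effort                      -> lower support, else lighten sedation
      R6 high lung pressure              -> lower support, else deepen sedation
    Every candidate move is clamped to the policy bounds; a rule whose lever
    is already pinned falls through to its alternative lever, and if every
    indicated change is bound-blocked the step returns no-move.
    """
    if assessment.all_ok:
        raise ValidationError("titration_step called on an all-ok assessment")
    v = set(assessment.violations)
    lo, hi, step = policy.support_bounds(settings.mode)
    plo, phi, pstep = policy.propofol_min, policy.propofol_max, policy.propofol_step

    # each rule: ordered candidate (lever, delta) moves
    if "acidosis" in v and "effort_low" in v:
        moves = [("propofol", -pstep)]
    elif "acidosis" in v:
        moves = [("support", +step)]
    elif "effort_high" in v and "lung_high" in v:
        moves = [("propofol", +pstep)]
    elif "effort_high" in v:
        moves = [("support", +step), ("propofol", +pstep)]
    elif "effort_low" in v:
        moves = [("support", -step), ("propofol", -pstep)]
    else:  # lung_high only
        moves = [("support", -step), ("propofol", +pstep)]

    for lever, delta in moves:
        if lever == "support":
            new = _clamped_move(settings.support, delta, lo, hi)
            if new is not None:
                return settings.with_support(new)
        else:
            new = _clamped_move(settings.propofol, delta, plo, phi)
            if new is not None:
                return settings.with_propofol(new)
    return None


def initial_settings(mode: str, ecco2r_frac: float = 0.0) -> VentilatorSettings:
    """Protocol starting point: PSV 10 cmH2O or PAV+ 50% gain, propofol 20."""
    if mode == "psv":
        return VentilatorSettings(mode="psv", ps=10.0, propofol=20.0,
                                  ecco2r_frac=ecco2r_frac)
    if mode == "pav":
        return VentilatorSettings(mode="pav", gain=0.5, propofol=20.0,
                                  ecco2r_frac=ecco2r_frac)
    raise ConfigurationError(f"unknown mode {mode!r}")


def run_titration(
    patient: PatientParameters,
    settings: VentilatorSettings,
    policy: TitrationPolicy = TitrationPolicy(),
    constants: ModelConstants = ModelConstants(),
    keep_trajectory: bool = True,
) -> TitrationResult:
    """Titrate one patient from the given settings to the LDP targets.

    Iteration 0 solves and assesses the initial settings (all-ok there is a
    primary success).  Each subsequent iteration applies one rule-table move
    and re-solves; success at iteration i >= 1 is a treatment success.  The
    run fails after ``max_iter`` moves, or earlier if every lever is pinned
    at its bound (no-move).
    """
    state = solve_steady_state(patient, settings, constants)
    assessment = assess_targets(state)
    trajectory = [(settings, state, assessment)] if keep_trajectory else []
    if assessment.all_ok:
        return TitrationResult(
            status="primary_success", iterations_used=0,
            final_settings=settings, final_state=state,
            ecco2r_frac=settings.ecco2r_frac, trajectory=trajectory,
        )
    for i in range(1, policy.max_iter + 1):
        new_settings = titration_step(assessment, settings, policy)
        if new_settings is None:
            return TitrationResult(
                status="failure", iterations_used=i - 1,
                final_settings=settings, final_state=state,
                ecco2r_frac=0.0, trajectory=trajectory,
            )
        settings = new_settings
        state = solve_steady_state(patient, settings, constants)
        assessment = assess_targets(state)
        if keep_trajectory:
            trajectory.append((settings, state, assessment))
        if assessment.all_ok:
            return TitrationResult(
                status="treatment_success", iterations_used=i,
                final_settings=settings, final_state=state,
                ecco2r_frac=settings.ecco2r_frac, trajectory=trajectory,
            )
    return TitrationResult(
        status="failure", iterations_used=policy.max_iter,
        final_settings=settings, final_state=state,
        ecco2r_frac=0.0, trajectory=trajectory,
    )


def escalate_ecco2r(
    patient: PatientParameters,
    mode: str,
    policy: TitrationPolicy = TitrationPolicy(),
    constants: ModelConstants = ModelConstants(),
    keep_trajectory: bool = False,
    base_result: TitrationResult | None = None,
) -> TitrationResult:
    """Escalating extracorporeal CO2 removal for a titration failure.

    Precondition: the patient must fail the plain titration (phi = 0).  The
    removal fraction then steps up by ``ecco2r_step`` to ``ecco2r_max``; at
    each level the titration restarts from the protocol initial settings.
    The first successful level is returned (as a treatment success carrying
    that level); if every level fails the last failing run is returned.

    ``base_result`` may carry the patient's already-computed phi = 0 run
    (titration is deterministic, so recomputation would be identical).
    """
    base = base_result if base_result is not None else run_titration(
        patient, initial_settings(mode), policy, constants,
        keep_trajectory=False)
    if base.success:
        raise ValidationError(
            f"patient {patient.id} succeeds without ECCO2R; escalation "
            "applies only to titration failures"
        )
    n_levels = round(policy.ecco2r_max / policy.ecco2r_step)
    result = base
    for lvl in range(1, n_levels + 1):
        phi = round(lvl * policy.ecco2r_step, 10)
        result = run_titration(
            patient, initial_settings(mode, ecco2r_frac=phi), policy,
            constants, keep_trajectory=keep_trajectory,
        )
        if result.success:
            return TitrationResult(
                status="treatment_success",
                iterations_used=result.iterations_used,
                final_settings=result.final_settings,
                final_state=result.final_state,
                ecco2r_frac=phi, trajectory=result.trajectory,
            )
    return TitrationResult(
        status="failure", iterations_used=result.iterations_used,
        final_settings=result.final_settings, final_state=result.final_state,
        ecco2r_frac=0.0, trajectory=result.trajectory,
    )


def awake_ecco2r(
    patient: PatientParameters,
    policy: TitrationPolicy = TitrationPolicy(),
    constants: ModelConstants = ModelConstants(),
    keep_trajectory: bool = False,
) -> TitrationResult:
    """Extracorporeal CO2 removal alone: zero support, zero sedation.

    No titration of ventilation or sedation occurs; the removal fraction is
    swept from 0 up to the maximum and the first level meeting all targets
    is a success (a primary success if that level is zero).
    """
    n_levels = round(policy.ecco2r_max / policy.ecco2r_step)
    trajectory = []
    result_state = None
    result_settings = None
    for lvl in range(0, n_levels + 1):
        phi = round(lvl * policy.ecco2r_step, 10)
        settings = VentilatorSettings(mode="psv", ps=0.0, propofol=0.0,
                                      ecco2r_frac=phi)
        state = solve_steady_state(patient, settings, constants)
        assessment = assess_targets(state)
        if keep_trajectory:
            trajectory.append((settings, state, assessment))
        result_state, result_settings = state, settings
        if assessment.all_ok:
            return TitrationResult(
                status="primary_success" if lvl == 0 else "treatment_success",
                iterations_used=0, final_settings=settings,
                final_state=state, ecco2r_frac=phi, trajectory=trajectory,
            )
    return TitrationResult(
        status="failure", iterations_used=0,
        final_settings=result_settings, final_state=result_state,
        ecco2r_frac=0.0, trajectory=trajectory,
    )
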