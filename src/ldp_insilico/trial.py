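"""Trial orchestration: arms, replicates, and success-rate statistics.

One trial replicate samples a fresh virtual population and pushes the same
population through every intervention arm (no randomisation is needed: the
arms are counterfactuals on identical patients).  Success proportions are
summarised with Wilson score intervals per arm, and across replicates with
a t-interval on the replicate proportions; arm contrasts are odds ratios
with Woolf confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, ValidationError
from .physiology import ModelConstants, VentilatorSettings
from .population import PatientParameters, sample_population
from .titration import (
    TitrationPolicy,
    TitrationResult,
    awake_ecco2r,
    escalate_ecco2r,
    initial_settings,
    run_titration,
)

__all__ = [
    "ArmSpec",
    "ARMS",
    "TrialSummary",
    "run_arm",
    "run_trial",
    "summarize_with_ci",
    "compare_arms_or",
    "results_frame",
]


@dataclass(frozen=True)
class ArmSpec:
    """One intervention arm of the in silico trial."""

    name: str             # psv | pav | psv_ecco2r | pav_ecco2r | awake_ecco2r
    mode: str             # underlying ventilator mode
    ecco2r: str = "none"  # none | escalate | awake


#: The five pre-defined arms.
ARMS: dict[str, ArmSpec] = {
    "psv": ArmSpec("psv", "psv"),
    "pav": ArmSpec("pav", "pav"),
    "psv_ecco2r": ArmSpec("psv_ecco2r", "psv", ecco2r="escalate"),
    "pav_ecco2r": ArmSpec("pav_ecco2r", "pav", ecco2r="escalate"),
    "awake_ecco2r": ArmSpec("awake_ecco2r", "psv", ecco2r="awake"),
}


def run_arm(
    population: Sequence[PatientParameters],
    arm: ArmSpec,
    policy: TitrationPolicy = TitrationPolicy(),
    constants: ModelConstants = ModelConstants(),
    base_results: Sequence[TitrationResult] | None = None,
    keep_trajectory: bool = True,
) -> list[TitrationResult]:
    """Run one arm over the whole population; deterministic per patient.

    For the escalation arms, ``base_results`` may supply the matching
    plain-titration arm's results so that only its failures are re-simulated
    under extracorporeal removal (the phi = 0 runs are identical either way).
    """
    if not population:
        raise ValidationError("population must be nonempty")
    results: list[TitrationResult] = []
    if arm.ecco2r == "awake":
        for p in population:
            results.append(awake_ecco2r(p, policy, constants))
        return results
    if base_results is not None and len(base_results) != len(population):
        raise ValidationError("base_results length must match population")
    for i, p in enumerate(population):
        base = base_results[i] if base_results is not None else run_titration(
            p, initial_settings(arm.mode), policy, constants,
            keep_trajectory=keep_trajectory)
        if arm.ecco2r == "none":
            results.append(base)
        elif base.success:
            results.append(base)
        else:
            results.append(
                escalate_ecco2r(p, arm.mode, policy, constants,
                                base_result=base)
            )
    return results


# ---------------------------------------------------------------------------
# proportion statistics


def summarize_with_ci(successes: int, n: int, alpha: float = 0.05) -> dict:
    """Success proportion with a Wilson score interval (and the Wald
    normal-approximation interval for comparison)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValidationError("successes must lie in [0, n]")
    p = successes / n
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="wilson")
    wlo, whi = proportion_confint(successes, n, alpha=alpha, method="normal")
    return {
        "proportion": p, "ci_low": float(lo), "ci_high": float(hi),
        "wald_low": float(wlo), "wald_high": float(whi), "n": n,
        "successes": successes,
    }


def compare_arms_or(success_a: int, n_a: int, success_b: int, n_b: int,
                    alpha: float = 0.05) -> dict:
    """Odds ratio of success in arm a vs arm b, with a Woolf CI and p-value.

    Adds a 0.5 continuity correction to every cell when any cell is zero
    (the table is flagged as corrected).
    """
    for val, tot in ((success_a, n_a), (success_b, n_b)):
        if tot < 1 or not 0 <= val <= tot:
            raise ValidationError("counts must satisfy 0 <= successes <= n >= 1")
    a, b = float(success_a), float(success_b)
    c, d = float(n_a - success_a), float(n_b - success_b)
    corrected = any(x == 0 for x in (a, b, c, d))
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (c * b)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_)
    pval = 2 * sps.norm.sf(abs(log_or) / se)
    return {
        "odds_ratio": or_,
        "ci_low": math.exp(log_or - z * se),
        "ci_high": math.exp(log_or + z * se),
        "p_value": pval,
        "continuity_corrected": corrected,
    }


# ---------------------------------------------------------------------------
# whole-trial orchestration


@dataclass
class TrialSummary:
    per_arm: pd.DataFrame          # pooled counts/proportions per arm
    per_replicate: pd.DataFrame    # per (replicate, arm) counts/proportions
    across_replicates: pd.DataFrame  # mean proportion + t-interval per arm
    contrasts: pd.DataFrame        # odds-ratio comparisons
    seeds: list[int] = field(default_factory=list)


def results_frame(population: Sequence[PatientParameters],
                  results: Sequence[TitrationResult],
                  arm: str, replicate: int = 0) -> pd.DataFrame:
    """Per-patient outcome table for one arm."""
    rows = []
    for p, r in zip(population, results):
        st = r.final_state
        rows.append({
            "replicate": replicate, "arm": arm, "patient_id": p.id,
            "status": r.status, "success": r.success,
            "iterations_used": r.iterations_used,
            "ecco2r_frac": r.ecco2r_frac,
            "ecco2r_rate": r.ecco2r_frac * p.vco2,
            "mode": r.final_settings.mode,
            "ps": r.final_settings.ps, "gain": r.final_settings.gain,
            "propofol": r.final_settings.propofol,
            "pmus": st.pmus, "vt": st.vt, "ve": st.ve, "paco2": st.paco2,
            "ph": st.ph, "dpes": st.dpes, "dpl_dyn": st.dpl_dyn, "vr": st.vr,
        })
    return pd.DataFrame(rows)


_CONTRAST_PAIRS = (("pav", "psv"), ("psv_ecco2r", "psv"),
                   ("pav_ecco2r", "pav"), ("awake_ecco2r", "psv_ecco2r"))


def run_trial(
    n_patients: int = 5000,
    replicates: int = 10,
    master_seed: int = 0,
    arms: Sequence[str] = tuple(ARMS),
    policy: TitrationPolicy = TitrationPolicy(),
    constants: ModelConstants = ModelConstants(),
    population_specs=None,
) -> tuple[TrialSummary, pd.DataFrame]:
    """Run the full in silico trial.

    Each replicate draws a fresh population from a per-replicate seed spawned
    deterministically from ``master_seed`` (seed_r = SeedSequence(master_seed)
    child r) and pushes the same population through every requested arm.
    Returns the summary plus the concatenated per-patient outcome table.
    """
    unknown = [a for a in arms if a not in ARMS]
    if unknown:
        raise ConfigurationError(f"unknown arms: {unknown}")
    if replicates < 1 or n_patients < 1:
        raise ConfigurationError("replicates and n_patients must be >= 1")

    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed).spawn(replicates)]
    patient_frames = []
    rep_rows = []
    for r, seed in enumerate(seeds):
        population = sample_population(population_specs, n=n_patients, seed=seed)
        arm_results: dict[str, list[TitrationResult]] = {}
        for arm_name in arms:
            arm = ARMS[arm_name]
            base = arm_results.get(arm.mode) if arm.ecco2r == "escalate" else None
            res = run_arm(population, arm, policy, constants,
                          base_results=base, keep_trajectory=False)
            arm_results[arm_name] = res
            patient_frames.append(results_frame(population, res, arm_name, r))
            n_primary = sum(x.status == "primary_success" for x in res)
            n_success = sum(x.success for x in res)
            ci = summarize_with_ci(n_success, n_patients)
            rep_rows.append({
                "replicate": r, "arm": arm_name, "seed": seed,
                "n": n_patients, "n_primary_success": n_primary,
                "n_treatment_success": n_success - n_primary,
                "n_success": n_success,
                "proportion": ci["proportion"],
                "ci_low": ci["ci_low"], "ci_high": ci["ci_high"],
            })

    per_replicate = pd.DataFrame(rep_rows)
    patients = pd.concat(patient_frames, ignore_index=True)

    arm_rows = []
    for arm_name in arms:
        sub = per_replicate[per_replicate["arm"] == arm_name]
        successes = int(sub["n_success"].sum())
        total = int(sub["n"].sum())
        ci = summarize_with_ci(successes, total)
        arm_rows.append({
            "arm": arm_name, "n": total, "n_success": successes,
            "n_primary_success": int(sub["n_primary_success"].sum()),
            "proportion": ci["proportion"],
            "ci_low": ci["ci_low"], "ci_high": ci["ci_high"],
        })
    per_arm = pd.DataFrame(arm_rows)

    across_rows = []
    for arm_name in arms:
        props = per_replicate.loc[per_replicate["arm"] == arm_name,
                                  "proportion"].to_numpy()
        mean = float(props.mean())
        if len(props) > 1 and props.std(ddof=1) > 0:
            half = sps.t.ppf(0.975, len(props) - 1) * props.std(ddof=1) / \
                math.sqrt(len(props))
        else:
            half = 0.0
        across_rows.append({"arm": arm_name, "replicates": len(props),
                            "mean_proportion": mean,
                            "ci_low": mean - half, "ci_high": mean + half})
    across = pd.DataFrame(across_rows)

    contrast_rows = []
    for a, b in _CONTRAST_PAIRS:
        if a in arms and b in arms:
            ra = per_arm.set_index("arm").loc[a]
            rb = per_arm.set_index("arm").loc[b]
            cmp = compare_arms_or(int(ra["n_success"]), int(ra["n"]),
                                  int(rb["n_success"]), int(rb["n"]))
            contrast_rows.append({"arm_a": a, "arm_b": b, **cmp})
    contrasts = pd.DataFrame(contrast_rows)

    summary = TrialSummary(per_arm=per_arm, per_replicate=per_replicate,
                           across_replicates=across, contrasts=contrasts,
                           seeds=seeds)
    return summary, patients
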