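"""Determinants of treatment success, the logistic success model, and the
ECCO2R score.

The analysis layer treats the simulated trial like an observed cohort:
patient-level clinical parameters (plus the baseline ventilatory ratio)
predict treatment success in the pressure-support arm without
extracorporeal support.  A random forest ranks predictor influence, the top
three feed a logistic model whose discrimination is the C-statistic, and a
bedside score (normalised respiratory-system elastance + ventilatory
ratio) stratifies the benefit of adjunctive extracorporeal CO2 removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .errors import ValidationError
from .population import PatientParameters
from .titration import TitrationResult

__all__ = [
    "FOREST_FEATURES",
    "build_predictor_table",
    "variable_importance",
    "fit_success_model",
    "c_statistic",
    "ecco2r_score",
    "score_stratification",
]

#: Predictors offered to the random forest: sampled patient characteristics
#: that are measurable at the bedside, plus the baseline ventilatory ratio.
#: The latent ventilatory-control parameters and the two dead-space
#: parameters are deliberately excluded: the former are unobservable, and
#: the latter enter clinical practice only through their surrogate, the
#: ventilatory ratio.
FOREST_FEATURES = (
    "age", "weight", "height", "sex_female", "pao2", "vco2", "r_rs",
    "peep_i", "c_lung", "c_cw", "sid", "rr", "vr",
)


def build_predictor_table(
    population: Sequence[PatientParameters],
    results: Sequence[TitrationResult],
) -> pd.DataFrame:
    """Per-patient predictor table with the treatment-success label.

    ``results`` must come from the plain pressure-support arm (no
    extracorporeal support); its trajectory's iteration-0 state provides the
    baseline ventilatory ratio.  Derived elastance columns are carried for
    the ECCO2R score.
    """
    if len(population) != len(results):
        raise ValidationError("population and results lengths differ")
    rows = []
    for p, r in zip(population, results):
        if not r.trajectory:
            raise ValidationError(
                f"patient {p.id}: result lacks a trajectory (baseline state "
                "needed for the ventilatory ratio)"
            )
        baseline = r.trajectory[0][1]
        mech = p.mechanics()
        rows.append({
            "patient_id": p.id, "age": p.age, "weight": p.weight,
            "height": p.height, "sex_female": 1.0 if p.sex == "female" else 0.0,
            "pao2": p.pao2, "vco2": p.vco2, "vd_anat": p.vd_anat,
            "f_alv_ds": p.f_alv_ds, "r_rs": p.r_rs, "peep_i": p.peep_i,
            "c_lung": p.c_lung, "c_cw": p.c_cw, "sid": p.sid, "rr": p.rr,
            "e_rs": mech.e_rs, "ers_norm": mech.e_rs * mech.pbw / 1000.0,
            "vr": baseline.vr,
            "success": 1 if r.success else 0,
        })
    table = pd.DataFrame(rows)
    if table.isna().any().any():
        raise ValidationError("predictor table contains missing values")
    return table


def variable_importance(
    table: pd.DataFrame,
    seed: int = 0,
    features: Sequence[str] = FOREST_FEATURES,
    n_trees: int = 500,
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Permutation importance of each predictor for treatment success.

    Fits a seeded random forest (500 trees, default depth) on half the
    table and scores each feature by the mean accuracy drop on the held-out
    half over ``n_repeats`` permutations; held-out evaluation keeps the
    importances of uninformative features at zero instead of rewarding
    memorisation.  Returns the full ranking, most influential first.
    """
    y = table["success"].to_numpy()
    if y.min() == y.max():
        raise ValidationError("success label must contain both classes")
    X = table.loc[:, list(features)]
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(table))
    half = len(table) // 2
    fit_idx, eval_idx = idx[:half], idx[half:]
    if y[eval_idx].min() == y[eval_idx].max() or \
            y[fit_idx].min() == y[fit_idx].max():
        raise ValidationError("both classes required in each importance split")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                    n_jobs=1)
    forest.fit(X.iloc[fit_idx], y[fit_idx])
    perm = permutation_importance(forest, X.iloc[eval_idx], y[eval_idx],
                                  n_repeats=n_repeats,
                                  random_state=seed, n_jobs=1)
    out = pd.DataFrame({
        "feature": list(features),
        "importance": perm.importances_mean,
        "importance_sd": perm.importances_std,
    }).sort_values("importance", ascending=False, ignore_index=True)
    return out


@dataclass
class SuccessModel:
    predictors: tuple[str, ...]
    coefficients: dict[str, float]   # includes "intercept"
    std_errors: dict[str, float]
    probabilities: np.ndarray        # in-sample predicted P(success)
    separation_flagged: bool = False


def fit_success_model(table: pd.DataFrame,
                      predictors: Sequence[str]) -> SuccessModel:
    """Maximum-likelihood logistic model of treatment success.

    Perfect (or quasi-) separation is flagged and handled by an L2-penalised
    refit so coefficients stay finite.
    """
    missing = [p for p in predictors if p not in table.columns]
    if missing:
        raise ValidationError(f"predictors not in table: {missing}")
    X = table.loc[:, list(predictors)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        flat = [p for p, s in zip(predictors, X.std(axis=0)) if s == 0]
        raise ValidationError(f"zero-variance predictors: {flat}")
    y = table["success"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValidationError("success label must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    flagged = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 1e3):
            raise np.linalg.LinAlgError("separation suspected")
        params, bse = fit.params, fit.bse
        probs = fit.predict(Xc)
    except Exception:
        flagged = True
        fit = sm.Logit(y, Xc).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0,
                                              maxiter=500)
        params = np.asarray(fit.params)
        bse = np.full_like(params, np.nan)
        probs = 1.0 / (1.0 + np.exp(-Xc @ params))
    names = ["intercept", *predictors]
    return SuccessModel(
        predictors=tuple(predictors),
        coefficients=dict(zip(names, map(float, params))),
        std_errors=dict(zip(names, map(float, bse))),
        probabilities=np.asarray(probs, dtype=float),
        separation_flagged=flagged,
    )


def c_statistic(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney midrank identity.

    Equals the probability that a randomly chosen success outranks a
    randomly chosen failure in predicted probability, with ties counted 1/2.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError("both classes must be present")
    ranks = rankdata(probs)           # midranks for ties
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def ecco2r_score(e_rs: float, pbw: float, vr: float) -> float:
    """Bedside ECCO2R score: normalised elastance plus ventilatory ratio.

    Elastance is expressed per mL/kg-PBW of inflation (e_rs * PBW / 1000),
    which puts it on the same numeric scale (~1-4) as the ventilatory ratio
    so the unweighted sum keeps both components influential.
    """
    if e_rs <= 0 or pbw <= 0 or vr < 0:
        raise ValidationError("e_rs and pbw must be > 0 and vr >= 0")
    return e_rs * pbw / 1000.0 + vr


def score_stratification(
    scores: Sequence[float],
    success_no_ecco2r: Sequence[bool],
    success_with_ecco2r: Sequence[bool],
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Success proportions by ECCO2R-score bin, with and without rescue.

    Bins cover [floor(min), ceil(max)) in steps of ``bin_width``.  Empty
    bins appear with NaN proportions (missing, not zero).
    """
    scores = np.asarray(scores, dtype=float)
    s0 = np.asarray(success_no_ecco2r, dtype=bool)
    s1 = np.asarray(success_with_ecco2r, dtype=bool)
    if not (len(scores) == len(s0) == len(s1)):
        raise ValidationError("input lengths differ")
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    lo = np.floor(scores.min())
    hi = np.ceil(scores.max())
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for left, right in zip(edges[:-1], edges[1:]):
        mask = (scores >= left) & (scores < right)
        n = int(mask.sum())
        if n == 0:
            rows.append({"bin_left": left, "bin_right": right, "n": 0,
                         "success_no_ecco2r": np.nan,
                         "success_with_ecco2r": np.nan, "difference": np.nan})
        else:
            p0 = float(s0[mask].mean())
            p1 = float(s1[mask].mean())
            rows.append({"bin_left": left, "bin_right": right, "n": n,
                         "success_no_ecco2r": p0, "success_with_ecco2r": p1,
                         "difference": p1 - p0})
    return pd.DataFrame(rows)
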