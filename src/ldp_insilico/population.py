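"""Virtual patient population for the in silico ventilation trial.

Each virtual patient is a vector of fixed physiological and demographic
parameters (mechanics, gas exchange, acid-base, ventilatory control) drawn
independently from published acute-respiratory-failure distributions.  The
same sampled population is reused across every simulated intervention arm,
so the only randomness in a trial replicate is the population draw itself.

Parameters are sampled by inverse-CDF transforms of a single seeded uniform
stream, which makes populations bitwise reproducible for a given seed and
spec set.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ValidationError

__all__ = [
    "DistributionSpec",
    "PatientParameters",
    "DerivedMechanics",
    "default_population_specs",
    "predicted_body_weight",
    "sample_population",
    "population_to_frame",
    "write_population",
    "read_population",
]


# ---------------------------------------------------------------------------
# distribution specs


@dataclass(frozen=True)
class DistributionSpec:
    """One marginal sampling distribution.

    family:
      ``truncnorm``     -- normal(mean, sd) truncated to [lower, upper]
      ``trunclognorm``  -- lognormal with log-scale parameters (mu, sigma)
                           truncated to [lower, upper]
      ``bernoulli``     -- success probability ``p`` (lower/upper unused)
    """

    family: str
    lower: float = -math.inf
    upper: float = math.inf
    mean: float | None = None
    sd: float | None = None
    mu: float | None = None
    sigma: float | None = None
    p: float | None = None

    def validate(self, name: str) -> None:
        if self.family not in ("truncnorm", "trunclognorm", "bernoulli"):
            raise ConfigurationError(f"{name}: unknown family {self.family!r}")
        if self.family == "bernoulli":
            if self.p is None or not 0.0 <= self.p <= 1.0:
                raise ConfigurationError(f"{name}: bernoulli p must lie in [0, 1]")
            return
        if not self.lower < self.upper:
            raise ConfigurationError(
                f"{name}: lower bound {self.lower} must be < upper bound {self.upper}"
            )
        if self.family == "truncnorm":
            if self.mean is None or self.sd is None or self.sd <= 0:
                raise ConfigurationError(f"{name}: truncnorm needs mean and sd > 0")
        else:
            if self.mu is None or self.sigma is None or self.sigma <= 0:
                raise ConfigurationError(
                    f"{name}: trunclognorm needs log-scale mu and sigma > 0"
                )
            if self.lower <= 0:
                raise ConfigurationError(f"{name}: trunclognorm lower bound must be > 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function of the truncated distribution (u in (0,1))."""
        if self.family == "bernoulli":
            return (u < self.p).astype(float)
        if self.family == "truncnorm":
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            return sps.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)
        # truncated lognormal via the underlying normal of log(x)
        a = (math.log(self.lower) - self.mu) / self.sigma
        b = (math.log(self.upper) - self.mu) / self.sigma if math.isfinite(self.upper) else math.inf
        z = sps.truncnorm.ppf(u, a, b)
        return np.exp(self.mu + self.sigma * z)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """CDF of the truncated distribution (inverse of :meth:`ppf`)."""
        if self.family == "bernoulli":
            raise ConfigurationError("cdf undefined for bernoulli specs")
        if self.family == "truncnorm":
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            return sps.truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd)
        a = (math.log(self.lower) - self.mu) / self.sigma
        b = (math.log(self.upper) - self.mu) / self.sigma if math.isfinite(self.upper) else math.inf
        z = (np.log(x) - self.mu) / self.sigma
        return sps.truncnorm.cdf(z, a, b)


def lognormal_from_moments(mean: float, sd: float, lower: float, upper: float) -> DistributionSpec:
    """Lognormal spec whose *untruncated* arithmetic mean/SD match (mean, sd)."""
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("lognormal moments must be positive")
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return DistributionSpec(
        family="trunclognorm", lower=lower, upper=upper, mu=mu, sigma=math.sqrt(sigma2)
    )


def lognormal_from_median_gsd(median: float, gsd: float, lower: float, upper: float) -> DistributionSpec:
    """Lognormal spec from median and geometric SD (gsd > 1)."""
    if median <= 0 or gsd <= 1.0:
        raise ConfigurationError("median must be > 0 and geometric SD > 1")
    return DistributionSpec(
        family="trunclognorm", lower=lower, upper=upper,
        mu=math.log(median), sigma=math.log(gsd),
    )


def _tnorm(mean: float, sd: float, floor: float = -math.inf, ceil: float = math.inf) -> DistributionSpec:
    """Truncated normal over [mean - 3 SD, mean + 3 SD] clipped to physical bounds."""
    return DistributionSpec(
        family="truncnorm", mean=mean, sd=sd,
        lower=max(mean - 3 * sd, floor), upper=min(mean + 3 * sd, ceil),
    )


def default_population_specs(
    g_chemo_median: float = 1.8, b_apnea_mean: float = 34.0
) -> dict[str, DistributionSpec]:
    """Default marginal distributions of the simulated trial population.

    Clinical parameters use the published cohort means/SDs; chest wall
    compliance is strongly right-skewed (SD larger than mean) and uses a
    moment-matched lognormal so that no negative compliances arise.  The two
    ventilatory-control parameters (chemoreflex gain, apneic threshold) are
    not observable clinically; their location parameters are calibration
    targets and can be overridden here.
    """
    return {
        "age": _tnorm(55.0, 10.0, floor=18.0),
        "weight": _tnorm(85.0, 15.0, floor=35.0),
        "height": _tnorm(1.70, 0.08, floor=1.30, ceil=2.10),
        "sex": DistributionSpec(family="bernoulli", p=0.49),  # p = female
        "pao2": _tnorm(100.0, 19.0, floor=40.0),
        "vco2": _tnorm(223.0, 37.0, floor=80.0),
        "vd_anat": _tnorm(128.0, 29.0, floor=40.0),
        "f_alv_ds": _tnorm(0.37, 0.14, floor=0.0, ceil=0.85),
        "r_rs": _tnorm(11.0, 2.4, floor=2.0),
        "peep_i": _tnorm(1.5, 0.8, floor=0.0),
        "c_lung": _tnorm(47.0, 13.0, floor=8.0),
        "c_cw": lognormal_from_moments(125.0, 180.0, lower=40.0, upper=600.0),
        "sid": _tnorm(34.0, 7.0, floor=15.0, ceil=55.0),
        "rr": _tnorm(28.0, 5.0, floor=8.0, ceil=45.0),
        "g_chemo": lognormal_from_median_gsd(g_chemo_median, 1.6, lower=0.3, upper=8.0),
        "b_apnea": DistributionSpec(
            family="truncnorm", mean=b_apnea_mean, sd=4.0, lower=25.0, upper=45.0
        ),
    }


# fixed sampling order: one uniform vector per name, drawn in this order
_SAMPLING_ORDER = (
    "age", "weight", "height", "sex", "pao2", "vco2", "vd_anat", "f_alv_ds",
    "r_rs", "peep_i", "c_lung", "c_cw", "sid", "rr", "g_chemo", "b_apnea",
)


# ---------------------------------------------------------------------------
# patient record


@dataclass(frozen=True)
class DerivedMechanics:
    """Quantities derived from the sampled parameters (never sampled)."""

    pbw: float        # predicted body weight, kg
    e_lung: float     # lung elastance, cmH2O/L
    e_cw: float       # chest wall elastance, cmH2O/L
    e_rs: float       # respiratory system elastance, cmH2O/L
    c_rs: float       # respiratory system compliance, mL/cmH2O


@dataclass(frozen=True)
class PatientParameters:
    """One virtual patient's fixed parameters.

    Units: weight kg; height m; pao2/b_apnea mmHg; vco2 mL/min STPD;
    vd_anat mL; r_rs cmH2O/(L/s); peep_i cmH2O; compliances mL/cmH2O;
    sid mEq/L; rr breaths/min; g_chemo cmH2O per mmHg CO2.
    """

    id: int
    age: float
    weight: float
    height: float
    sex: str          # "female" | "male"
    pao2: float
    vco2: float
    vd_anat: float
    f_alv_ds: float
    r_rs: float
    peep_i: float
    c_lung: float
    c_cw: float
    sid: float
    rr: float
    g_chemo: float
    b_apnea: float

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positives = (
            "age", "weight", "height", "pao2", "vco2", "vd_anat",
            "r_rs", "c_lung", "c_cw", "g_chemo", "b_apnea",
        )
        for name in positives:
            if not getattr(self, name) > 0:
                raise ValidationError(f"patient {self.id}: {name} must be > 0")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"patient {self.id}: sex must be female/male")
        if self.peep_i < 0:
            raise ValidationError(f"patient {self.id}: peep_i must be >= 0")
        if not 0.0 <= self.f_alv_ds <= 0.9:
            raise ValidationError(f"patient {self.id}: f_alv_ds outside [0, 0.9]")
        if not 8.0 <= self.rr <= 45.0:
            raise ValidationError(f"patient {self.id}: rr outside [8, 45]")
        if not 15.0 <= self.sid <= 60.0:
            raise ValidationError(f"patient {self.id}: sid outside [15, 60]")

    @property
    def pbw(self) -> float:
        return predicted_body_weight(self.sex, self.height)

    @property
    def e_lung(self) -> float:
        return 1000.0 / self.c_lung

    @property
    def e_cw(self) -> float:
        return 1000.0 / self.c_cw

    @property
    def e_rs(self) -> float:
        return self.e_lung + self.e_cw

    def mechanics(self) -> DerivedMechanics:
        e_rs = self.e_rs
        return DerivedMechanics(
            pbw=self.pbw, e_lung=self.e_lung, e_cw=self.e_cw,
            e_rs=e_rs, c_rs=1000.0 / e_rs,
        )


def predicted_body_weight(sex: str, height: float) -> float:
    """Devine predicted body weight (kg) from sex and height in metres.

    Floored at 30 kg so very short patients keep a physical weight.
    """
    if not 1.2 <= height <= 2.2:
        raise ValidationError(f"height {height} m outside [1.2, 2.2]")
    if sex not in ("female", "male"):
        raise ValidationError(f"sex must be 'female' or 'male', got {sex!r}")
    base = 50.0 if sex == "male" else 45.5
    return max(30.0, base + 0.91 * (height * 100.0 - 152.4))


# ---------------------------------------------------------------------------
# sampling


def sample_population(
    specs: dict[str, DistributionSpec] | None = None,
    n: int = 5000,
    seed: int = 0,
) -> list[PatientParameters]:
    """Draw ``n`` independent virtual patients.

    Deterministic for a given (specs, n, seed): one uniform vector is drawn
    per parameter in a fixed order from a single PCG64 stream and pushed
    through each marginal quantile function.
    """
    if n < 1:
        raise ConfigurationError("population size n must be >= 1")
    if specs is None:
        specs = default_population_specs()
    missing = [k for k in _SAMPLING_ORDER if k not in specs]
    if missing:
        raise ConfigurationError(f"missing distribution specs: {missing}")
    for name in _SAMPLING_ORDER:
        specs[name].validate(name)

    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in _SAMPLING_ORDER:
        u = rng.random(n)
        draws[name] = specs[name].ppf(u)

    patients = []
    for i in range(n):
        patients.append(
            PatientParameters(
                id=i,
                age=float(draws["age"][i]),
                weight=float(draws["weight"][i]),
                height=float(draws["height"][i]),
                sex="female" if draws["sex"][i] > 0.5 else "male",
                pao2=float(draws["pao2"][i]),
                vco2=float(draws["vco2"][i]),
                vd_anat=float(draws["vd_anat"][i]),
                f_alv_ds=float(draws["f_alv_ds"][i]),
                r_rs=float(draws["r_rs"][i]),
                peep_i=float(draws["peep_i"][i]),
                c_lung=float(draws["c_lung"][i]),
                c_cw=float(draws["c_cw"][i]),
                sid=float(draws["sid"][i]),
                rr=float(draws["rr"][i]),
                g_chemo=float(draws["g_chemo"][i]),
                b_apnea=float(draws["b_apnea"][i]),
            )
        )
    return patients


def population_to_frame(patients: Sequence[PatientParameters]) -> pd.DataFrame:
    """Tabular view of a population, including derived mechanics columns."""
    rows = []
    for p in patients:
        row = {f.name: getattr(p, f.name) for f in fields(PatientParameters)}
        mech = p.mechanics()
        row.update(pbw=mech.pbw, e_lung=mech.e_lung, e_cw=mech.e_cw,
                   e_rs=mech.e_rs, c_rs=mech.c_rs)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round trip

_CSV_FIELDS = tuple(f.name for f in fields(PatientParameters))


def write_population(patients: Sequence[PatientParameters], path) -> None:
    """Write one row per patient; floats at full repr precision."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for p in patients:
            w.writerow([repr(v) if isinstance(v := getattr(p, name), float) else v
                        for name in _CSV_FIELDS])


def read_population(path) -> list[PatientParameters]:
    """Read a population CSV written by :func:`write_population`.

    Raises a parse/validation error naming the offending data row.
    """
    patients = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected a header row")
        if tuple(header) != _CSV_FIELDS:
            raise ValidationError(f"{path}: unexpected header {header}")
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(_CSV_FIELDS):
                raise ValidationError(f"{path}: row {rownum}: expected "
                                      f"{len(_CSV_FIELDS)} fields, got {len(row)}")
            kwargs = {}
            for name, raw in zip(_CSV_FIELDS, row):
                if name == "sex":
                    kwargs[name] = raw
                elif name == "id":
                    kwargs[name] = int(raw)
                else:
                    try:
                        kwargs[name] = float(raw)
                    except ValueError as exc:
                        raise ValidationError(
                            f"{path}: row {rownum}: bad value for {name}: {raw!r}"
                        ) from exc
            try:
                patients.append(PatientParameters(**kwargs))
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {rownum}: {exc}") from exc
    return patients
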