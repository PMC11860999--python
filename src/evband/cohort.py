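"""Synthetic virtual-patient cohort generation and weight-quartile partitioning.

The simulation needs a demographically realistic adult European cohort whose
body weights drive both the mg/kg dose and the allometric PK scaling.  Weights
are drawn from a sex-stratified log-normal distribution truncated to a
plausibility range; the default parameters in :mod:`evband.config` are
calibrated so that the population-average capped 1.25 mg/kg dose matches the
registrational simulation cohort (~90 mg per administration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Subject",
    "SexWeightDistribution",
    "DemographicsConfig",
    "Cohort",
    "WeightQuartiles",
    "generate_cohort",
    "weight_quartiles",
    "read_cohort_csv",
    "write_cohort_csv",
]


class ConfigurationError(ValueError):
    """Raised for invalid demographic / distribution parameters."""


@dataclass(frozen=True)
class Subject:
    """A virtual patient.

    Attributes
    ----------
    id : str
        Unique identifier within a cohort.
    sex : str
        ``"female"`` or ``"male"``.
    age : float
        Age in years (adult); carried for covariate hooks, unused by the
        default PK model.
    body_weight : float
        Body weight in kg; must be positive and inside the configured
        plausibility range.
    """

    id: str
    sex: str
    age: float
    body_weight: float

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.body_weight > 0:
            raise ConfigurationError("body_weight must be positive")


@dataclass(frozen=True)
class SexWeightDistribution:
    """Log-scale normal law for body weight of one sex.

    ``mu`` and ``sigma`` are the mean and standard deviation of log(weight/kg).
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError("weight distribution scale must be positive")


@dataclass(frozen=True)
class DemographicsConfig:
    n: int
    seed: int
    sex_fraction_female: float
    female: SexWeightDistribution
    male: SexWeightDistribution
    weight_bounds: tuple[float, float] = (35.0, 150.0)
    age_range: tuple[float, float] = (40.0, 85.0)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("cohort size n must be >= 1")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigurationError("sex_fraction_female must be in [0, 1]")
        lo, hi = self.weight_bounds
        if not (0 < lo < hi):
            raise ConfigurationError("weight truncation bounds must be ordered and positive")


Cohort = list[Subject]


def _truncated_lognormal(rng: np.random.Generator, dist: SexWeightDistribution,
                         bounds: tuple[float, float], size: int) -> np.ndarray:
    """Draw from a log-normal truncated to ``bounds`` via the inverse CDF.

    Inverse-CDF sampling keeps the draw count fixed, so the cohort is
    reproducible from the seed regardless of the truncation mass.
    """
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    a = (lo - dist.mu) / dist.sigma
    b = (hi - dist.mu) / dist.sigma
    u = rng.uniform(size=size)
    z = stats.truncnorm.ppf(u, a, b)
    return np.exp(dist.mu + dist.sigma * z)


def generate_cohort(config: DemographicsConfig) -> Cohort:
    """Generate ``config.n`` virtual subjects, deterministically from the seed.

    Sex is Bernoulli(``sex_fraction_female``), weight is sex-stratified
    truncated log-normal, age is uniform on ``age_range``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    is_female = rng.uniform(size=n) < config.sex_fraction_female
    ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    weights = np.empty(n)
    # one uniform stream per sex keeps per-subject draws aligned with membership
    weights[is_female] = _truncated_lognormal(
        rng, config.female, config.weight_bounds, int(is_female.sum()))
    weights[~is_female] = _truncated_lognormal(
        rng, config.male, config.weight_bounds, int((~is_female).sum()))
    return [
        Subject(
            id=f"S{i + 1:04d}",
            sex="female" if is_female[i] else "male",
            age=float(round(ages[i], 1)),
            body_weight=float(weights[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class WeightQuartiles:
    """Cohort partition into four body-weight quartiles.

    ``boundaries`` are the 25/50/75th weight percentiles; ``assignment`` maps
    subject id -> quartile index (0 = lightest).  A subject whose weight equals
    a boundary is assigned to the lower quartile (documented tie rule).
    """

    boundaries: tuple[float, float, float]
    assignment: dict[str, int] = field(repr=False)

    def members(self, q: int) -> list[str]:
        return [sid for sid, qq in self.assignment.items() if qq == q]


def weight_quartiles(cohort: Cohort) -> WeightQuartiles:
    """Partition a cohort into weight quartiles at the 25/50/75th percentiles.

    Every subject lands in exactly one quartile.  Ties at a boundary go to the
    lower quartile (``searchsorted`` with side='left'); if all weights are
    equal the boundaries degenerate and all subjects fall in quartile 0.
    """
    if not cohort:
        raise ValueError("cannot compute quartiles of an empty cohort")
    w = np.array([s.body_weight for s in cohort])
    q25, q50, q75 = np.percentile(w, [25, 50, 75])
    bounds = np.array([q25, q50, q75])
    idx = np.searchsorted(bounds, w, side="left")
    assignment = {s.id: int(idx[i]) for i, s in enumerate(cohort)}
    return WeightQuartiles(boundaries=(float(q25), float(q50), float(q75)),
                           assignment=assignment)


_CSV_COLUMNS = ["id", "sex", "age", "body_weight"]


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write a cohort as UTF-8 CSV with columns id, sex, age, body_weight."""
    df = pd.DataFrame(
        [(s.id, s.sex, s.age, s.body_weight) for s in cohort], columns=_CSV_COLUMNS)
    df.to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path) -> Cohort:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cohort CSV missing columns: {missing}")
    cohort = [
        Subject(id=str(r.id), sex=str(r.sex), age=float(r.age),
                body_weight=float(r.body_weight))
        for r in df.itertuples(index=False)
    ]
    ids = [s.id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate subject ids in cohort CSV")
    return cohort
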