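"""Paired-population equivalence statistics for exposure endpoints.

Geometric means, geometric mean ratios (GMRs), coefficients of variation and
the conservative narrow-therapeutic-window equivalence rule: the regimens are
declared equivalent when the GMR of every endpoint lies inside 90-111%
(bounds inclusive).  Because the PK is linear and the simulation is paired
(same subjects, same random effects under both regimens), each subject's
metric ratio equals their dose ratio, so all four endpoint GMRs coincide
exactly with the geometric mean of the per-subject dose ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import WeightQuartiles
from .pkmodel import ENDPOINTS, ExposureMetrics

__all__ = [
    "EQUIVALENCE_BOUNDS",
    "EquivalenceResult",
    "QuartileSummary",
    "geometric_mean",
    "percent_cv",
    "gmr_paired",
    "equivalence_check",
    "distribution_summary",
]

EQUIVALENCE_BOUNDS = (0.90, 1.11)


def geometric_mean(values) -> float:
    """exp(mean(log x)); requires a non-empty, strictly positive sample."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of an empty sample")
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(x))))


def percent_cv(values, convention: str = "arithmetic") -> float:
    """Coefficient of variation in percent.

    ``arithmetic`` (default): 100 * sd(x)/mean(x) with the sample sd (ddof=1;
    0 for a single value).  ``geometric``: 100 * sqrt(exp(var(log x)) - 1).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("%CV of an empty sample")
    ddof = 1 if x.size > 1 else 0
    if convention == "arithmetic":
        return float(100.0 * np.std(x, ddof=ddof) / np.mean(x))
    if convention == "geometric":
        if np.any(x <= 0):
            raise ValueError("geometric %CV requires positive values")
        return float(100.0 * np.sqrt(np.exp(np.var(np.log(x), ddof=ddof)) - 1.0))
    raise ValueError(f"unknown %CV convention {convention!r}")


@dataclass(frozen=True)
class EquivalenceResult:
    endpoint: str
    gm_reference: float
    gm_alternative: float
    gmr: float
    cv_reference: float
    cv_alternative: float
    lower_bound: float = EQUIVALENCE_BOUNDS[0]
    upper_bound: float = EQUIVALENCE_BOUNDS[1]

    @property
    def passed(self) -> bool:
        return self.lower_bound <= self.gmr <= self.upper_bound


def equivalence_check(gmr: float,
                      bounds: tuple[float, float] = EQUIVALENCE_BOUNDS) -> bool:
    """Inclusive-bound equivalence decision on a geometric mean ratio."""
    if gmr <= 0:
        raise ValueError("GMR must be positive")
    lo, hi = bounds
    return lo <= gmr <= hi


MetricsMap = Mapping[str, ExposureMetrics]


def gmr_paired(reference: MetricsMap, alternative: MetricsMap,
               cv_convention: str = "arithmetic",
               bounds: tuple[float, float] = EQUIVALENCE_BOUNDS,
               ) -> dict[str, EquivalenceResult]:
    """Per-endpoint equivalence results from paired per-subject metrics.

    Both maps must be keyed by the same subject ids (same cohort, same
    individual random effects).  Subjects with a zero metric under either
    regimen are rejected (geometric statistics need positive values).
    """
    if set(reference) != set(alternative):
        raise ValueError("reference and alternative metrics cover different subjects")
    ids = sorted(reference)
    results = {}
    for endpoint in ENDPOINTS:
        ref = np.array([getattr(reference[i], endpoint) for i in ids])
        alt = np.array([getattr(alternative[i], endpoint) for i in ids])
        gm_ref = geometric_mean(ref)
        gm_alt = geometric_mean(alt)
        results[endpoint] = EquivalenceResult(
            endpoint=endpoint,
            gm_reference=gm_ref,
            gm_alternative=gm_alt,
            gmr=gm_alt / gm_ref,
            cv_reference=percent_cv(ref, cv_convention),
            cv_alternative=percent_cv(alt, cv_convention),
            lower_bound=bounds[0],
            upper_bound=bounds[1],
        )
    return results


@dataclass(frozen=True)
class QuartileSummary:
    """Boxplot-style summary of one metric per weight quartile and overall.

    ``per_quartile`` rows: quartile index, n, median, q1, q3, whisker_low,
    whisker_high (sample min/max).  ``flatness`` is the spread of quartile
    medians relative to the population median — smaller means more even
    exposure across the weight range.
    """

    endpoint: str
    per_quartile: pd.DataFrame
    population_median: float
    population_iqr: tuple[float, float]
    flatness: float


def distribution_summary(metrics: MetricsMap, quartiles: WeightQuartiles,
                         endpoint: str = "auc_ss") -> QuartileSummary:
    """Per-weight-quartile and population medians/IQR of one endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    missing = set(quartiles.assignment) - set(metrics)
    if missing:
        raise ValueError(f"metrics missing for subjects: {sorted(missing)[:5]} ...")
    values = {sid: getattr(metrics[sid], endpoint) for sid in quartiles.assignment}
    all_vals = np.array(list(values.values()))
    rows = []
    medians = []
    for q in range(4):
        vals = np.array([values[sid] for sid in quartiles.members(q)])
        if vals.size == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        medians.append(med)
        rows.append({"quartile": q, "n": vals.size, "median": med,
                     "q1": q1, "q3": q3,
                     "whisker_low": vals.min(), "whisker_high": vals.max()})
    pop_q1, pop_med, pop_q3 = np.percentile(all_vals, [25, 50, 75])
    flatness = (max(medians) - min(medians)) / pop_med if pop_med > 0 else 0.0
    return QuartileSummary(
        endpoint=endpoint,
        per_quartile=pd.DataFrame(rows),
        population_median=float(pop_med),
        population_iqr=(float(pop_q1), float(pop_q3)),
        flatness=float(flatness),
    )
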