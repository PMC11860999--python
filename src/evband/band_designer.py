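"""Derivation of whole-vial weight-band dose tables under equivalence constraints.

Given band edges, a virtual cohort and the population-PK model, the designer
picks for every band the smallest whole-vial dose whose band geometric-mean
exposure stays within the equivalence window of the reference target, subject
to three global constraints on the finished table: all four endpoint GMRs in
the equivalence window, no material increase in population %CV, and monotone
non-decreasing doses.  Among feasible tables the expected whole-vial drug use
is minimized, ties broken toward the lower dose.

Because the PK is linear and the simulation paired, a subject's exposure under
a candidate dose is (dose / reference dose) x reference exposure, which makes
the candidate search closed-form over precomputed per-mg exposures.

The default per-band target is the *population* reference geometric mean; a
``per_band_mode="band"`` variant compares each band against its own members'
reference exposure instead (a per-band GMR window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, weight_quartiles
from .equivalence import (EQUIVALENCE_BOUNDS, EquivalenceResult, distribution_summary,
                          geometric_mean, gmr_paired, percent_cv)
from .pkmodel import ENDPOINTS, PopPKParameters, draw_cohort_individuals
from .regimens import (BandTable, VialFormulary, WeightBand, drug_accounting,
                       monotherapy_schedule, simulate_exposures, vial_decomposition)

__all__ = [
    "DesignConstraints",
    "DesignReport",
    "InfeasibleDesignError",
    "candidate_doses",
    "design_bands",
    "design_bands_exhaustive",
    "evaluate_table",
    "LevelReport",
]


class InfeasibleDesignError(ValueError):
    """No candidate dose satisfies the constraints for at least one band."""


@dataclass(frozen=True)
class DesignConstraints:
    gmr_bounds: tuple[float, float] = EQUIVALENCE_BOUNDS
    per_band_gm_bounds: tuple[float, float] = EQUIVALENCE_BOUNDS
    max_cv_increase: float = 2.0        # percentage points
    dose_range_mg: tuple[float, float] = (20.0, 200.0)
    per_band_mode: str = "population"   # or "band"

    def __post_init__(self) -> None:
        if self.gmr_bounds[0] >= self.gmr_bounds[1]:
            raise ValueError("gmr_bounds must be ordered")
        if self.per_band_gm_bounds[0] >= self.per_band_gm_bounds[1]:
            raise ValueError("per_band_gm_bounds must be ordered")
        if self.per_band_mode not in ("population", "band"):
            raise ValueError("per_band_mode must be 'population' or 'band'")


@dataclass(frozen=True)
class DesignReport:
    table: BandTable
    per_band: pd.DataFrame           # band, n, candidates, chosen, band_gm_ratio
    gmrs: dict[str, float]
    cv_increase: dict[str, float]
    expected_vial_mg: float
    feasible: bool
    notes: tuple[str, ...] = ()


def candidate_doses(formulary: VialFormulary,
                    dose_range_mg: tuple[float, float]) -> list[float]:
    """All exact whole-vial sums within the range, ascending."""
    lo, hi = dose_range_mg
    sizes = formulary.sizes
    sums = {0.0}
    frontier = [0.0]
    while frontier:
        new = []
        for s in frontier:
            for size in sizes:
                t = s + size
                if t <= hi and t not in sums:
                    sums.add(t)
                    new.append(t)
        frontier = new
    return sorted(t for t in sums if lo <= t <= hi)


def _band_partition(cohort: Cohort, band_edges: Sequence[float]) -> list[list[int]]:
    edges = list(band_edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise ValueError("band_edges must be strictly increasing")
    bounds = [0.0] + edges + [math.inf]
    members: list[list[int]] = [[] for _ in range(len(bounds) - 1)]
    for i, subj in enumerate(cohort):
        w = subj.body_weight
        for b in range(len(bounds) - 1):
            if bounds[b] <= w < bounds[b + 1]:
                members[b].append(i)
                break
    return members


def _design_setup(level, band_edges, cohort, params, formulary, constraints, seed):
    """Shared precomputation: paired reference exposures and per-mg scale."""
    reference = monotherapy_schedule(level)
    individuals = draw_cohort_individuals(cohort, params, seed)
    ref_metrics = simulate_exposures(cohort, individuals, reference,
                                     infusion_duration=params.infusion_duration)
    ids = [s.id for s in cohort]
    ref_dose = np.array([reference.level * min(s.body_weight, reference.weight_cap_kg)
                         for s in cohort])
    ref_auc = np.array([ref_metrics[i].auc_ss for i in ids])
    members = _band_partition(cohort, band_edges)
    grid = candidate_doses(formulary, constraints.dose_range_mg)
    if not grid:
        raise ValueError("candidate dose grid is empty")
    pop_gm_ref = geometric_mean(ref_auc)
    return (reference, individuals, ref_metrics, ref_dose, ref_auc, members,
            grid, pop_gm_ref)


def _band_candidates(band_idx, members, grid, ref_dose, ref_auc, pop_gm_ref,
                     constraints) -> list[float]:
    """Doses whose band geometric-mean exposure sits in the per-band window."""
    idx = members[band_idx]
    if not idx:
        return list(grid)      # empty band: unconstrained, flagged by caller
    # exposure under dose d for subject i = d * (ref_auc_i / ref_dose_i)
    gm_per_mg = geometric_mean(ref_auc[idx] / ref_dose[idx])
    target = pop_gm_ref if constraints.per_band_mode == "population" \
        else geometric_mean(ref_auc[idx])
    lo, hi = constraints.per_band_gm_bounds
    return [d for d in grid if lo * target <= d * gm_per_mg <= hi * target]


def _table_from_doses(level, band_edges, doses) -> BandTable:
    bounds = [0.0] + list(band_edges) + [math.inf]
    bands = tuple(WeightBand(bounds[i], bounds[i + 1], doses[i])
                  for i in range(len(doses)))
    return BandTable(level=level, bands=bands)


def _global_stats(doses, members, ref_dose, ref_metrics, ids, cohort,
                  formulary, cv_convention="arithmetic"):
    """GMRs, %CV deltas and expected whole-vial mg for a full dose vector."""
    alt_dose = np.empty(len(cohort))
    for b, idx in enumerate(members):
        for i in idx:
            alt_dose[i] = doses[b]
    ratio = alt_dose / ref_dose
    gmr = geometric_mean(ratio)         # identical across endpoints (linear PK)
    gmrs = {ep: gmr for ep in ENDPOINTS}
    cv_inc = {}
    for ep in ENDPOINTS:
        ref_vals = np.array([getattr(ref_metrics[i], ep) for i in ids])
        alt_vals = ref_vals * ratio
        cv_inc[ep] = percent_cv(alt_vals, cv_convention) - percent_cv(ref_vals, cv_convention)
    vial_mg = []
    for d in alt_dose:
        counts = vial_decomposition(d, formulary)
        vial_mg.append(sum(s * n for s, n in counts.items()))
    return gmrs, cv_inc, float(np.mean(vial_mg))


def _globally_feasible(gmrs, cv_inc, constraints) -> bool:
    lo, hi = constraints.gmr_bounds
    return (all(lo <= g <= hi for g in gmrs.values())
            and all(dc <= constraints.max_cv_increase for dc in cv_inc.values()))


def design_bands(level: float, band_edges: Sequence[float], cohort: Cohort,
                 params: PopPKParameters, formulary: VialFormulary,
                 constraints: DesignConstraints = DesignConstraints(),
                 seed: int = 0) -> DesignReport:
    """Greedy per-band design with a global feasibility re-check.

    Each band gets the smallest candidate dose in its per-band window
    (monotonicity enforced across bands); if the finished table violates a
    global constraint, band doses are raised one grid step at a time, always
    taking the cheapest expected-mg increase, until feasible or exhausted.
    """
    (reference, individuals, ref_metrics, ref_dose, ref_auc, members,
     grid, pop_gm_ref) = _design_setup(level, band_edges, cohort, params,
                                       formulary, constraints, seed)
    ids = [s.id for s in cohort]
    notes = []
    cand: list[list[float]] = []
    for b in range(len(members)):
        cb = _band_candidates(b, members, grid, ref_dose, ref_auc, pop_gm_ref,
                              constraints)
        if not members[b]:
            notes.append(f"band {b} is empty in this cohort; dose unconstrained")
        if not cb:
            raise InfeasibleDesignError(
                f"no candidate dose satisfies the per-band window for band {b} "
                f"(edges {list(band_edges)})")
        cand.append(sorted(cb))

    # smallest per band, monotone non-decreasing
    doses = []
    for b, cb in enumerate(cand):
        floor = doses[-1] if doses else -math.inf
        feas = [d for d in cb if d >= floor]
        if not feas:
            raise InfeasibleDesignError(
                f"band {b}: no candidate >= previous band dose {floor} mg")
        doses.append(feas[0])

    gmrs, cv_inc, exp_mg = _global_stats(doses, members, ref_dose, ref_metrics,
                                         ids, cohort, formulary)
    while not _globally_feasible(gmrs, cv_inc, constraints):
        if all(g >= constraints.gmr_bounds[0] for g in gmrs.values()):
            # not a low-GMR problem: raising doses cannot fix CV/upper violations
            break
        best = None
        for b in range(len(doses)):
            higher = [d for d in cand[b] if d > doses[b]]
            if not higher:
                continue
            trial = list(doses)
            trial[b] = higher[0]
            if any(trial[i] > trial[i + 1] for i in range(len(trial) - 1)):
                continue
            g2, c2, m2 = _global_stats(trial, members, ref_dose, ref_metrics,
                                       ids, cohort, formulary)
            key = (m2 - exp_mg, b)
            if best is None or key < best[0]:
                best = (key, trial, g2, c2, m2)
        if best is None:
            break
        _, doses, gmrs, cv_inc, exp_mg = best

    feasible = _globally_feasible(gmrs, cv_inc, constraints)
    if not feasible:
        notes.append("global constraints not met by greedy search; table reported as-is")
    table = _table_from_doses(level, band_edges, doses)
    per_band = pd.DataFrame({
        "band": [band.label() for band in table.bands],
        "n": [len(m) for m in members],
        "n_candidates": [len(c) for c in cand],
        "dose_mg": doses,
    })
    return DesignReport(table=table, per_band=per_band, gmrs=gmrs,
                        cv_increase=cv_inc, expected_vial_mg=exp_mg,
                        feasible=feasible, notes=tuple(notes))


def design_bands_exhaustive(level: float, band_edges: Sequence[float],
                            cohort: Cohort, params: PopPKParameters,
                            formulary: VialFormulary,
                            constraints: DesignConstraints = DesignConstraints(),
                            seed: int = 0,
                            max_combinations: int = 2_000_000) -> DesignReport:
    """Validation oracle: exhaustive search over all per-band candidate doses.

    Minimizes expected whole-vial mg over every monotone, globally feasible
    table; ties broken toward the lexicographically lowest dose vector.
    Intended for small grids (raises if the candidate space is too large).
    """
    (reference, individuals, ref_metrics, ref_dose, ref_auc, members,
     grid, pop_gm_ref) = _design_setup(level, band_edges, cohort, params,
                                       formulary, constraints, seed)
    ids = [s.id for s in cohort]
    cand = []
    for b in range(len(members)):
        cb = _band_candidates(b, members, grid, ref_dose, ref_auc, pop_gm_ref,
                              constraints)
        if not cb:
            raise InfeasibleDesignError(f"no candidate dose for band {b}")
        cand.append(sorted(cb))
    n_comb = math.prod(len(c) for c in cand)
    if n_comb > max_combinations:
        raise ValueError(f"candidate space too large for exhaustive search ({n_comb})")
    best = None
    for doses in product(*cand):
        if any(doses[i] > doses[i + 1] for i in range(len(doses) - 1)):
            continue
        gmrs, cv_inc, exp_mg = _global_stats(doses, members, ref_dose,
                                             ref_metrics, ids, cohort, formulary)
        if not _globally_feasible(gmrs, cv_inc, constraints):
            continue
        key = (exp_mg, doses)
        if best is None or key < best[0]:
            best = (key, doses, gmrs, cv_inc, exp_mg)
    if best is None:
        raise InfeasibleDesignError("no globally feasible table exists on this grid")
    _, doses, gmrs, cv_inc, exp_mg = best
    table = _table_from_doses(level, band_edges, list(doses))
    per_band = pd.DataFrame({
        "band": [band.label() for band in table.bands],
        "n": [len(m) for m in members],
        "n_candidates": [len(c) for c in cand],
        "dose_mg": list(doses),
    })
    return DesignReport(table=table, per_band=per_band, gmrs=gmrs,
                        cv_increase=cv_inc, expected_vial_mg=exp_mg, feasible=True)


# ---------------------------------------------------------------------------
# Full evaluation of a band table at one dose level
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelReport:
    """Composed equivalence + accounting + cost report for one dose level."""

    level: float
    equivalence: dict[str, EquivalenceResult]
    accounting_exact: pd.DataFrame
    accounting_whole_vial: pd.DataFrame
    quartiles_reference: "pd.DataFrame"
    quartiles_alternative: "pd.DataFrame"
    flatness_reference: float
    flatness_alternative: float
    population_median_auc_ss_reference: float
    population_iqr_auc_ss_reference: tuple[float, float]
    costs: pd.DataFrame
    metrics_reference: dict = field(repr=False, default=None)
    metrics_alternative: dict = field(repr=False, default=None)

    @property
    def all_endpoints_pass(self) -> bool:
        return all(r.passed for r in self.equivalence.values())


def evaluate_table(table: BandTable, level: float, cohort: Cohort,
                   params: PopPKParameters, formulary: VialFormulary,
                   cost_model=None, seed: int = 0,
                   cv_convention: str = "arithmetic",
                   accounting_mode: str = "whole_vial_reference",
                   require_vial_feasible: bool = True) -> LevelReport:
    """Simulate both regimens on a shared cohort and compose the full report.

    Pure function of its inputs and seed: cohort generation is upstream, the
    only randomness here is the shared individual-parameter draw.
    """
    from .costs_report import CostModel, cost_table   # local import avoids a cycle

    if table.level != level:
        raise ValueError("band table level does not match requested level")
    if require_vial_feasible:
        table.validate_vial_feasibility(formulary)
    empty = [b.label() for b in table.bands
             if not any(b.contains(s.body_weight) for s in cohort)]
    if empty:
        raise InfeasibleDesignError(f"cohort leaves band(s) empty: {empty}")
    if cost_model is None:
        cost_model = CostModel(formulary=formulary)

    reference = monotherapy_schedule(level, rule="per_kg_capped")
    alternative = monotherapy_schedule(level, rule="band_table")
    individuals = draw_cohort_individuals(cohort, params, seed)
    ref_metrics = simulate_exposures(cohort, individuals, reference,
                                     infusion_duration=params.infusion_duration)
    alt_metrics = simulate_exposures(cohort, individuals, alternative, table,
                                     infusion_duration=params.infusion_duration)
    equivalence = gmr_paired(ref_metrics, alt_metrics, cv_convention=cv_convention)

    _, acc_exact = drug_accounting(cohort, reference, alternative, table,
                                   formulary, mode="exact_mg_reference")
    _, acc_vial = drug_accounting(cohort, reference, alternative, table,
                                  formulary, mode="whole_vial_reference")

    quartiles = weight_quartiles(cohort)
    ref_summary = distribution_summary(ref_metrics, quartiles, "auc_ss")
    alt_summary = distribution_summary(alt_metrics, quartiles, "auc_ss")

    acc_for_costs = acc_vial if accounting_mode == "whole_vial_reference" else acc_exact
    pop = acc_for_costs[acc_for_costs["band"] == "population"].iloc[0]
    costs = cost_table(level, pop["reference_mg"], pop["alternative_mg"],
                       cost_model)
    return LevelReport(
        level=level,
        equivalence=equivalence,
        accounting_exact=acc_exact,
        accounting_whole_vial=acc_vial,
        quartiles_reference=ref_summary.per_quartile,
        quartiles_alternative=alt_summary.per_quartile,
        flatness_reference=ref_summary.flatness,
        flatness_alternative=alt_summary.flatness,
        population_median_auc_ss_reference=ref_summary.population_median,
        population_iqr_auc_ss_reference=ref_summary.population_iqr,
        costs=costs,
        metrics_reference=ref_metrics,
        metrics_alternative=alt_metrics,
    )
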