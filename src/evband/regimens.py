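"""Dosing rules, schedules, vial decomposition and per-patient drug accounting.

Approved dosing is linear mg/kg with the weight capped at 100 kg (so the
1.25 mg/kg starting dose tops out at 125 mg).  The alternative regimen assigns
one fixed whole-vial dose per body-weight band.  Band intervals are half-open
``[lower, upper)``: a 45.0 kg patient falls in the 45-55 band and a 95.0 kg
patient in the 75-95 band.

Whole-vial accounting assumes complete spillage of any partially used vial:
the drug consumed per administration is the smallest achievable sum of whole
vials covering the prescribed dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Subject
from .pkmodel import DoseEvent

__all__ = [
    "DOSE_LEVELS",
    "DEFAULT_WEIGHT_CAP_KG",
    "Regimen",
    "WeightBand",
    "BandTable",
    "VialFormulary",
    "DrugAccounting",
    "approved_dose",
    "band_dose",
    "build_dose_events",
    "vial_decomposition",
    "drug_accounting",
    "load_band_table",
    "read_band_tables_csv",
    "write_band_tables_csv",
    "MONOTHERAPY",
    "COMBINATION",
]

DOSE_LEVELS = (1.25, 1.0, 0.75, 0.5)
DEFAULT_WEIGHT_CAP_KG = 100.0

AccountingMode = Literal["exact_mg_reference", "whole_vial_reference"]


class BandTableError(ValueError):
    """Raised for malformed weight-band tables."""


@dataclass(frozen=True)
class Regimen:
    """A dosing rule plus administration schedule.

    ``rule`` is ``"per_kg_capped"`` (approved: level x min(weight, cap)) or
    ``"band_table"`` (fixed dose per weight band).  ``schedule_days`` are day
    numbers within the cycle (1-based, as on the label).
    """

    label: str
    rule: Literal["per_kg_capped", "band_table"]
    level: float
    schedule_days: tuple[int, ...]
    cycle_length_days: int
    weight_cap_kg: float = DEFAULT_WEIGHT_CAP_KG

    def __post_init__(self) -> None:
        days = self.schedule_days
        if list(days) != sorted(set(days)):
            raise ValueError("schedule_days must be strictly increasing")
        if days[0] < 1 or days[-1] > self.cycle_length_days:
            raise ValueError("schedule_days must lie within the cycle")

    @property
    def schedule_hours(self) -> tuple[float, ...]:
        return tuple((d - 1) * 24.0 for d in self.schedule_days)

    @property
    def cycle_length_hours(self) -> float:
        return self.cycle_length_days * 24.0

    @property
    def administrations_per_cycle(self) -> int:
        return len(self.schedule_days)


def monotherapy_schedule(level: float, rule: str = "per_kg_capped") -> Regimen:
    """Days 1, 8 and 15 of a 28-day cycle."""
    return Regimen(label=f"mono-{level}", rule=rule, level=level,
                   schedule_days=(1, 8, 15), cycle_length_days=28)


def combination_schedule(level: float, rule: str = "per_kg_capped") -> Regimen:
    """Days 1 and 8 of a 21-day cycle (with pembrolizumab)."""
    return Regimen(label=f"combo-{level}", rule=rule, level=level,
                   schedule_days=(1, 8), cycle_length_days=21)


MONOTHERAPY = monotherapy_schedule
COMBINATION = combination_schedule


@dataclass(frozen=True)
class WeightBand:
    lower_kg: float            # inclusive
    upper_kg: float            # exclusive (math.inf for the open top band)
    dose_mg: float

    def contains(self, weight: float) -> bool:
        return self.lower_kg <= weight < self.upper_kg

    def label(self) -> str:
        if self.lower_kg == 0:
            return f"< {self.upper_kg:g} kg"
        if math.isinf(self.upper_kg):
            return f"> {self.lower_kg:g} kg"
        return f"{self.lower_kg:g}-{self.upper_kg:g} kg"


@dataclass(frozen=True)
class BandTable:
    """Contiguous, non-overlapping weight bands covering (0, inf)."""

    level: float
    bands: tuple[WeightBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise BandTableError("band table has no bands")
        if self.bands[0].lower_kg != 0.0:
            raise BandTableError("first band must start at 0 kg")
        if not math.isinf(self.bands[-1].upper_kg):
            raise BandTableError("last band must be open-ended")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.upper_kg != b.lower_kg:
                raise BandTableError(
                    f"bands not contiguous at {a.upper_kg} / {b.lower_kg} kg")
            if b.dose_mg < a.dose_mg:
                raise BandTableError("band doses must be non-decreasing with weight")
        for band in self.bands:
            if not band.upper_kg > band.lower_kg:
                raise BandTableError("band bounds must be ordered")
            if band.dose_mg < 0:
                raise BandTableError("band doses must be non-negative")

    def validate_vial_feasibility(self, formulary: "VialFormulary") -> None:
        for band in self.bands:
            counts = vial_decomposition(band.dose_mg, formulary)
            total = sum(size * n for size, n in counts.items())
            if total != band.dose_mg:
                raise BandTableError(
                    f"band dose {band.dose_mg} mg is not an exact vial sum")

    def band_for(self, weight: float) -> WeightBand:
        for band in self.bands:
            if band.contains(weight):
                return band
        raise BandTableError(f"no band contains weight {weight} kg")


@dataclass(frozen=True)
class VialFormulary:
    """Available single-use vial sizes (mg) with per-vial prices (EUR)."""

    vials: tuple[tuple[float, float], ...]   # (size_mg, price)

    def __post_init__(self) -> None:
        sizes = [s for s, _ in self.vials]
        if not sizes:
            raise ValueError("formulary must contain at least one vial size")
        if len(set(sizes)) != len(sizes):
            raise ValueError("vial sizes must be distinct")
        if any(s <= 0 for s in sizes) or any(p <= 0 for _, p in self.vials):
            raise ValueError("vial sizes and prices must be positive")

    @property
    def sizes(self) -> tuple[float, ...]:
        return tuple(sorted(s for s, _ in self.vials))

    @property
    def prices(self) -> dict[float, float]:
        return dict(self.vials)

    def cost_of(self, counts: dict[float, int]) -> float:
        prices = self.prices
        return sum(prices[size] * n for size, n in counts.items())


def approved_dose(level: float, weight: float,
                  weight_cap_kg: float = DEFAULT_WEIGHT_CAP_KG) -> float:
    """Label dose: level (mg/kg) x body weight, weight capped at 100 kg."""
    if level <= 0 or weight <= 0:
        raise ValueError("level and weight must be positive")
    return level * min(weight, weight_cap_kg)


def band_dose(table: BandTable, weight: float) -> float:
    """Fixed dose of the band containing ``weight`` ([lower, upper) convention)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return table.band_for(weight).dose_mg


def regimen_dose(regimen: Regimen, subject: Subject,
                 band_table: BandTable | None = None) -> float:
    if regimen.rule == "per_kg_capped":
        return approved_dose(regimen.level, subject.body_weight, regimen.weight_cap_kg)
    if band_table is None:
        raise ValueError("band_table required for a band_table regimen")
    if band_table.level != regimen.level:
        raise ValueError("band table level does not match regimen level")
    return band_dose(band_table, subject.body_weight)


def build_dose_events(regimen: Regimen, subject: Subject,
                      band_table: BandTable | None = None,
                      n_cycles: int = 1,
                      infusion_duration: float = 0.5) -> list[DoseEvent]:
    """Concrete timed infusions for ``n_cycles`` cycles of a regimen."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    dose = regimen_dose(regimen, subject, band_table)
    events = []
    for cycle in range(n_cycles):
        offset = cycle * regimen.cycle_length_hours
        events.extend(
            DoseEvent(start_time=offset + h, amount=dose, duration=infusion_duration)
            for h in regimen.schedule_hours)
    return events


def vial_decomposition(dose: float, formulary: VialFormulary) -> dict[float, int]:
    """Optimal whole-vial cover of a dose.

    Among all vial multisets whose total is >= dose, pick the one with minimal
    total mg; break ties by fewest vials, then by the most large vials
    (lexicographic preference for bigger sizes).  Dose 0 returns no vials.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return {}
    sizes = sorted(formulary.sizes, reverse=True)
    # upper bound: covering everything with the smallest vial
    max_counts = [max(1, int(math.ceil(dose / s))) for s in sizes]
    best: tuple | None = None
    for counts in product(*(range(m + 1) for m in max_counts)):
        total = sum(c * s for c, s in zip(counts, sizes))
        if total < dose:
            continue
        # larger counts earlier in `counts` (big sizes) preferred on the tie
        key = (total, sum(counts), tuple(-c for c in counts))
        if best is None or key < best[0]:
            best = (key, counts)
    assert best is not None
    return {s: c for s, c in zip(sizes, best[1]) if c > 0}


@dataclass(frozen=True)
class DrugAccounting:
    """Per-administration drug use for one subject under paired regimens."""

    subject_id: str
    band_label: str
    prescribed_reference_mg: float
    prescribed_alternative_mg: float
    reference_mg: float           # consumed per administration (mode-dependent)
    alternative_mg: float         # consumed per administration (whole vials)
    reference_vials: dict[float, int] = field(default_factory=dict)
    alternative_vials: dict[float, int] = field(default_factory=dict)

    @property
    def saved_mg(self) -> float:
        return self.reference_mg - self.alternative_mg


def drug_accounting(cohort: Cohort, reference: Regimen, alternative: Regimen,
                    band_table: BandTable, formulary: VialFormulary,
                    mode: AccountingMode = "exact_mg_reference",
                    ) -> tuple[list[DrugAccounting], pd.DataFrame]:
    """Per-subject and per-band drug accounting for one dose level.

    The alternative regimen always consumes whole vials.  In
    ``exact_mg_reference`` mode the reference consumes exactly the prescribed
    mg (the convention behind the published population quantity ratios); in
    ``whole_vial_reference`` mode it also consumes whole vials (the worst-case
    spillage convention behind the per-band saved quantities).

    Returns the per-subject records and a per-band summary DataFrame with a
    trailing "population" row; per-band averages aggregate exactly to the
    population average, weighted by band occupancy.
    """
    if reference.level != alternative.level or band_table.level != reference.level:
        raise ValueError("reference, alternative and band table must share one level")
    if mode not in ("exact_mg_reference", "whole_vial_reference"):
        raise ValueError(f"unknown accounting mode {mode!r}")
    records = []
    for subj in cohort:
        ref_rx = regimen_dose(reference, subj, band_table)
        alt_rx = regimen_dose(alternative, subj, band_table)
        ref_vials = vial_decomposition(ref_rx, formulary)
        alt_vials = vial_decomposition(alt_rx, formulary)
        ref_vial_mg = sum(s * n for s, n in ref_vials.items())
        alt_mg = sum(s * n for s, n in alt_vials.items())
        ref_mg = ref_rx if mode == "exact_mg_reference" else ref_vial_mg
        records.append(DrugAccounting(
            subject_id=subj.id,
            band_label=band_table.band_for(subj.body_weight).label(),
            prescribed_reference_mg=ref_rx,
            prescribed_alternative_mg=alt_rx,
            reference_mg=ref_mg,
            alternative_mg=alt_mg,
            reference_vials=ref_vials,
            alternative_vials=alt_vials,
        ))
    df = pd.DataFrame({
        "band": [r.band_label for r in records],
        "reference_mg": [r.reference_mg for r in records],
        "alternative_mg": [r.alternative_mg for r in records],
        "saved_mg": [r.saved_mg for r in records],
    })
    order = [b.label() for b in band_table.bands]
    grouped = (df.groupby("band", sort=False)
                 .agg(n=("saved_mg", "size"),
                      reference_mg=("reference_mg", "mean"),
                      alternative_mg=("alternative_mg", "mean"),
                      saved_mg=("saved_mg", "mean"))
                 .reindex([b for b in order if b in set(df["band"])])
                 .reset_index())
    pop = pd.DataFrame([{
        "band": "population", "n": len(df),
        "reference_mg": df["reference_mg"].mean(),
        "alternative_mg": df["alternative_mg"].mean(),
        "saved_mg": df["saved_mg"].mean(),
    }])
    summary = pd.concat([grouped, pop], ignore_index=True)
    return records, summary


def simulate_exposures(cohort: Cohort, individuals, regimen: Regimen,
                       band_table: BandTable | None = None,
                       infusion_duration: float = 0.5):
    """Per-subject :class:`~evband.pkmodel.ExposureMetrics` under one regimen.

    ``individuals`` is a sequence of IndividualPK aligned with ``cohort``
    (same subjects, typically one shared draw across paired regimens).
    Returns a dict keyed by subject id.
    """
    from .pkmodel import exposure_metrics
    out = {}
    for subj, indiv in zip(cohort, individuals, strict=True):
        if indiv.subject_id != subj.id:
            raise ValueError("individuals not aligned with cohort")
        dose = regimen_dose(regimen, subj, band_table)
        out[subj.id] = exposure_metrics(
            indiv, regimen.schedule_hours, dose, regimen.cycle_length_hours,
            infusion_duration=infusion_duration)
    return out


# ---------------------------------------------------------------------------
# Band-table CSV I/O (schema: level, lower_kg, upper_kg, dose_mg)
# ---------------------------------------------------------------------------

def _table_from_rows(level: float, rows: pd.DataFrame) -> BandTable:
    bands = []
    for r in rows.sort_values("lower_kg").itertuples(index=False):
        upper = math.inf if pd.isna(r.upper_kg) or r.upper_kg in ("inf", "") else float(r.upper_kg)
        bands.append(WeightBand(float(r.lower_kg), upper, float(r.dose_mg)))
    return BandTable(level=level, bands=tuple(bands))


def read_band_tables_csv(path_or_buffer) -> dict[float, BandTable]:
    """Read band tables (columns level, lower_kg, upper_kg, dose_mg)."""
    df = pd.read_csv(path_or_buffer, encoding="utf-8")
    required = {"level", "lower_kg", "upper_kg", "dose_mg"}
    if not required <= set(df.columns):
        raise BandTableError(f"band table CSV must have columns {sorted(required)}")
    return {float(level): _table_from_rows(float(level), rows)
            for level, rows in df.groupby("level")}


def write_band_tables_csv(tables: Sequence[BandTable], path) -> None:
    rows = []
    for table in tables:
        for band in table.bands:
            rows.append({
                "level": table.level,
                "lower_kg": band.lower_kg,
                "upper_kg": "" if math.isinf(band.upper_kg) else band.upper_kg,
                "dose_mg": band.dose_mg,
            })
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def load_band_table(level: float) -> BandTable:
    """The packaged published weight-band table for one dose level."""
    ref = resources.files("evband.data").joinpath("band_tables.csv")
    with ref.open("r", encoding="utf-8") as fh:
        tables = read_band_tables_csv(fh)
    if level not in tables:
        raise BandTableError(f"no packaged band table for level {level}")
    return tables[level]
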