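"""Drug-cost projection and the reporting pipeline.

Converts average per-administration drug quantities into per-treatment costs
and savings.  Treatment durations follow the reported medians: monotherapy
5 cycles of 3 administrations (15), combination with pembrolizumab 12 cycles
of 2 administrations (24).  Reference-regimen cost is computed from the
average *prescribed* mg (the convention that reproduces the published cost
table); the whole-vial reference ("worst case" complete-spillage) variant is
reported alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import RunConfig, get_logger
from .cohort import generate_cohort
from .regimens import VialFormulary, load_band_table, write_band_tables_csv

__all__ = [
    "CostModel",
    "CostSummary",
    "per_mg_price",
    "treatment_cost",
    "savings",
    "cost_table",
    "run_pipeline",
]

log = get_logger("evband.costs")


@dataclass(frozen=True)
class CostModel:
    """Price and treatment-duration assumptions for cost projection."""

    formulary: VialFormulary
    administrations_monotherapy: int = 15     # 5 cycles x days 1/8/15
    administrations_combination: int = 24     # 12 cycles x days 1/8
    currency: str = "EUR"

    def __post_init__(self) -> None:
        if self.administrations_monotherapy < 1 or self.administrations_combination < 1:
            raise ValueError("administration counts must be >= 1")

    def administrations(self, setting: str) -> int:
        if setting == "monotherapy":
            return self.administrations_monotherapy
        if setting == "combination":
            return self.administrations_combination
        raise ValueError(f"unknown treatment setting {setting!r}")


@dataclass(frozen=True)
class CostSummary:
    level: float
    setting: str
    cost_reference: float
    cost_alternative: float

    @property
    def savings_fraction(self) -> float:
        return savings(self.cost_reference, self.cost_alternative)


def per_mg_price(formulary: VialFormulary) -> float | dict[float, float]:
    """Price per mg: a single float if uniform across vial sizes, else a map.

    With the Dutch list prices (EUR 698 / 20 mg and EUR 1,047 / 30 mg) the
    price per mg is uniform at EUR 34.90, so mg-based and vial-based cost
    accounting coincide.
    """
    per_mg = {size: price / size for size, price in formulary.vials}
    values = list(per_mg.values())
    if all(abs(v - values[0]) < 1e-9 * values[0] for v in values):
        return values[0]
    return per_mg


def treatment_cost(average_mg_per_administration: float, cost_model: CostModel,
                   setting: str = "monotherapy") -> float:
    """Average per-patient treatment cost: avg mg x administrations x EUR/mg.

    Requires a uniform per-mg price; with size-dependent prices cost must be
    accounted per whole vial instead.  Full precision — round only at
    presentation.
    """
    if average_mg_per_administration < 0:
        raise ValueError("average quantity must be >= 0")
    price = per_mg_price(cost_model.formulary)
    if isinstance(price, dict):
        raise ValueError("non-uniform per-mg price: use whole-vial costing")
    return average_mg_per_administration * cost_model.administrations(setting) * price


def savings(cost_reference: float, cost_alternative: float) -> float:
    """Percentage saved: 100 x (1 - alternative / reference)."""
    if cost_reference <= 0:
        raise ValueError("reference cost must be positive")
    return 100.0 * (1.0 - cost_alternative / cost_reference)


def cost_table(level: float, reference_mg: float, alternative_mg: float,
               cost_model: CostModel) -> pd.DataFrame:
    """Per-setting cost summary for one dose level (one row per setting)."""
    rows = []
    for setting in ("monotherapy", "combination"):
        ref = treatment_cost(reference_mg, cost_model, setting)
        alt = treatment_cost(alternative_mg, cost_model, setting)
        rows.append({
            "level": level,
            "setting": setting,
            "cost_reference": ref,
            "cost_alternative": alt,
            "savings_pct": savings(ref, alt),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Cohort -> PK -> regimens -> equivalence -> costs for every dose level.

    Returns a report bundle ``{"cohort": ..., "levels": {level: LevelReport},
    "summary": dict}``; if ``outdir`` is given, also writes the CSV tables,
    a plain-text run log and a machine-readable summary JSON there.
    Deterministic: identical config (including seed) gives identical outputs.
    """
    from .band_designer import evaluate_table

    cohort = generate_cohort(config.demographics)
    cost_model = CostModel(
        formulary=config.formulary,
        administrations_monotherapy=config.cost.administrations_monotherapy,
        administrations_combination=config.cost.administrations_combination,
        currency=config.cost.currency,
    )
    reports = {}
    for level in config.levels:
        table = load_band_table(level)
        # eta draws are shared across regimens within a level (paired design)
        reports[level] = evaluate_table(
            table, level, cohort, config.pk, config.formulary,
            cost_model=cost_model, seed=config.seed + 1,
            cv_convention=config.cv_convention,
            accounting_mode=config.accounting_mode)

    provenance = ("supplementary-transcribed" if config.pk.authoritative
                  else "non-authoritative parameters (calibrated placeholder)")
    summary = {
        "schema_version": config.schema_version,
        "seed": config.seed,
        "n_subjects": len(cohort),
        "parameter_provenance": provenance,
        "levels": {},
    }
    for level, rep in reports.items():
        mono = rep.costs[rep.costs["setting"] == "monotherapy"].iloc[0]
        acc = (rep.accounting_whole_vial
               if config.accounting_mode == "whole_vial_reference"
               else rep.accounting_exact)
        pop = acc[acc["band"] == "population"].iloc[0]
        summary["levels"][str(level)] = {
            "gmr": rep.equivalence["auc_ss"].gmr,
            "all_endpoints_pass": rep.all_endpoints_pass,
            "reference_mg": pop["reference_mg"],
            "alternative_mg": pop["alternative_mg"],
            "quantity_ratio": pop["alternative_mg"] / pop["reference_mg"],
            "cost_reference_mono": mono["cost_reference"],
            "cost_alternative_mono": mono["cost_alternative"],
            "savings_pct": mono["savings_pct"],
            "flatness_reference": rep.flatness_reference,
            "flatness_alternative": rep.flatness_alternative,
        }
    savings_all = [v["savings_pct"] for v in summary["levels"].values()]
    summary["average_savings_pct"] = sum(savings_all) / len(savings_all)

    bundle = {"cohort": cohort, "levels": reports, "summary": summary}
    if outdir is not None:
        _write_outputs(bundle, config, Path(outdir), provenance)
    return bundle


def _equivalence_frame(reports: dict) -> pd.DataFrame:
    rows = []
    for level, rep in reports.items():
        for ep, res in rep.equivalence.items():
            rows.append({
                "level": level, "endpoint": ep,
                "gm_reference": res.gm_reference,
                "gm_alternative": res.gm_alternative,
                "cv_reference_pct": res.cv_reference,
                "cv_alternative_pct": res.cv_alternative,
                "gmr": res.gmr,
                "lower_bound": res.lower_bound, "upper_bound": res.upper_bound,
                "pass": res.passed,
            })
    return pd.DataFrame(rows)


def _write_outputs(bundle: dict, config: RunConfig, outdir: Path,
                   provenance: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    reports = bundle["levels"]
    write_band_tables_csv([load_band_table(level) for level in reports],
                          outdir / "band_tables.csv")
    _equivalence_frame(reports).to_csv(outdir / "equivalence.csv", index=False,
                                       encoding="utf-8")
    acc = []
    for level, rep in reports.items():
        for mode, frame in (("exact_mg_reference", rep.accounting_exact),
                            ("whole_vial_reference", rep.accounting_whole_vial)):
            f = frame.copy()
            f.insert(0, "mode", mode)
            f.insert(0, "level", level)
            acc.append(f)
    pd.concat(acc, ignore_index=True).to_csv(outdir / "accounting.csv",
                                             index=False, encoding="utf-8")
    pd.concat([r.costs for r in reports.values()], ignore_index=True).to_csv(
        outdir / "costs.csv", index=False, encoding="utf-8")
    quart = []
    for level, rep in reports.items():
        for regimen, frame in (("reference", rep.quartiles_reference),
                               ("alternative", rep.quartiles_alternative)):
            f = frame.copy()
            f.insert(0, "regimen", regimen)
            f.insert(0, "level", level)
            quart.append(f)
    pd.concat(quart, ignore_index=True).to_csv(outdir / "quartile_summary.csv",
                                               index=False, encoding="utf-8")
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["summary"], fh, indent=2)
    log_lines = [
        f"seed: {config.seed}",
        f"n_subjects: {config.n_subjects}",
        f"levels: {list(config.levels)}",
        f"accounting_mode: {config.accounting_mode}",
        f"cv_convention: {config.cv_convention}",
        f"parameter_provenance: {provenance}",
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    log.info("pipeline outputs written to %s (%s)", outdir, provenance)
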