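"""Two-compartment population-PK engine for the intact antibody-drug conjugate.

Linear, time-invariant two-compartment disposition with zero-order IV infusion
input, solved in closed form (bi-exponential macro constants).  Population
variability enters as log-normal inter-individual random effects on clearance
and volumes, and body weight scales clearances and volumes allometrically:

    CL_i = CL_typ * (W_i / W_ref)**theta_cl * exp(eta_CL,i)

with theta_cl < 1, so systemic exposure under mg/kg dosing rises
less-than-proportionally with body weight.

Exposure endpoints per subject and regimen are the cycle AUC and the
end-of-cycle trough concentration, for the first cycle and at steady state.
Steady state is evaluated analytically by summing the per-exponential
geometric series over infinitely many past cycles; an iterative multi-cycle
superposition is provided as a validation fallback.  Residual (within-subject)
error is deliberately excluded: endpoints are model-predicted concentrations,
as is standard for simulation-based equivalence assessment.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import Subject

__all__ = [
    "PopPKParameters",
    "IndividualPK",
    "DoseEvent",
    "ExposureMetrics",
    "parse_nonmem_control",
    "serialize_control_stream",
    "draw_individual",
    "concentration",
    "auc_to",
    "exposure_metrics",
    "exposure_metrics_iterative",
]

IIV_PARAMETERS = ("cl", "v1", "q", "v2")


class ControlStreamError(ValueError):
    """Raised when a NONMEM control stream cannot be parsed."""


class ConvergenceError(RuntimeError):
    """Raised when iterative steady-state evaluation fails to converge."""


@dataclass(frozen=True)
class PopPKParameters:
    """Typical values, allometric exponents and IIV variances.

    Units: clearances L/h, volumes L, weight kg, infusion duration h.
    ``iiv_variances`` holds log-scale variances (omega^2) keyed by
    ``"cl"``, ``"v1"``, ``"q"``, ``"v2"`` (missing keys mean no IIV).
    ``authoritative`` is False for calibrated placeholder values that do not
    come from a transcribed registrational control stream.
    """

    cl_typ: float
    v1_typ: float
    q_typ: float
    v2_typ: float
    reference_weight: float = 70.0
    weight_exponent_clearances: float = 0.75
    weight_exponent_volumes: float = 1.0
    iiv_variances: Mapping[str, float] = field(default_factory=dict)
    infusion_duration: float = 0.5
    authoritative: bool = False

    def __post_init__(self) -> None:
        for name in ("cl_typ", "v1_typ", "q_typ", "v2_typ", "reference_weight",
                     "infusion_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("weight_exponent_clearances", "weight_exponent_volumes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.5:
                raise ValueError(f"{name} must lie in [0, 1.5]")
        for key, om2 in self.iiv_variances.items():
            if key not in IIV_PARAMETERS:
                raise ValueError(f"unknown IIV key {key!r}")
            if om2 < 0:
                raise ValueError("omega^2 must be non-negative")


@dataclass(frozen=True)
class IndividualPK:
    """Realized PK parameters of one subject (all positive, L and L/h)."""

    subject_id: str
    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        for name in ("cl", "v1", "q", "v2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def micro_constants(self) -> tuple[float, float, float]:
        """(k10, k12, k21) in 1/h."""
        return self.cl / self.v1, self.q / self.v1, self.q / self.v2

    def hybrid_constants(self) -> tuple[float, float, float, float]:
        """Macro constants (alpha, beta, A, B) of the unit-bolus solution.

        c(t) = A exp(-alpha t) + B exp(-beta t) per mg of bolus dose.
        """
        k10, k12, k21 = self.micro_constants
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
        alpha = 0.5 * (s + disc)
        beta = 0.5 * (s - disc)
        if alpha == beta:
            raise ValueError("degenerate two-compartment roots (alpha == beta)")
        a_coef = (alpha - k21) / ((alpha - beta) * self.v1)
        b_coef = (k21 - beta) / ((alpha - beta) * self.v1)
        return alpha, beta, a_coef, b_coef


@dataclass(frozen=True)
class DoseEvent:
    """One IV infusion: start time (h), amount (mg), duration (h)."""

    start_time: float
    amount: float
    duration: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("dose amount must be >= 0")
        if not self.duration > 0:
            raise ValueError("infusion duration must be positive")
        if self.start_time < 0:
            raise ValueError("dose start time must be non-negative")


@dataclass(frozen=True)
class ExposureMetrics:
    """Cycle AUC (mg*h/L) and end-of-cycle trough (mg/L), cycle 1 and steady state."""

    auc_cycle1: float
    ctrough_cycle1: float
    auc_ss: float
    ctrough_ss: float

    def as_dict(self) -> dict[str, float]:
        return {
            "auc_cycle1": self.auc_cycle1,
            "ctrough_cycle1": self.ctrough_cycle1,
            "auc_ss": self.auc_ss,
            "ctrough_ss": self.ctrough_ss,
        }


ENDPOINTS = ("auc_cycle1", "ctrough_cycle1", "auc_ss", "ctrough_ss")


# ---------------------------------------------------------------------------
# NONMEM control-stream reader (best-effort documented subset)
# ---------------------------------------------------------------------------

_THETA_TOKEN = re.compile(
    r"\(\s*([-\d.eE+]+)\s*,\s*([-\d.eE+]+)\s*(?:,\s*([-\d.eE+]+)\s*)?\)(?:\s*FIX(?:ED)?)?"
    r"|([-\d.eE+]+)(?:\s*FIX(?:ED)?)?")


def _strip_comments(text: str) -> list[str]:
    lines = []
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].rstrip()
        if line.strip():
            lines.append(line)
    return lines


def _collect_block(lines: Sequence[str], name: str) -> list[str]:
    """Return the concatenated records of every $<name> block."""
    out: list[str] = []
    inside = False
    for line in lines:
        stripped = line.strip()
        if stripped.startswith("$"):
            head = stripped.split(None, 1)
            tag = head[0][1:].upper()
            inside = tag.startswith(name)
            if inside and len(head) > 1:
                out.append(head[1])
            continue
        if inside:
            out.append(stripped)
    return out


def _parse_theta_records(records: Sequence[str]) -> list[float]:
    thetas: list[float] = []
    for rec in records:
        pos = 0
        while pos < len(rec):
            m = _THETA_TOKEN.search(rec, pos)
            if m is None:
                leftover = rec[pos:].strip()
                if leftover:
                    raise ControlStreamError(f"unparseable $THETA record: {rec!r}")
                break
            if m.group(4) is not None:           # bare initial value
                thetas.append(float(m.group(4)))
            elif m.group(3) is not None:         # (low, init, up)
                thetas.append(float(m.group(2)))
            else:                                # (low, init)
                thetas.append(float(m.group(2)))
            pos = m.end()
    return thetas


def _parse_omega_records(records: Sequence[str]) -> list[float]:
    omegas: list[float] = []
    for rec in records:
        cleaned = re.sub(r"\bFIX(?:ED)?\b", " ", rec, flags=re.I)
        if re.search(r"\bBLOCK\b|\bSAME\b", cleaned, flags=re.I):
            raise ControlStreamError(
                "only diagonal $OMEGA records are supported "
                f"(offending record: {rec!r})")
        for tok in cleaned.replace("(", " ").replace(")", " ").split():
            try:
                omegas.append(float(tok))
            except ValueError as exc:
                raise ControlStreamError(
                    f"unparseable $OMEGA token {tok!r} in record {rec!r}") from exc
    return omegas


_FIELD_NAMES = {
    "cl_typ", "v1_typ", "q_typ", "v2_typ", "reference_weight",
    "weight_exponent_clearances", "weight_exponent_volumes",
}


def parse_nonmem_control(
    text: str,
    theta_map: Mapping[int, str],
    omega_order: Sequence[str] = IIV_PARAMETERS,
    infusion_duration: float = 0.5,
) -> PopPKParameters:
    """Transcribe a NONMEM control stream into :class:`PopPKParameters`.

    Parameters
    ----------
    text : str
        Control-stream text with ``$THETA`` and ``$OMEGA`` blocks (diagonal
        omegas; ``(low, init)``, ``(low, init, up)``, bare values and FIX
        annotations are understood; ``;`` comments stripped).
    theta_map : mapping of 1-based THETA index -> field name
        Field names: cl_typ, v1_typ, q_typ, v2_typ, reference_weight,
        weight_exponent_clearances, weight_exponent_volumes.
    omega_order : sequence of IIV keys
        Which parameter each diagonal omega^2 belongs to, in declaration order.
    """
    lines = _strip_comments(text)
    theta_recs = _collect_block(lines, "THETA")
    omega_recs = _collect_block(lines, "OMEGA")
    if not theta_recs:
        raise ControlStreamError("no $THETA block found")
    thetas = _parse_theta_records(theta_recs)
    omegas = _parse_omega_records(omega_recs) if omega_recs else []

    fields: dict[str, float] = {}
    for index, name in theta_map.items():
        if name not in _FIELD_NAMES:
            raise ControlStreamError(f"unknown parameter field {name!r}")
        if not 1 <= index <= len(thetas):
            raise ControlStreamError(
                f"theta index {index} out of range (stream has {len(thetas)})")
        fields[name] = thetas[index - 1]
    if len(omegas) < len(omega_order):
        omega_order = omega_order[: len(omegas)]
    iiv = {key: omegas[i] for i, key in enumerate(omega_order)}
    parsed = PopPKParameters(
        cl_typ=fields["cl_typ"],
        v1_typ=fields["v1_typ"],
        q_typ=fields["q_typ"],
        v2_typ=fields["v2_typ"],
        reference_weight=fields.get("reference_weight", 70.0),
        weight_exponent_clearances=fields.get("weight_exponent_clearances", 0.75),
        weight_exponent_volumes=fields.get("weight_exponent_volumes", 1.0),
        iiv_variances=iiv,
        infusion_duration=infusion_duration,
        authoritative=True,
    )
    return parsed


def serialize_control_stream(params: PopPKParameters) -> tuple[str, dict[int, str], list[str]]:
    """Emit a control-stream fragment round-trippable by :func:`parse_nonmem_control`.

    Returns (text, theta_map, omega_order).
    """
    order = ["cl_typ", "v1_typ", "q_typ", "v2_typ", "reference_weight",
             "weight_exponent_clearances", "weight_exponent_volumes"]
    theta_lines = [f"(0, {getattr(params, name)!r})  ; {name}" for name in order]
    omega_keys = [k for k in IIV_PARAMETERS if k in params.iiv_variances]
    omega_lines = [f"{params.iiv_variances[k]!r}  ; IIV {k}" for k in omega_keys]
    text = "$THETA\n" + "\n".join(theta_lines) + "\n$OMEGA\n" + "\n".join(omega_lines) + "\n"
    theta_map = {i + 1: name for i, name in enumerate(order)}
    return text, theta_map, omega_keys


# ---------------------------------------------------------------------------
# Individual parameters
# ---------------------------------------------------------------------------

def draw_individual(subject: Subject, params: PopPKParameters,
                    rng: np.random.Generator) -> IndividualPK:
    """Realize one subject's PK parameters: allometry times exp(eta).

    Exactly four standard-normal draws are consumed per subject (one per
    parameter, in cl/v1/q/v2 order), so cohort-level streams stay aligned
    whichever omegas are zero.
    """
    z = rng.standard_normal(4)
    eta = {key: math.sqrt(params.iiv_variances.get(key, 0.0)) * z[i]
           for i, key in enumerate(IIV_PARAMETERS)}
    fw_cl = (subject.body_weight / params.reference_weight) ** params.weight_exponent_clearances
    fw_v = (subject.body_weight / params.reference_weight) ** params.weight_exponent_volumes
    return IndividualPK(
        subject_id=subject.id,
        cl=params.cl_typ * fw_cl * math.exp(eta["cl"]),
        v1=params.v1_typ * fw_v * math.exp(eta["v1"]),
        q=params.q_typ * fw_cl * math.exp(eta["q"]),
        v2=params.v2_typ * fw_v * math.exp(eta["v2"]),
    )


def draw_cohort_individuals(cohort: Sequence[Subject], params: PopPKParameters,
                            seed: int) -> list[IndividualPK]:
    """One independent eta stream per subject, spawned from ``seed``."""
    root = np.random.default_rng(seed)
    streams = root.spawn(len(cohort))
    return [draw_individual(s, params, streams[i]) for i, s in enumerate(cohort)]


# ---------------------------------------------------------------------------
# Closed-form concentrations and AUC
# ---------------------------------------------------------------------------

def _dose_concentration(t: np.ndarray, dose: DoseEvent,
                        lam: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Concentration contribution of one infusion at absolute times t."""
    te = t - dose.start_time
    rate = dose.amount / dose.duration
    out = np.zeros_like(te, dtype=float)
    during = (te > 0) & (te <= dose.duration)
    after = te > dose.duration
    for c, l in zip(coef, lam):
        if np.any(during):
            out[during] += rate * c / l * (1.0 - np.exp(-l * te[during]))
        if np.any(after):
            out[after] += (rate * c / l * (1.0 - np.exp(-l * dose.duration))
                           * np.exp(-l * (te[after] - dose.duration)))
    return out


def concentration(t, doses: Sequence[DoseEvent], indiv: IndividualPK):
    """Plasma concentration (mg/L) at time(s) ``t`` under superposition.

    Zero before the first dose start; continuous in t; linear in dose amounts.
    """
    alpha, beta, a_coef, b_coef = indiv.hybrid_constants()
    lam = np.array([alpha, beta])
    coef = np.array([a_coef, b_coef])
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    total = np.zeros_like(t_arr)
    for dose in doses:
        if dose.amount == 0:
            continue
        total += _dose_concentration(t_arr, dose, lam, coef)
    return float(total[0]) if np.isscalar(t) or np.ndim(t) == 0 else total


def _dose_auc_to(t: float, dose: DoseEvent, lam: np.ndarray, coef: np.ndarray) -> float:
    """AUC contribution of one infusion over [0, t] (absolute time)."""
    te = t - dose.start_time
    if te <= 0 or dose.amount == 0:
        return 0.0
    rate = dose.amount / dose.duration
    auc = 0.0
    for c, l in zip(coef, lam):
        t1 = min(te, dose.duration)
        # during-infusion integral of (1 - e^{-l s})
        auc += rate * c / l * (t1 - (1.0 - math.exp(-l * t1)) / l)
        if te > dose.duration:
            auc += (rate * c / l * (1.0 - math.exp(-l * dose.duration))
                    * (1.0 - math.exp(-l * (te - dose.duration))) / l)
    return auc


def auc_to(t: float, doses: Sequence[DoseEvent], indiv: IndividualPK) -> float:
    """Analytic AUC (mg*h/L) of the superposed profile over [0, t]."""
    alpha, beta, a_coef, b_coef = indiv.hybrid_constants()
    lam = np.array([alpha, beta])
    coef = np.array([a_coef, b_coef])
    return sum(_dose_auc_to(t, d, lam, coef) for d in doses)


# ---------------------------------------------------------------------------
# Exposure metrics: first cycle and steady state
# ---------------------------------------------------------------------------

def _cycle_doses(schedule_hours: Sequence[float], dose_mg: float,
                 duration: float) -> list[DoseEvent]:
    return [DoseEvent(start_time=t0, amount=dose_mg, duration=duration)
            for t0 in schedule_hours]


def exposure_metrics(indiv: IndividualPK, schedule_hours: Sequence[float],
                     dose_mg: float, cycle_length: float,
                     infusion_duration: float = 0.5) -> ExposureMetrics:
    """AUC and end-of-cycle trough for cycle 1 and at steady state.

    ``schedule_hours`` are infusion start times within one cycle (e.g.
    0, 168, 336 for days 1/8/15); ``cycle_length`` in hours.  Steady state is
    exact via the per-exponential geometric series over past cycles; the
    steady-state cycle AUC reduces to (sum of cycle doses)/CL.
    """
    if dose_mg < 0:
        raise ValueError("dose must be >= 0")
    if any(t0 < 0 or t0 + infusion_duration > cycle_length for t0 in schedule_hours):
        raise ValueError("schedule must fit within one cycle")
    if list(schedule_hours) != sorted(schedule_hours):
        raise ValueError("schedule times must be sorted")
    if dose_mg == 0:
        return ExposureMetrics(0.0, 0.0, 0.0, 0.0)

    doses = _cycle_doses(schedule_hours, dose_mg, infusion_duration)
    alpha, beta, a_coef, b_coef = indiv.hybrid_constants()
    lam = np.array([alpha, beta])
    coef = np.array([a_coef, b_coef])

    auc_c1 = auc_to(cycle_length, doses, indiv)
    ctr_c1 = float(concentration(cycle_length, doses, indiv))

    # steady state: each exponential term accumulates by 1/(1 - e^{-l*tau})
    tau = cycle_length
    ctr_ss = 0.0
    for d in doses:
        rate = d.amount / d.duration
        t_end = tau - d.start_time - d.duration   # time after end of infusion
        for c, l in zip(coef, lam):
            acc = 1.0 / (1.0 - math.exp(-l * tau))
            ctr_ss += (rate * c / l * (1.0 - math.exp(-l * d.duration))
                       * math.exp(-l * t_end) * acc)
    auc_ss = dose_mg * len(schedule_hours) / indiv.cl
    return ExposureMetrics(auc_cycle1=auc_c1, ctrough_cycle1=ctr_c1,
                           auc_ss=auc_ss, ctrough_ss=ctr_ss)


def exposure_metrics_iterative(indiv: IndividualPK, schedule_hours: Sequence[float],
                               dose_mg: float, cycle_length: float,
                               infusion_duration: float = 0.5,
                               rel_tol: float = 1e-4,
                               max_cycles: int = 200) -> ExposureMetrics:
    """Validation fallback: iterate cycles until successive cycle AUCs converge.

    Raises :class:`ConvergenceError` if the relative change in cycle AUC is
    still above ``rel_tol`` after ``max_cycles`` cycles.
    """
    if dose_mg == 0:
        return ExposureMetrics(0.0, 0.0, 0.0, 0.0)
    doses: list[DoseEvent] = []
    prev_auc = None
    result_c1 = None
    for cycle in range(max_cycles):
        offset = cycle * cycle_length
        doses.extend(DoseEvent(offset + t0, dose_mg, infusion_duration)
                     for t0 in schedule_hours)
        end = (cycle + 1) * cycle_length
        cyc_auc = auc_to(end, doses, indiv) - auc_to(offset, doses, indiv)
        cyc_trough = float(concentration(end, doses, indiv))
        if cycle == 0:
            result_c1 = (cyc_auc, cyc_trough)
        if prev_auc is not None and abs(cyc_auc - prev_auc) <= rel_tol * cyc_auc:
            return ExposureMetrics(auc_cycle1=result_c1[0], ctrough_cycle1=result_c1[1],
                                   auc_ss=cyc_auc, ctrough_ss=cyc_trough)
        prev_auc = cyc_auc
    raise ConvergenceError(
        f"steady state not reached within {max_cycles} cycles (rel_tol={rel_tol})")
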