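import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from evband.cohort import Subject
from evband.pkmodel import (
    ENDPOINTS,
    ControlStreamError,
    ConvergenceError,
    DoseEvent,
    IndividualPK,
    PopPKParameters,
    auc_to,
    concentration,
    draw_cohort_individuals,
    draw_individual,
    exposure_metrics,
    exposure_metrics_iterative,
    parse_nonmem_control,
    serialize_control_stream,
)

MONO_SCHEDULE = (0.0, 168.0, 336.0)
TAU = 672.0


def _typical_individual(default_pk, weight=70.0):
    subj = Subject(id="T", sex="male", age=60.0, body_weight=weight)
    params = PopPKParameters(
        cl_typ=default_pk.cl_typ, v1_typ=default_pk.v1_typ,
        q_typ=default_pk.q_typ, v2_typ=default_pk.v2_typ,
        reference_weight=default_pk.reference_weight,
        iiv_variances={},
    )
    return draw_individual(subj, params, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# Control-stream transcription
# ---------------------------------------------------------------------------

CONTROL_TEXT = """
$PROBLEM two-compartment ADC
$THETA
(0, 0.1)      ; TVCL (L/h)
(0, 2.7)      ; TVV1 (L)
(0, 0.0125)   ; TVQ (L/h)
(0, 3.74)     ; TVV2 (L)
70 FIX        ; reference weight
(0, 0.75, 1)  ; allometric exponent CL/Q
1 FIX         ; allometric exponent V1/V2
$OMEGA
0.09  ; IIV CL
0.04  ; IIV V1
0.02  ; IIV Q
0.03  ; IIV V2
"""

THETA_MAP = {1: "cl_typ", 2: "v1_typ", 3: "q_typ", 4: "v2_typ",
             5: "reference_weight", 6: "weight_exponent_clearances",
             7: "weight_exponent_volumes"}


def test_parse_control_stream():
    params = parse_nonmem_control(CONTROL_TEXT, THETA_MAP)
    assert params.cl_typ == pytest.approx(0.1)
    assert params.v1_typ == pytest.approx(2.7)
    assert params.q_typ == pytest.approx(0.0125)
    assert params.v2_typ == pytest.approx(3.74)
    assert params.reference_weight == pytest.approx(70.0)
    assert params.weight_exponent_clearances == pytest.approx(0.75)
    assert params.weight_exponent_volumes == pytest.approx(1.0)
    assert params.iiv_variances == pytest.approx(
        {"cl": 0.09, "v1": 0.04, "q": 0.02, "v2": 0.03})
    assert params.authoritative is True


def test_control_stream_round_trip(default_pk):
    text, theta_map, omega_order = serialize_control_stream(default_pk)
    parsed = parse_nonmem_control(text, theta_map, omega_order)
    assert parsed.cl_typ == pytest.approx(default_pk.cl_typ, rel=1e-12)
    assert parsed.v1_typ == pytest.approx(default_pk.v1_typ, rel=1e-12)
    assert parsed.q_typ == pytest.approx(default_pk.q_typ, rel=1e-12)
    assert parsed.v2_typ == pytest.approx(default_pk.v2_typ, rel=1e-12)
    assert parsed.iiv_variances == pytest.approx(default_pk.iiv_variances)


def test_parse_control_stream_errors():
    with pytest.raises(ControlStreamError):
        parse_nonmem_control("$OMEGA 0.1\n", {1: "cl_typ"})      # no $THETA
    with pytest.raises(ControlStreamError):
        parse_nonmem_control(CONTROL_TEXT, {99: "cl_typ"})       # index range
    with pytest.raises(ControlStreamError):
        parse_nonmem_control(CONTROL_TEXT, {1: "not_a_field"})   # unknown field


# ---------------------------------------------------------------------------
# Individual draws
# ---------------------------------------------------------------------------

def test_draw_individual_allometry_no_iiv(default_pk):
    ind70 = _typical_individual(default_pk, 70.0)
    assert ind70.cl == pytest.approx(default_pk.cl_typ, rel=1e-12)
    assert ind70.v1 == pytest.approx(default_pk.v1_typ, rel=1e-12)
    ind140 = _typical_individual(default_pk, 140.0)
    assert ind140.cl == pytest.approx(default_pk.cl_typ * 2 ** 0.75, rel=1e-12)
    assert ind140.q == pytest.approx(default_pk.q_typ * 2 ** 0.75, rel=1e-12)
    assert ind140.v1 == pytest.approx(default_pk.v1_typ * 2.0, rel=1e-12)
    assert ind140.v2 == pytest.approx(default_pk.v2_typ * 2.0, rel=1e-12)


def test_draw_individual_log_variance_matches_omega():
    subj = Subject(id="T", sex="male", age=60.0, body_weight=70.0)
    params = PopPKParameters(cl_typ=0.1, v1_typ=2.7, q_typ=0.0125, v2_typ=3.74,
                             iiv_variances={"cl": 0.09, "v1": 0.04})
    rng = np.random.default_rng(123)
    draws = [draw_individual(subj, params, rng) for _ in range(6000)]
    var_cl = np.var(np.log([d.cl for d in draws]), ddof=1)
    var_v1 = np.var(np.log([d.v1 for d in draws]), ddof=1)
    var_q = np.var(np.log([d.q for d in draws]), ddof=1)
    assert var_cl == pytest.approx(0.09, rel=0.10)
    assert var_v1 == pytest.approx(0.04, rel=0.10)
    assert var_q == pytest.approx(0.0, abs=1e-12)   # omega omitted -> no IIV


def test_draw_cohort_deterministic(small_cohort, default_pk):
    a = draw_cohort_individuals(small_cohort, default_pk, seed=5)
    b = draw_cohort_individuals(small_cohort, default_pk, seed=5)
    assert all(x.cl == y.cl and x.v1 == y.v1 for x, y in zip(a, b))
    c = draw_cohort_individuals(small_cohort, default_pk, seed=6)
    assert any(x.cl != y.cl for x, y in zip(a, c))


# ---------------------------------------------------------------------------
# Closed form vs numerical ODE integration
# ---------------------------------------------------------------------------

def _ode_profile(indiv: IndividualPK, doses, t_grid):
    """Independent oracle: integrate the 2-compartment ODEs segment by segment.

    States: central amount, peripheral amount, cumulative AUC of C = A1/V1.
    """
    k10, k12, k21 = indiv.micro_constants

    boundaries = sorted({0.0, *[d.start_time for d in doses],
                         *[d.start_time + d.duration for d in doses],
                         float(t_grid[-1])})
    boundaries = [b for b in boundaries if b <= t_grid[-1]]

    def rate_at(t):
        return sum(d.amount / d.duration for d in doses
                   if d.start_time < t < d.start_time + d.duration)

    conc, auc = {}, {}
    state = np.zeros(3)
    for lo, hi in zip(boundaries, boundaries[1:]):
        rate = rate_at((lo + hi) / 2.0)

        def rhs(_t, y, rate=rate):
            a1, a2, _ = y
            return [rate - (k10 + k12) * a1 + k21 * a2,
                    k12 * a1 - k21 * a2,
                    a1 / indiv.v1]

        eval_pts = [t for t in t_grid if lo < t <= hi]
        sol = solve_ivp(rhs, (lo, hi), state, t_eval=sorted({*eval_pts, hi}),
                        rtol=1e-11, atol=1e-13, method="LSODA")
        for i, t in enumerate(sol.t):
            conc[round(t, 9)] = sol.y[0, i] / indiv.v1
            auc[round(t, 9)] = sol.y[2, i]
        state = sol.y[:, -1]
    return conc, auc


def test_concentration_matches_ode(default_pk):
    indiv = _typical_individual(default_pk)
    doses = [DoseEvent(t0, 90.0, 0.5) for t0 in MONO_SCHEDULE]
    t_grid = np.array([0.25, 0.5, 1.0, 24.0, 167.9, 168.4, 200.0,
                       336.25, 400.0, 671.9, 672.0])
    conc_ode, auc_ode = _ode_profile(indiv, doses, t_grid)
    for t in t_grid:
        closed = concentration(float(t), doses, indiv)
        numeric = conc_ode[round(float(t), 9)]
        assert closed == pytest.approx(numeric, rel=1e-6)
    assert auc_to(TAU, doses, indiv) == pytest.approx(auc_ode[672.0], rel=1e-6)


def test_concentration_zero_before_dose_and_linearity(default_pk):
    indiv = _typical_individual(default_pk)
    doses = [DoseEvent(10.0, 90.0, 0.5)]
    assert concentration(5.0, doses, indiv) == 0.0
    assert concentration(10.0, doses, indiv) == 0.0
    double = [DoseEvent(10.0, 180.0, 0.5)]
    for t in (12.0, 48.0, 300.0):
        assert concentration(t, double, indiv) == pytest.approx(
            2.0 * concentration(t, doses, indiv), rel=1e-12)
    with pytest.raises(ValueError):
        concentration(-1.0, doses, indiv)


# ---------------------------------------------------------------------------
# Exposure metrics
# ---------------------------------------------------------------------------

def test_steady_state_auc_is_cycle_dose_over_cl(default_pk):
    indiv = _typical_individual(default_pk)
    m = exposure_metrics(indiv, MONO_SCHEDULE, 90.0, TAU)
    assert m.auc_ss * indiv.cl == pytest.approx(3 * 90.0, rel=1e-12)


def test_steady_state_trough_matches_long_superposition(default_pk):
    indiv = _typical_individual(default_pk)
    m = exposure_metrics(indiv, MONO_SCHEDULE, 90.0, TAU)
    n_cycles = 80
    doses = [DoseEvent(c * TAU + t0, 90.0, 0.5)
             for c in range(n_cycles) for t0 in MONO_SCHEDULE]
    brute = concentration(n_cycles * TAU, doses, indiv)
    assert m.ctrough_ss == pytest.approx(brute, rel=1e-9)


def test_cycle1_metrics_match_direct_evaluation(default_pk):
    indiv = _typical_individual(default_pk)
    m = exposure_metrics(indiv, MONO_SCHEDULE, 90.0, TAU)
    doses = [DoseEvent(t0, 90.0, 0.5) for t0 in MONO_SCHEDULE]
    assert m.auc_cycle1 == pytest.approx(auc_to(TAU, doses, indiv), rel=1e-12)
    assert m.ctrough_cycle1 == pytest.approx(
        concentration(TAU, doses, indiv), rel=1e-12)
    assert m.auc_ss > m.auc_cycle1          # accumulation
    assert m.ctrough_ss > m.ctrough_cycle1


def test_iterative_fallback_agrees_with_analytic(default_pk):
    indiv = _typical_individual(default_pk)
    analytic = exposure_metrics(indiv, MONO_SCHEDULE, 90.0, TAU)
    iterative = exposure_metrics_iterative(indiv, MONO_SCHEDULE, 90.0, TAU,
                                           rel_tol=1e-6)
    for ep in ENDPOINTS:
        assert getattr(iterative, ep) == pytest.approx(
            getattr(analytic, ep), rel=1e-3)


def test_iterative_non_convergence_raises(default_pk):
    indiv = _typical_individual(default_pk)
    with pytest.raises(ConvergenceError):
        exposure_metrics_iterative(indiv, MONO_SCHEDULE, 90.0, TAU,
                                   rel_tol=1e-12, max_cycles=2)


def test_exposure_metrics_edge_cases(default_pk):
    indiv = _typical_individual(default_pk)
    zero = exposure_metrics(indiv, MONO_SCHEDULE, 0.0, TAU)
    assert zero.as_dict() == {ep: 0.0 for ep in ENDPOINTS}
    with pytest.raises(ValueError):
        exposure_metrics(indiv, MONO_SCHEDULE, -1.0, TAU)
    with pytest.raises(ValueError):
        exposure_metrics(indiv, (336.0, 0.0, 168.0), 90.0, TAU)  # unsorted
    with pytest.raises(ValueError):
        exposure_metrics(indiv, (0.0, 700.0), 90.0, TAU)         # outside cycle


def test_macro_constants_consistent_with_micro(default_pk):
    indiv = _typical_individual(default_pk)
    k10, k12, k21 = indiv.micro_constants
    alpha, beta, a_coef, b_coef = indiv.hybrid_constants()
    assert alpha * beta == pytest.approx(k10 * k21, rel=1e-12)
    assert alpha + beta == pytest.approx(k10 + k12 + k21, rel=1e-12)
    # bolus coefficients integrate to 1/CL
    assert a_coef / alpha + b_coef / beta == pytest.approx(
        1.0 / indiv.cl, rel=1e-12)
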