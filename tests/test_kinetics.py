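"""Unit and property tests for the rate-law conversions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cqtkit import (
    ArrheniusParams,
    ExponentialResponse,
    IdenticalResponsesError,
    InvalidArgumentError,
    arrhenius_extrapolate,
    b_from_q10,
    crossover_temperature,
    delta_ea,
    ea_from_enthalpy,
    ea_from_q10,
    half_life,
    q10_from_b,
    q10_from_ea,
    rate_enhancement,
)
from cqtkit.kinetics import KELVIN_OFFSET, SECONDS_PER_YEAR


@pytest.mark.parametrize(
    "b, expected",
    [(0.0, 1.0), (math.log(2) / 10, 2.0), (0.1, math.e)],
)
def test_q10_from_slope(b, expected):
    assert q10_from_b(b) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "q10, expected",
    [(1.0, 0.0), (2.0, math.log(2) / 10), (math.exp(10), 1.0)],
)
def test_slope_from_q10(q10, expected):
    assert b_from_q10(q10) == pytest.approx(expected, abs=1e-12)


@given(st.floats(min_value=1.01, max_value=100.0))
@settings(derandomize=True, deadline=None)
def test_q10_slope_round_trip(q10):
    assert q10_from_b(b_from_q10(q10)) == pytest.approx(q10, rel=1e-12)


@pytest.mark.parametrize(
    "bad_call",
    [
        lambda: q10_from_b(float("nan")),
        lambda: b_from_q10(0.0),
        lambda: b_from_q10(-1.0),
        lambda: q10_from_ea(100, t_low=30, t_high=20),
        lambda: ea_from_enthalpy(100, 0.0),
        lambda: half_life(0.0),
        lambda: half_life(1.0, unit="fortnights"),
    ],
)
def test_invalid_arguments_rejected(bad_call):
    with pytest.raises(InvalidArgumentError):
        bad_call()


class TestQ10FromActivationEnergy:
    """Q10 between 20 and 30°C from an Arrhenius barrier."""

    @pytest.mark.parametrize(
        "ea, expected, tol",
        [
            (199.0, 14.78, 0.01),  # upper end of the uncatalysed barrier range
            (35.0, 1.61, 0.01),  # lower end
            (0.0, 1.0, 1e-12),  # no barrier, no temperature sensitivity
        ],
    )
    def test_barrier_endpoints(self, ea, expected, tol):
        assert q10_from_ea(ea) == pytest.approx(expected, abs=tol)

    @given(st.floats(min_value=0.0, max_value=300.0))
    @settings(derandomize=True, deadline=None)
    def test_round_trip_and_lower_bound(self, ea):
        q10 = q10_from_ea(ea)
        assert q10 >= 1.0
        assert ea_from_q10(q10) == pytest.approx(ea, abs=1e-9)

    def test_strictly_increasing_in_ea(self):
        values = [q10_from_ea(ea) for ea in range(0, 301, 10)]
        assert all(lo < hi for lo, hi in zip(values, values[1:]))

    def test_known_inverse_value(self):
        # frozen from a numeric root of q10_from_ea
        assert ea_from_q10(2.0) == pytest.approx(51.213, abs=0.01)

    def test_generalized_interval(self):
        # over a 20°C gap the (10/dT) exponent halves the log-ratio
        q_wide = q10_from_ea(100.0, t_low=10, t_high=30)
        q_narrow = q10_from_ea(100.0, t_low=10, t_high=20)
        assert q_wide < q_narrow
        assert ea_from_q10(q_wide, 10, 30) == pytest.approx(100.0, abs=1e-9)


def test_enthalpy_to_arrhenius_energy():
    assert ea_from_enthalpy(100.0, 298.15) == pytest.approx(102.479, abs=1e-3)
    assert ea_from_enthalpy(60.0, 310.15) == pytest.approx(62.579, abs=1e-3)
    assert ea_from_enthalpy(0.0, 1e-9) == pytest.approx(0.0, abs=1e-9)


class TestArrheniusExtrapolation:
    def test_identity_at_reference(self):
        p = ArrheniusParams(ea=123.0, ln_k_ref=-5.0, t_ref=298.15)
        assert arrhenius_extrapolate(p, 298.15) == -5.0

    def test_ten_degree_step(self):
        p = ArrheniusParams(ea=100.0, ln_k_ref=math.log(1e-10))
        k = math.exp(arrhenius_extrapolate(p, 308.15))
        assert k == pytest.approx(3.70e-10, rel=1e-2)

    def test_zero_barrier_is_flat(self):
        p = ArrheniusParams(ea=0.0, ln_k_ref=-3.0)
        for t in (273.15, 298.15, 473.15):
            assert arrhenius_extrapolate(p, t) == -3.0

    def test_monotone_in_temperature(self):
        p = ArrheniusParams(ea=80.0, ln_k_ref=-20.0)
        lnk = [arrhenius_extrapolate(p, 273.15 + t) for t in range(0, 201, 5)]
        assert all(lo < hi for lo, hi in zip(lnk, lnk[1:]))

    def test_round_trip_25_100_25(self):
        p = ArrheniusParams(ea=150.0, ln_k_ref=-30.0)
        ln_k100 = arrhenius_extrapolate(p, 373.15)
        back = arrhenius_extrapolate(
            ArrheniusParams(ea=150.0, ln_k_ref=ln_k100, t_ref=373.15), 298.15
        )
        assert back == pytest.approx(-30.0, abs=1e-10)


def test_half_life():
    # slowest known uncatalysed biological reaction: ~1.1 trillion years
    assert half_life(2.0e-20, "years") == pytest.approx(1.1e12, rel=0.01)
    assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-12)
    assert half_life(math.log(2) / SECONDS_PER_YEAR, "years") == pytest.approx(1.0)


@given(st.floats(min_value=1e-25, max_value=1e3))
@settings(derandomize=True, deadline=None)
def test_half_life_times_rate_is_ln2(k):
    assert half_life(k) * k == pytest.approx(math.log(2), rel=1e-12)


class TestCrossover:
    def test_forced_by_linearity(self):
        a = ExponentialResponse(ln_r0=1.0, b=0.05)
        c = ExponentialResponse(ln_r0=0.0, b=0.10)
        t = crossover_temperature(a, c)
        assert t == pytest.approx(20.0)
        assert a.ln_rate(t) == pytest.approx(2.0)

    def test_parallel_lines_never_cross(self):
        a = ExponentialResponse(ln_r0=1.0, b=0.07)
        c = ExponentialResponse(ln_r0=0.0, b=0.07)
        assert crossover_temperature(a, c) is None

    def test_identical_curves_flagged(self):
        a = ExponentialResponse(ln_r0=1.0, b=0.07)
        with pytest.raises(IdenticalResponsesError):
            crossover_temperature(a, a)

    def test_numeric_example(self):
        a = ExponentialResponse(ln_r0=0.0, b=0.0693)
        c = ExponentialResponse(ln_r0=-1.0, b=0.1386)
        assert crossover_temperature(a, c) == pytest.approx(14.43, abs=0.01)

    @given(
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=0.01, max_value=0.2),
        st.floats(min_value=-3, max_value=3),
        st.floats(min_value=0.01, max_value=0.2),
    )
    @settings(derandomize=True, deadline=None)
    def test_rates_equal_at_crossover(self, r0a, ba, r0c, bc):
        a = ExponentialResponse(ln_r0=r0a, b=ba)
        c = ExponentialResponse(ln_r0=r0c, b=bc)
        if ba == bc:
            return
        t = crossover_temperature(a, c)
        assert abs(a.ln_rate(t) - c.ln_rate(t)) < 1e-9


def test_rate_enhancement():
    assert rate_enhancement(0.0, math.log(1e-20)) == pytest.approx(1e20, rel=1e-9)
    assert rate_enhancement(-3.3, -3.3) == 1.0
    # the span of uncatalysed rates itself: 1e-1 vs 1e-20 is 1e19-fold
    assert rate_enhancement(math.log(1e-1), math.log(1e-20)) == pytest.approx(
        1e19, rel=1e-9
    )


def test_delta_ea():
    assert delta_ea(199.0, 60.0) == pytest.approx(139.0)
    assert delta_ea(50.0, 50.0) == 0.0
    with pytest.warns(UserWarning, match="negative"):
        assert delta_ea(35.0, 70.0) == pytest.approx(-35.0)


def test_exponential_response_q10():
    resp = ExponentialResponse(ln_r0=0.0, b=math.log(2) / 10)
    assert resp.q10 == pytest.approx(2.0)
    assert resp.ln_rate(10.0) == pytest.approx(math.log(2))
    with pytest.raises(InvalidArgumentError):
        ExponentialResponse(ln_r0=float("inf"), b=0.1)


def test_kelvin_offset_constant_used_consistently():
    # q10_from_ea over (0, 10)°C must equal the Arrhenius two-point ratio
    p = ArrheniusParams(ea=100.0, ln_k_ref=0.0, t_ref=KELVIN_OFFSET)
    direct = math.exp(arrhenius_extrapolate(p, KELVIN_OFFSET + 10.0))
    assert q10_from_ea(100.0, 0.0, 10.0) == pytest.approx(direct, rel=1e-12)
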