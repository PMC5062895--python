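"""Tests of the consecutive-reaction model against closed forms and the ODE oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smokekin import (
    ConsecutiveModel,
    DomainError,
    derived_summary,
    intermediate_at,
    invert_k2_from_product,
    nic_at,
    ode_oracle,
    product_at,
    product_simplified,
    time_of_max_intermediate,
)


class TestClosedForms:
    def test_initial_conditions(self, es1_model):
        assert nic_at(es1_model, 0.0) == es1_model.nic0
        assert intermediate_at(es1_model, 0.0) == 0.0
        assert product_at(es1_model, 0.0) == pytest.approx(0.0, abs=1e-6 * es1_model.nic0)

    def test_nicotine_decay(self, es1_model):
        assert nic_at(es1_model, 2.0) == pytest.approx(8.0e8 * math.exp(-2.22), rel=1e-12)
        assert nic_at(es1_model, 500.0) == pytest.approx(0.0, abs=1e-90)

    def test_intermediate_with_printed_rate_constants(self, es1_model):
        # the inferred pyridinyl-radical concentration for ES1
        assert intermediate_at(es1_model, 2.0) == pytest.approx(6.0025e8, rel=1e-4)

    def test_product_closed_form(self, es1_model):
        assert product_at(es1_model, 2.0) == pytest.approx(1.128587e8, rel=1e-5)

    def test_product_simplified(self, es1_model):
        assert product_simplified(es1_model, 2.0) == pytest.approx(
            8.0e8 * (1.0 - math.exp(-0.26)), rel=1e-12
        )

    def test_negative_time_rejected(self, es1_model):
        for fn in (nic_at, intermediate_at, product_at, product_simplified):
            with pytest.raises(DomainError):
                fn(es1_model, -0.1)


@settings(derandomize=True, max_examples=200)
@given(
    k1=st.floats(1e-3, 10.0),
    k2=st.floats(1e-3, 10.0),
    t=st.floats(0.0, 10.0),
)
def test_mass_conservation_property(k1, k2, t):
    """nic + intermediate + product equals [Nic]0 at every time."""
    m = ConsecutiveModel(k1=k1, k2=k2, nic0=8.0e8)
    total = nic_at(m, t) + intermediate_at(m, t) + product_at(m, t)
    assert total == pytest.approx(m.nic0, rel=1e-9)


@pytest.mark.parametrize("ratio", [0.1, 1.0, 10.0, 100.0])
def test_analytic_solutions_match_ode_oracle(ratio):
    """Closed forms agree with direct numerical integration of the rate equations."""
    k2 = 0.5
    k1 = k2 * ratio
    m = ConsecutiveModel(k1=k1, k2=k2, nic0=8.0e8)
    times = np.linspace(0.0, 10.0, 41)
    traj = ode_oracle(m, times)
    for i, t in enumerate(times):
        tol = dict(rel=1e-6, abs=1e-9 * m.nic0)
        assert traj.nic[i] == pytest.approx(nic_at(m, t), **tol)
        assert traj.intermediate[i] == pytest.approx(intermediate_at(m, t), **tol)
        assert traj.product[i] == pytest.approx(product_at(m, t), **tol)


def test_ode_oracle_equal_rates_matches_analytic_limit():
    k = 0.8
    m = ConsecutiveModel(k1=k, k2=k, nic0=1.0e6)
    times = np.linspace(0.0, 6.0, 13)
    traj = ode_oracle(m, times)
    for i, t in enumerate(times):
        expected = m.nic0 * k * t * math.exp(-k * t)
        assert traj.intermediate[i] == pytest.approx(expected, rel=1e-6, abs=1e-4)


def test_ode_oracle_conservation_and_validation():
    m = ConsecutiveModel(k1=1.11, k2=0.13, nic0=8.0e8)
    times = np.linspace(0.0, 10.0, 21)
    traj = ode_oracle(m, times)
    np.testing.assert_allclose(
        traj.nic + traj.intermediate + traj.product, m.nic0, rtol=1e-8
    )
    with pytest.raises(DomainError):
        ode_oracle(m, np.array([2.0, 1.0]))
    with pytest.raises(DomainError):
        ode_oracle(m, np.array([-1.0, 1.0]))


def test_intermediate_continuous_across_equal_rate_branch():
    """The k1 = k2 analytic limit joins the generic formula continuously."""
    k = 0.7
    nic0 = 8.0e8
    t = 2.0
    limit = ConsecutiveModel(k1=k, k2=k, nic0=nic0)
    near = ConsecutiveModel(k1=k * (1.0 + 1e-8), k2=k, nic0=nic0)
    assert intermediate_at(near, t) == pytest.approx(intermediate_at(limit, t), rel=1e-7)
    # just outside the switch threshold the generic formula must agree too
    outside = ConsecutiveModel(k1=k * (1.0 + 1e-5), k2=k, nic0=nic0)
    assert intermediate_at(outside, t) == pytest.approx(intermediate_at(limit, t), rel=1e-4)


@pytest.mark.parametrize("ratio", [10.0, 30.0, 100.0, 300.0])
def test_simplified_product_converges_when_k1_dominates(ratio):
    """The rate-determining-step approximation improves as k1/k2 grows."""
    k2 = 0.13
    m = ConsecutiveModel(k1=k2 * ratio, k2=k2, nic0=8.0e8)
    ts = np.linspace(1.0 / m.k1, 10.0, 25)
    gap = max(abs(product_simplified(m, t) - product_at(m, t)) / m.nic0 for t in ts)
    assert gap < 2.0 / ratio  # ~1/ratio scaling; < 0.02 at ratio 100


def test_simplified_convergence_is_monotone_in_ratio():
    k2 = 0.13
    gaps = []
    for ratio in (10.0, 30.0, 100.0, 300.0):
        m = ConsecutiveModel(k1=k2 * ratio, k2=k2, nic0=8.0e8)
        ts = np.linspace(1.0 / m.k1, 10.0, 25)
        gaps.append(max(abs(product_simplified(m, t) - product_at(m, t)) / m.nic0 for t in ts))
    assert gaps == sorted(gaps, reverse=True)


class TestInvertK2:
    def test_zero_product(self):
        assert invert_k2_from_product(8.0e8, 0.0, 2.0) == 0.0

    def test_printed_inputs_give_point_four(self):
        # -ln(1 - 4.4/8.0)/2: the closed form disagrees with the source's
        # printed 0.13 s^-1 (which coincides with the formation-side value)
        assert invert_k2_from_product(8.0e8, 4.4e8, 2.0) == pytest.approx(
            0.399253848, rel=1e-8
        )

    def test_product_exceeding_precursor_rejected(self):
        with pytest.raises(DomainError):
            invert_k2_from_product(8.0e8, 8.0e8, 2.0)

    @settings(derandomize=True, max_examples=100)
    @given(k2=st.floats(1e-4, 2.0), t=st.floats(0.1, 10.0))
    def test_round_trip_through_simplified_product(self, k2, t):
        m = ConsecutiveModel(k1=5.0, k2=k2, nic0=8.0e8)
        assert invert_k2_from_product(m.nic0, product_simplified(m, t), t) == pytest.approx(
            k2, rel=1e-9
        )


class TestTimeOfMaxIntermediate:
    def test_printed_rate_constants(self, es1_model):
        assert time_of_max_intermediate(es1_model) == pytest.approx(2.1883478, rel=1e-6)

    def test_closed_form_factor_two(self):
        k = 0.4
        m = ConsecutiveModel(k1=2 * k, k2=k, nic0=1.0)
        assert time_of_max_intermediate(m) == pytest.approx(math.log(2.0) / k, rel=1e-12)

    def test_symmetric_under_rate_swap(self):
        a = time_of_max_intermediate(ConsecutiveModel(k1=1.11, k2=0.13, nic0=1.0))
        b = time_of_max_intermediate(ConsecutiveModel(k1=0.13, k2=1.11, nic0=1.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_equal_rates_limit(self):
        m = ConsecutiveModel(k1=0.5, k2=0.5, nic0=1.0)
        assert time_of_max_intermediate(m) == pytest.approx(2.0, rel=1e-9)

    def test_maximizes_the_intermediate(self, es1_model):
        tm = time_of_max_intermediate(es1_model)
        peak = intermediate_at(es1_model, tm)
        for t in np.linspace(0.0, 10.0, 400):
            assert intermediate_at(es1_model, t) <= peak * (1.0 + 1e-12)


class TestDerivedSummary:
    def test_es1_summary(self, es1_model):
        s = derived_summary(es1_model, 4.4e8)
        assert s.ratio_product_to_nic == pytest.approx(0.55, rel=1e-12)
        assert s.pct_transferred_intact == pytest.approx(45.0, rel=1e-12)
        assert s.ratio_nic_to_sum == pytest.approx(0.769, abs=5e-4)
        assert s.intermediate_at_t == pytest.approx(6.0025e8, rel=1e-4)

    def test_rejects_undefined_ratio(self):
        # a k1/k2 pair cannot make the intermediate negative, so force the
        # degenerate denominator with product_max = 0 at t = 0
        m = ConsecutiveModel(k1=1.0, k2=1.0, nic0=1.0, t=0.0)
        with pytest.raises(DomainError):
            derived_summary(m, 0.0)

    def test_rejects_product_above_precursor(self, es1_model):
        with pytest.raises(DomainError):
            derived_summary(es1_model, 9.0e8)


def test_model_validation():
    with pytest.raises(DomainError):
        ConsecutiveModel(k1=0.0, k2=0.1, nic0=1.0)
    with pytest.raises(DomainError):
        ConsecutiveModel(k1=0.1, k2=0.1, nic0=-1.0)
    with pytest.raises(DomainError):
        ConsecutiveModel(k1=0.1, k2=0.1, nic0=1.0, t=-1.0)
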