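"""Exact stationary law of the binding motif and its QSSA approximations.

Reference values come from independent routes: hand-enumerated two-state
balance for tiny systems, a literal linear-pass solution of the
steady-state three-term recurrence for the general law, and closed-form
algebra for the deterministic branch.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoqssa import (
    BindingPair,
    UndefinedValueError,
    exact_mean,
    exact_mean_complex,
    exact_mean_partner,
    exact_stationary_distribution,
    exact_variance,
    fano_factor,
    relative_error,
    relative_sensitivity,
    slqssa,
    slqssa_two_state,
    sqssa_complex,
    stqssa,
    tqssa,
)
from stoqssa.binding import stqssa_unbound

from conftest import random_pairs


def recurrence_distribution(pair):
    """Independent oracle: solve the steady-state CME recurrence directly.

    Starting from p(A_0) = 1 and p(A_0 - 1) = 0, the three-term balance

        (l+1)(B_T - A_T + l + 1) p(l+1) - l (B_T - A_T + l) p(l)
        + K_d (A_T - l + 1) p(l-1) - K_d (A_T - l) p(l) = 0

    is stepped upward one state at a time, then normalized.  Exact
    rational arithmetic (on the binary-exact K_d) keeps the forward pass
    free of the catastrophic cancellation it suffers in floats, so this
    is a rigorous independent route to the same law.
    """
    from fractions import Fraction

    a0, at, bt = pair.A_0, pair.A_T, pair.B_T
    kd = Fraction(pair.K_d)
    p = {a0 - 1: Fraction(0), a0: Fraction(1)}
    for l in range(a0, at):
        num = (
            l * (bt - at + l) * p[l]
            + kd * (at - l) * p[l]
            - kd * (at - l + 1) * p[l - 1]
        )
        p[l + 1] = num / ((l + 1) * (bt - at + l + 1))
    total = sum(p[l] for l in range(a0, at + 1))
    return np.array([float(p[l] / total) for l in range(a0, at + 1)])


class TestExactDistribution:
    def test_two_state_enumeration(self):
        # A_T=2, B_T=1, K_d=1: states A in {1,2}; balance gives
        # p(2)/p(1) = K_d/2, hence p = (2/3, 1/3)
        d = exact_stationary_distribution(BindingPair(2, 1, 1.0))
        assert list(d.support) == [1, 2]
        np.testing.assert_allclose(d.probabilities, [2 / 3, 1 / 3], rtol=1e-12)

    def test_no_partner_is_point_mass(self):
        d = exact_stationary_distribution(BindingPair(3, 0, 7.0))
        assert list(d.support) == [3]
        assert d.pmf(3) == 1.0 and d.pmf(2) == 0.0

    def test_single_pair_tight_binding_ratio(self):
        # A_T=B_T=1: p(1)/p(0) = K_d exactly
        d = exact_stationary_distribution(BindingPair(1, 1, 1e-4))
        assert d.pmf(1) / d.pmf(0) == pytest.approx(1e-4, rel=1e-12)

    def test_sequestration_low_state_probability(self):
        # 1:1 tight binding: a single unbound molecule is a ~1% event
        d = exact_stationary_distribution(BindingPair(100, 100, 1e-4))
        assert d.pmf(1) == pytest.approx(0.01, abs=2e-3)

    def test_matches_recurrence_linear_pass(self, rng):
        for pair in random_pairs(rng, 25, max_total=200):
            d = exact_stationary_distribution(pair)
            ref = recurrence_distribution(pair)
            np.testing.assert_allclose(
                d.probabilities, ref, rtol=1e-10, atol=1e-300,
                err_msg=f"{pair}",
            )

    def test_normalization_and_support(self, rng):
        for pair in random_pairs(rng, 40):
            d = exact_stationary_distribution(pair)
            assert abs(d.probabilities.sum() - 1.0) < 1e-12
            assert (d.probabilities >= 0).all()
            assert d.support[0] == pair.A_0 and d.support[-1] == pair.A_T
            assert d.pmf(pair.A_0 - 1) == 0.0 and d.pmf(pair.A_T + 1) == 0.0

    def test_large_totals_stay_finite(self):
        pair = BindingPair(10**6, 10**6, 1e-2)
        d = exact_stationary_distribution(pair)
        assert np.isfinite(d.probabilities).all()
        assert abs(d.probabilities.sum() - 1.0) < 1e-9
        # mean must sit between the low-state value and the tQSSA value
        assert 0 < d.mean() < stqssa_unbound(1e6, 1e6, 1e-2) * 1.01


class TestExactMean:
    def test_enumerated_mean(self):
        assert exact_mean(BindingPair(2, 1, 1.0)).value == pytest.approx(
            4 / 3, rel=1e-12
        )

    def test_empty_partner_pool(self):
        assert exact_mean(BindingPair(7, 0, 3.3)).value == 7.0

    def test_consistent_with_distribution(self, rng):
        for pair in random_pairs(rng, 20):
            d = exact_stationary_distribution(pair)
            assert exact_mean(pair).value == pytest.approx(d.mean(), rel=1e-10)

    def test_conservation_accessors(self):
        pair = BindingPair(10, 6, 0.5)
        a = exact_mean(pair).value
        assert exact_mean_complex(pair).value == pytest.approx(10 - a, rel=1e-12)
        assert exact_mean_partner(pair).value == pytest.approx(
            6 - 10 + a, rel=1e-12
        )

    def test_role_swap_symmetry(self, rng):
        # <B>(A_T,B_T) from conservation equals <A> of the swapped pair
        for pair in random_pairs(rng, 15, max_total=150):
            if pair.A_T == 0 and pair.B_T == 0:
                continue
            b_via_conservation = exact_mean_partner(pair).value
            b_direct = exact_mean(pair.swapped()).value
            # the conservation route subtracts totals, so its absolute
            # noise floor is ~eps * (A_T + B_T)
            floor = 1e-9 * (pair.A_T + pair.B_T + 1)
            assert b_via_conservation == pytest.approx(
                b_direct, rel=1e-9, abs=floor
            )


class TestMomentIdentities:
    def test_quadratic_moment_identity(self, rng):
        # <A^2> - (A_T - B_T - K_d)<A> - A_T K_d = 0 at stationarity
        for pair in random_pairs(rng, 25, max_total=150):
            d = exact_stationary_distribution(pair)
            m, m2 = d.mean(), d.second_moment()
            resid = m2 - (pair.A_T - pair.B_T - pair.K_d) * m - pair.A_T * pair.K_d
            scale = max(abs(m2), pair.A_T * pair.K_d, 1.0)
            assert abs(resid) / scale < 1e-8, f"{pair}"

    def test_mean_recovered_from_variance(self, rng):
        # <A> = ((A_T-B_T-K_d) + sqrt((A_T-B_T-K_d)^2 + 4 A_T K_d - 4Var))/2
        for pair in random_pairs(rng, 25, max_total=150):
            if pair.A_T == 0:
                continue
            b = pair.A_T - pair.B_T - pair.K_d
            disc = b * b + 4 * pair.A_T * pair.K_d - 4 * exact_variance(pair)
            assert disc >= -1e-9
            recovered = 0.5 * (b + math.sqrt(max(disc, 0.0)))
            assert recovered == pytest.approx(
                exact_mean(pair).value, rel=1e-7, abs=1e-9
            )


class TestStqssa:
    def test_direct_evaluation(self):
        a, b, c = tqssa(2.0, 1.0, 1.0)
        assert a == pytest.approx(math.sqrt(2), rel=1e-12)
        assert c == pytest.approx(2 - math.sqrt(2), rel=1e-12)

    def test_collapse_without_partner(self):
        assert tqssa(9.0, 0.0, 0.37)[0] == pytest.approx(9.0, rel=1e-12)

    def test_tight_one_to_one_value(self):
        # 1:1 tight binding: A_tq ~= sqrt(A_T K_d) >> <A>
        a_tq = stqssa_unbound(100, 100, 1e-4)
        assert a_tq == pytest.approx(0.1, abs=5e-4)

    def test_conservation_identities(self, rng):
        for pair in random_pairs(rng, 30):
            a, b, c = stqssa(pair)
            tot = max(pair.A_T, pair.B_T, 1.0)
            assert a.value + c.value == pytest.approx(pair.A_T, abs=1e-12 * tot)
            assert b.value + c.value == pytest.approx(pair.B_T, abs=1e-12 * tot)

    def test_stable_branch_in_deep_sequestration(self):
        # naive quadratic root would cancel catastrophically here
        a = stqssa_unbound(1e6, 2e6, 1e-8)
        expected = 1e6 * 1e-8 / (1e6 + 1e-8)  # ~ A_T K_d / (B_T - A_T)
        assert a == pytest.approx(expected, rel=1e-6)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            tqssa(float("nan"), 1.0, 1.0)
        with pytest.raises(ValueError):
            tqssa(1.0, 1.0, 0.0)


class TestSlqssa:
    def test_two_state_closed_form_matches_truncation(self, rng):
        for pair in random_pairs(rng, 30):
            if pair.A_T == 0:
                continue
            assert slqssa(pair, 2).value == pytest.approx(
                slqssa_two_state(pair).value, rel=1e-12, abs=1e-300
            )

    def test_two_state_worked_value(self):
        # A_T = B_T = 100, K_d = 1e-4: lower branch gives 0.01/1.01
        est = slqssa(BindingPair(100, 100, 1e-4), 2)
        assert est.value == pytest.approx(0.01 / 1.01, rel=1e-12)

    def test_full_support_truncation_is_exact(self, rng):
        for pair in random_pairs(rng, 15, max_total=60):
            k = pair.A_T - pair.A_0 + 1
            if k < 2:
                k = 2
            assert slqssa(pair, k).value == pytest.approx(
                exact_mean(pair).value, rel=1e-12, abs=1e-300
            )

    def test_exact_truncation_on_enumerated_pair(self):
        # support {1, 2} has exactly two states: k=2 is the exact mean
        assert slqssa(BindingPair(2, 1, 1.0), 2).value == pytest.approx(
            4 / 3, rel=1e-12
        )

    def test_error_shrinks_with_k_in_tight_regime(self, rng):
        for _ in range(15):
            kd = float(np.exp(rng.uniform(np.log(1e-5), np.log(1e-1))))
            a_t = int(rng.integers(1, int(10 / kd) + 1))
            if a_t * kd > 10:
                continue
            b_t = int(rng.integers(0, 2 * a_t + 1))
            pair = BindingPair(a_t, b_t, kd)
            ex = exact_mean(pair).value
            e2 = abs(slqssa(pair, 2).value - ex)
            e5 = abs(slqssa(pair, 5).value - ex)
            assert e5 <= e2 + 1e-15

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            slqssa(BindingPair(5, 5, 1.0), 1)


class TestSqssa:
    @pytest.mark.parametrize(
        "a_t,b,kd,expected",
        [(4.0, 0.0, 1.0, 0.0), (10.0, 2.0, 2.0, 5.0), (1.0, 100.0, 1.0, 100 / 101)],
    )
    def test_michaelis_menten_form(self, a_t, b, kd, expected):
        assert sqssa_complex(a_t, b, kd).value == pytest.approx(expected, abs=1e-12)

    def test_validity_regime_matches_tqssa_complex(self, rng):
        # B_T + K_d >> A_T: the Michaelis-Menten complex tracks C_tq
        for _ in range(20):
            a_t = float(rng.integers(1, 50))
            b_t = float(rng.integers(1, 1000)) + 100.0 * a_t
            kd = float(np.exp(rng.uniform(np.log(1e-2), np.log(1e3))))
            _, b_tq, c_tq = tqssa(a_t, b_t, kd)
            c_sq = sqssa_complex(a_t, b_tq, kd).value
            if c_tq > 0:
                assert abs(c_sq - c_tq) / c_tq < 0.05


class TestDiagnostics:
    def test_sensitivity_closed_form(self):
        pair = BindingPair(2, 1, 1.0)
        assert relative_sensitivity(pair) == pytest.approx(
            1 / math.sqrt(8), rel=1e-12
        )

    def test_sensitivity_peak_at_matched_totals(self):
        # B_T = A_T - K_d maximizes S_A at 1/sqrt(4 A_T K_d)
        a_t, kd = 100, 1.0
        peak = relative_sensitivity(BindingPair(a_t, a_t - 1, kd))
        assert peak == pytest.approx(1 / math.sqrt(4 * a_t * kd), rel=1e-12)
        for b_t in (0, 50, 80, 120, 200):
            assert relative_sensitivity(BindingPair(a_t, b_t, kd)) <= peak + 1e-15

    def test_sensitivity_vanishes_for_weak_binding(self):
        assert relative_sensitivity(BindingPair(10, 10, 1e9)) < 1e-8

    def test_fano_factor_enumerated(self):
        d = exact_stationary_distribution(BindingPair(2, 1, 1.0))
        # Var = 2/9, mean = 4/3
        assert fano_factor(d) == pytest.approx(1 / 6, rel=1e-10)

    def test_fano_point_mass_zero(self):
        d = exact_stationary_distribution(BindingPair(3, 0, 1.0))
        assert fano_factor(d) == 0.0

    def test_fano_undefined_at_zero_mean(self):
        d = exact_stationary_distribution(BindingPair(0, 5, 1.0))
        with pytest.raises(UndefinedValueError):
            fano_factor(d)

    def test_sub_poissonian_on_random_grid(self, rng):
        for pair in random_pairs(rng, 40):
            if pair.A_T == 0:
                continue
            assert fano_factor(exact_stationary_distribution(pair)) < 1.0

    def test_relative_error_worked_value(self):
        pair = BindingPair(2, 1, 1.0)
        r = relative_error(stqssa(pair)[0], exact_mean(pair))
        assert r == pytest.approx(abs(math.sqrt(2) - 4 / 3) / (4 / 3), rel=1e-10)

    def test_relative_error_undefined_at_zero(self):
        pair = BindingPair(0, 5, 1.0)
        with pytest.raises(UndefinedValueError):
            relative_error(stqssa(pair)[0], exact_mean(pair))

    def test_error_bounds_from_fano_and_sensitivity(self, rng):
        # F_A S_A <= R_A <= 2 F_A S_A for the stQSSA of the unbound species
        for pair in random_pairs(rng, 40):
            if pair.A_T == 0:
                continue
            ex = exact_mean(pair)
            if ex.value <= 0:
                continue
            r = relative_error(stqssa(pair)[0], ex)
            f = fano_factor(exact_stationary_distribution(pair))
            s = relative_sensitivity(pair)
            assert r >= f * s - 1e-9 * (1 + f * s), f"{pair}"
            assert r <= 2 * f * s + 1e-9 * (1 + f * s), f"{pair}"

    def test_thermodynamic_limit_shrinks_error(self):
        # scaling counts and K_d together sends the stQSSA error to zero
        errs = []
        for c in (1, 10, 100):
            pair = BindingPair(20 * c, 20 * c, 1e-3 * c)
            errs.append(relative_error(stqssa(pair)[0], exact_mean(pair)))
        assert errs[0] > errs[1] > errs[2]


class TestBindingPairValidation:
    @pytest.mark.parametrize(
        "a_t,b_t,kd",
        [(-1, 0, 1.0), (0, -2, 1.0), (1, 1, 0.0), (1, 1, -3.0),
         (1.5, 1, 1.0), (1, 1, float("inf"))],
    )
    def test_invalid_inputs_rejected(self, a_t, b_t, kd):
        with pytest.raises(ValueError):
            BindingPair(a_t, b_t, kd)

    def test_near_integer_totals_rounded(self):
        pair = BindingPair(3.0 + 1e-12, 2.0 - 1e-12, 0.5)
        assert pair.A_T == 3 and pair.B_T == 2

    def test_from_rates(self):
        pair = BindingPair.from_rates(100, 100, 1e4, 1.0)
        assert pair.K_d == pytest.approx(1e-4, rel=1e-12)

    def test_support_lower_bound(self):
        assert BindingPair(7, 3, 1.0).A_0 == 4
        assert BindingPair(3, 7, 1.0).A_0 == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a_t=st.integers(0, 120),
    b_t=st.integers(0, 120),
    kd=st.floats(1e-6, 1e3),
)
def test_distribution_properties_hold_generally(a_t, b_t, kd):
    """Normalization, support bounds, and the sub-Poissonian property."""
    pair = BindingPair(a_t, b_t, kd)
    d = exact_stationary_distribution(pair)
    assert abs(d.probabilities.sum() - 1.0) < 1e-12
    assert d.mean() <= pair.A_T + 1e-9
    assert d.mean() >= pair.A_0 - 1e-9
    if d.mean() > 0:
        assert d.variance() / d.mean() < 1.0
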