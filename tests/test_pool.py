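"""One-pool model: closed forms, inversions, and ODE cross-checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrpkinetics import pool
from rrpkinetics.types import RateTriple, SucroseProtocol

WT = RateTriple(385.6, 0.0903, 0.000844)
D166Y = RateTriple(37.68, 0.0294, 0.03522)

rate_triples = st.builds(
    RateTriple,
    k1=st.floats(1.0, 2000.0),
    k_minus1=st.floats(1e-3, 2.0),
    kf=st.floats(1e-5, 0.5),
)


class TestForwardModel:
    @pytest.mark.parametrize(
        "rates,expected",
        [
            (WT, 385.6 / (0.0903 + 0.000844)),          # 4230.66
            (D166Y, 37.68 / (0.0294 + 0.03522)),        # 583.10
            (RateTriple(0.0, 0.3, 0.1), 0.0),
        ],
    )
    def test_steady_state(self, rates, expected):
        assert pool.steady_state_rrp(rates) == pytest.approx(expected, rel=1e-12)

    def test_steady_state_rejects_zero_denominator(self):
        with pytest.raises(ValueError):
            pool.steady_state_rrp(RateTriple(1.0, 0.0, 0.0))

    def test_time_course_anchors(self):
        assert pool.rrp_time_course(WT, 0.0, rrp0=0.0) == 0.0
        inf = pool.steady_state_rrp(WT)
        assert pool.rrp_time_course(WT, 1e6) == pytest.approx(inf, rel=1e-9)
        # one relaxation time: (1 - 1/e) of the asymptote ~ 2674.3
        t = 1.0 / WT.decay_rate
        assert pool.rrp_time_course(WT, t) == pytest.approx(
            inf * (1 - math.exp(-1)), rel=1e-12
        )

    def test_time_course_rejects_negative_time(self):
        with pytest.raises(ValueError):
            pool.rrp_time_course(WT, -1.0)

    @pytest.mark.parametrize(
        "rates,expected",
        [
            (WT, 0.000844 * 385.6 / 0.091144),   # 3.5707
            (D166Y, 0.03522 * 37.68 / 0.06462),  # 20.537
            (RateTriple(100.0, 0.5, 0.0), 0.0),
        ],
    )
    def test_predicted_mini_rate(self, rates, expected):
        assert pool.predicted_mini_rate(rates) == pytest.approx(expected,
                                                                rel=1e-9)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(rates=rate_triples, rrp0=st.floats(0.0, 5000.0))
    def test_closed_form_matches_ode(self, rates, rrp0):
        """Analytic relaxation equals numerical integration to 1e-8."""
        from scipy.integrate import solve_ivp

        t_eval = np.linspace(0.0, 3.0 / rates.decay_rate, 7)
        sol = solve_ivp(
            lambda t, y: [rates.k1 - rates.decay_rate * y[0]],
            (0.0, t_eval[-1]), [rrp0], t_eval=t_eval,
            rtol=1e-11, atol=1e-11,
        )
        closed = pool.rrp_time_course(rates, t_eval, rrp0=rrp0)
        scale = max(pool.steady_state_rrp(rates), rrp0, 1.0)
        assert np.max(np.abs(closed - sol.y[0])) / scale < 1e-8


class TestEstimateRates:
    def test_round_trip_is_exact(self):
        est = pool.estimate_rates(
            rrp_vesicles=pool.steady_state_rrp(WT),
            mini_rate=pool.predicted_mini_rate(WT),
            plateau_rate=WT.k1,
        )
        assert est.rates.k1 == pytest.approx(WT.k1, rel=1e-12)
        assert est.rates.k_minus1 == pytest.approx(WT.k_minus1, rel=1e-9)
        assert est.rates.kf == pytest.approx(WT.kf, rel=1e-12)
        assert est.flags == ()

    def test_wildtype_observables(self):
        est = pool.estimate_rates(4230.66, 3.5707, 385.6)
        assert est.rates.k1 == pytest.approx(385.6)
        assert est.rates.k_minus1 == pytest.approx(0.0903, rel=1e-3)
        assert est.rates.kf == pytest.approx(0.000844, rel=1e-3)

    def test_plateau_below_mini_rejected(self):
        with pytest.raises(ValueError):
            pool.estimate_rates(100.0, 5.0, 3.0)

    def test_negative_depriming_flagged_not_clipped_silently(self):
        # a plateau slower than the resting mini flux implies k_minus1 < 0
        # once the finite fold-increase is accounted for
        est = pool.estimate_rates_finite_nsuc(
            rrp_vesicles=100.0, mini_rate=1.0, plateau_rate=0.5, n_suc=10.0
        )
        assert "negative_k_minus1" in est.flags
        assert est.k_minus1_raw < 0
        assert est.rates.k_minus1 == 0.0  # stored value floored, raw kept


class TestEstimateRatesFiniteNsuc:
    def test_converges_to_infinite_limit(self):
        rrp = pool.steady_state_rrp(WT)
        mini = pool.predicted_mini_rate(WT)
        inf = pool.estimate_rates(rrp, mini, WT.k1)
        fin = pool.estimate_rates_finite_nsuc(rrp, mini, WT.k1, n_suc=1e6)
        # agreement to 4 significant digits (residual ~ k_minus1/(kf*n_suc))
        assert fin.rates.k1 == pytest.approx(inf.rates.k1, rel=5e-4)
        assert fin.rates.k_minus1 == pytest.approx(inf.rates.k_minus1,
                                                   rel=5e-3)

    def test_exact_recovery_from_forward_observables(self):
        """Closed-form inversion of its own forward model is exact."""
        n_suc = 5000.0
        rrp = pool.steady_state_rrp(WT)
        mini = pool.predicted_mini_rate(WT)
        plateau = WT.kf * n_suc * WT.k1 / (WT.k_minus1 + WT.kf * n_suc)
        est = pool.estimate_rates_finite_nsuc(rrp, mini, plateau, n_suc)
        assert est.rates.k1 == pytest.approx(WT.k1, rel=1e-10)
        assert est.rates.k_minus1 == pytest.approx(WT.k_minus1, rel=1e-10)

    def test_monotone_in_nsuc_and_mutant_less_dependent(self):
        """Estimated k1 rises monotonically to its asymptote with n_suc;
        conditions with higher resting kf depend less on n_suc."""
        def k1_curve(rates):
            rrp = pool.steady_state_rrp(rates)
            mini = pool.predicted_mini_rate(rates)
            plateau = rates.kf * 5000 * rates.k1 / (
                rates.k_minus1 + rates.kf * 5000
            )  # observables generated at true n_suc=5000
            out = []
            # restrict to the domain where a positive solution exists
            # (assumed kf*n_suc*RRP must exceed the measured plateau)
            for n in [1000, 2000, 5000, 2e4, 1e5, 1e6]:
                est = pool.estimate_rates_finite_nsuc(rrp, mini, plateau, n)
                assert "no_positive_solution" not in est.flags
                out.append(est.rates.k1)
            return np.array(out)

        wt_curve = k1_curve(WT)
        assert np.all(np.diff(wt_curve) < 0)  # decreasing toward asymptote
        rel_dep_wt = abs(wt_curve[0] / wt_curve[-1] - 1)
        mut_curve = k1_curve(D166Y)
        rel_dep_mut = abs(mut_curve[0] / mut_curve[-1] - 1)
        assert rel_dep_mut < rel_dep_wt

    def test_no_positive_solution_flagged(self):
        # plateau faster than total sucrose-driven turnover is impossible
        est = pool.estimate_rates_finite_nsuc(
            rrp_vesicles=100.0, mini_rate=0.1, plateau_rate=10_000.0,
            n_suc=10.0,
        )
        assert "no_positive_solution" in est.flags


class TestEstimateRatesFromSucrose:
    @pytest.mark.parametrize("rates", [WT, D166Y], ids=["WT", "D166Y"])
    def test_inverts_its_forward_model(self, rates):
        protocol = SucroseProtocol(onset_time=0.0, duration=5.0,
                                   n_suc=5000.0, exchange_time=0.05)
        obs = pool.expected_sucrose_observables(rates, protocol)
        est = pool.estimate_rates_from_sucrose(
            obs["transient_vesicles"], obs["mini_rate"],
            obs["plateau_rate"], protocol,
        )
        assert est.rates.k1 == pytest.approx(rates.k1, rel=1e-6)
        assert est.rates.k_minus1 == pytest.approx(rates.k_minus1, rel=1e-5)
        assert est.rates.kf == pytest.approx(rates.kf, rel=1e-6)

    def test_transient_smaller_than_resting_pool(self):
        """The measurable transient undershoots the resting RRP (finite
        n_suc plateau fraction + residual steady pool)."""
        protocol = SucroseProtocol(onset_time=0.0, duration=5.0,
                                   n_suc=5000.0, exchange_time=0.05)
        obs = pool.expected_sucrose_observables(WT, protocol)
        assert obs["transient_vesicles"] < pool.steady_state_rrp(WT)

    def test_submaximal_transient_fraction_increases_with_nsuc(self):
        """The released fraction under a sub-maximal challenge grows with
        its fold-increase (lower barrier -> larger sub-maximal pool)."""
        def transient(n_suc):
            protocol = SucroseProtocol(onset_time=0.0, duration=5.0,
                                       n_suc=n_suc, exchange_time=0.05)
            return pool.expected_sucrose_observables(
                WT, protocol)["transient_vesicles"]

        ref = transient(5000.0)
        fracs = [transient(n) / ref for n in (50, 200, 1000, 5000)]
        assert np.all(np.diff(fracs) > 0)


class TestDecomposeRrpChange:
    def test_identical_conditions_give_zero(self):
        dec = pool.decompose_rrp_change(WT, WT)
        assert dec.total_log_ratio == 0.0
        assert all(abs(v) < 1e-12 for v in dec.contributions.values())

    def test_d166y_contributions_sum_to_total(self):
        wt2 = RateTriple(457.4, 0.1114, 0.000398)
        dec = pool.decompose_rrp_change(wt2, D166Y)
        total = math.log(
            pool.steady_state_rrp(D166Y) / pool.steady_state_rrp(wt2)
        )
        assert dec.total_log_ratio == pytest.approx(total, rel=1e-12)
        assert sum(dec.contributions.values()) == pytest.approx(total,
                                                                rel=1e-12)
        assert dec.total_ratio == pytest.approx(0.1425, abs=0.001)

    def test_pure_kf_change_lands_in_kf_term(self):
        ref = RateTriple(100.0, 0.1, 0.001)
        mut = RateTriple(100.0, 0.1, 0.05)
        dec = pool.decompose_rrp_change(ref, mut)
        assert dec.contributions["k1"] == 0.0
        assert dec.contributions["k_minus1"] == pytest.approx(0.0, abs=1e-12)
        assert dec.contributions["kf"] == pytest.approx(dec.total_log_ratio,
                                                        rel=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(ref=rate_triples, mut=rate_triples)
    def test_contributions_always_sum_exactly(self, ref, mut):
        dec = pool.decompose_rrp_change(ref, mut)
        assert sum(dec.contributions.values()) == pytest.approx(
            dec.total_log_ratio, abs=1e-9
        )
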