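import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import qsmemory as qs
from qsmemory import analytical as an

times = st.floats(min_value=0.0, max_value=2000.0, allow_nan=False)
fcs = st.floats(min_value=1.0, max_value=100.0, allow_nan=False)


class TestLuxIDecay:
    def test_starts_at_fold_change_times_off(self, analytical_params):
        assert an.luxi_decay(0.0, analytical_params) == pytest.approx(
            analytical_params.FC * analytical_params.I_OFF)

    def test_relaxes_to_off_level(self, analytical_params):
        assert an.luxi_decay(1e6, analytical_params) == pytest.approx(
            analytical_params.I_OFF, rel=1e-9)

    def test_half_life_value(self):
        p = qs.analytical_defaults(FC=10.0, gamma=0.017, beta_I=17.0)  # I_OFF = 1000 nM
        assert an.luxi_decay(math.log(2) / 0.017, p) == pytest.approx(5500.0)


class TestTotalLuxR:
    def test_starts_at_fold_change_times_off(self, analytical_params):
        assert an.total_luxr_decay(0.0, analytical_params) == pytest.approx(
            analytical_params.FC * analytical_params.R_OFF)

    def test_without_intrinsic_degradation_rate_equals_growth(self):
        p = qs.analytical_defaults(gamma_intrinsic=0.0)
        t = math.log(2) / p.gamma
        expected = p.R_OFF * (1 + (p.FC - 1) * 0.5)
        assert an.total_luxr_decay(t, p) == pytest.approx(expected, rel=1e-12)

    def test_half_life_value(self):
        p = qs.analytical_defaults()  # gamma_R = 0.018
        t = math.log(2) / 0.018
        assert an.total_luxr_decay(t, p) == pytest.approx(p.R_OFF * 5.5, rel=1e-9)


class TestMemoryTerms:
    def test_xi_limit_at_zero_is_fc_minus_one(self, analytical_params):
        assert an.xi(0.0, analytical_params) == pytest.approx(9.0)
        assert an.xi(1e-9, analytical_params) == pytest.approx(9.0, rel=1e-6)

    def test_xi_zero_for_unit_fold_change(self):
        p = qs.analytical_defaults(FC=1.0)
        assert np.all(an.xi(np.linspace(0, 700, 100), p) == 0.0)

    def test_xi_frozen_value(self):
        # gamma (FC-1) t / (e^{gamma t} - 1) at FC=10, gamma=0.017, t=100
        p = qs.analytical_defaults()
        assert an.xi(100.0, p) == pytest.approx(15.3 / (math.e ** 1.7 - 1),
                                                rel=1e-12)
        assert an.xi(100.0, p) == pytest.approx(3.4198, rel=1e-4)

    def test_theta_limits(self, analytical_params):
        assert an.theta(0.0, analytical_params) == pytest.approx(
            analytical_params.FC ** 2 - 1)  # (FC-1) + (FC-1) FC
        assert an.theta(5e4, analytical_params) == pytest.approx(0.0, abs=1e-9)
        assert np.all(an.theta(np.linspace(0, 700, 50), qs.analytical_defaults(FC=1.0)) == 0.0)

    @given(t=times, fc=fcs)
    def test_ordering_and_positivity(self, t, fc):
        p = qs.analytical_defaults(FC=fc)
        x, th = an.xi(t, p), an.theta(t, p)
        assert th >= x >= 0.0
        if fc > 1.0:
            assert x > 0.0

    @given(t=st.floats(min_value=0.0, max_value=1999.0), fc=fcs)
    def test_memory_terms_non_increasing(self, t, fc):
        p = qs.analytical_defaults(FC=fc)
        assert an.xi(t, p) >= an.xi(t + 1.0, p) - 1e-12
        assert an.theta(t, p) >= an.theta(t + 1.0, p) - 1e-12


class TestAccumulatedAhl:
    def test_zero_at_dilution(self, analytical_params):
        assert an.accumulated_ahl(0.0, analytical_params) == 0.0

    def test_unit_fold_change_reduces_to_naive_expression(self):
        p = qs.analytical_defaults(FC=1.0)
        t = np.linspace(0, 700, 20)
        assert np.allclose(an.accumulated_ahl(t, p, initially_on=True),
                           an.accumulated_ahl(t, p, initially_on=False),
                           rtol=1e-12)

    def test_closed_form_matches_quadrature_over_random_draws(self):
        """The closed form equals trapezoid quadrature of the production
        integrand v b I_OFF N_0 e^{gamma t} (1 + (FC-1) e^{-gamma t})."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = qs.analytical_defaults(
                gamma=rng.uniform(0.003, 0.05),
                gamma_intrinsic=rng.uniform(0.0, 0.2),
                FC=rng.uniform(1.0, 50.0),
                b=rng.uniform(0.005, 0.2),
                beta_I=rng.uniform(1.0, 100.0),
                N_0=10 ** rng.uniform(5, 9),
            )
            t_end = rng.uniform(50.0, 700.0)
            tq = np.linspace(0.0, t_end, 100_001)
            integrand = (p.v_cell * p.b * p.I_OFF * p.N_0 * np.exp(p.gamma * tq)
                         * (1.0 + (p.FC - 1.0) * np.exp(-p.gamma * tq)))
            quad = np.trapezoid(integrand, tq)
            closed = an.accumulated_ahl(t_end, p)
            assert closed == pytest.approx(quad, rel=1e-8)

    def test_memory_form_factorises_through_xi(self, analytical_params):
        t = np.linspace(1.0, 700.0, 13)
        basal = an.accumulated_ahl(t, analytical_params, initially_on=False)
        on = an.accumulated_ahl(t, analytical_params, initially_on=True)
        assert np.allclose(on, basal * (1.0 + an.xi(t, analytical_params)), rtol=1e-12)


class TestBindingRate:
    def test_zero_at_dilution(self, analytical_params):
        assert an.binding_rate(0.0, analytical_params) == 0.0

    def test_naive_rate_monotone_increasing(self):
        r = an.binding_rate(np.linspace(0, 700, 2000), qs.analytical_defaults(FC=1.0))
        assert np.all(np.diff(r) > 0)

    def test_memory_rate_monotone_once_the_transient_has_passed(self):
        """The initially-ON rate can dip while the memory term decays faster
        than growth accelerates, but is increasing once growth dominates."""
        for fc in (3.0, 10.0, 30.0):
            r = an.binding_rate(np.linspace(300, 700, 500), qs.analytical_defaults(FC=fc))
            assert np.all(np.diff(r) > 0)

    @given(t=st.floats(min_value=1.0, max_value=700.0), fc=fcs)
    def test_memory_never_slows_binding(self, t, fc):
        p = qs.analytical_defaults(FC=fc)
        on = an.binding_rate(t, p, initially_on=True)
        off = an.binding_rate(t, p, initially_on=False)
        assert on >= off
        if fc > 1.001:
            assert on > off


class TestActivationTimes:
    def test_overdiluted_naive_cells_activate_at_the_known_time(self):
        p = qs.analytical_defaults(FC=1.0, N_0=1e6)
        t = an.activation_time_numeric(p, initially_on=False)
        assert t == pytest.approx(532.0, abs=1.0)

    def test_memory_accelerates_activation(self, analytical_params):
        t_on = an.activation_time_numeric(analytical_params, initially_on=True)
        t_off = an.activation_time_numeric(analytical_params, initially_on=False)
        assert t_on < t_off

    def test_short_horizon_never_activates(self):
        p = qs.analytical_defaults(N_0=1e6, horizon=100.0)
        assert an.activation_time_numeric(p, initially_on=False) is None

    def test_approximation_matches_numeric_under_overdilution(self):
        """Within the over-dilution regime (N_0 <= N_C/100) the closed-form
        activation time is within 5% of the root of the step condition."""
        for n0 in (1e5, 1e6, 1e7, 8.5e7):
            p = qs.analytical_defaults(FC=1.0, N_0=n0, horizon=2000.0)
            assert n0 <= an.critical_density_off(p) / 100 * 1.01
            t_num = an.activation_time_numeric(p, initially_on=False)
            t_approx = an.activation_time_approx(p)
            assert abs(t_approx / t_num - 1.0) <= 0.05

    def test_approx_log_arithmetic(self, analytical_params):
        p = analytical_params.with_(N_0=1e6)
        t1 = an.activation_time_approx(p)
        t2 = an.activation_time_approx(p.with_(A_thresh=10.0))
        assert t1 - t2 == pytest.approx(math.log(2) / p.gamma, rel=1e-9)
        assert an.activation_time_approx(p.with_(b=0.08)) < t1

    def test_approx_invalid_when_not_overdiluted(self):
        with pytest.raises(ValueError, match="invalid"):
            an.activation_time_approx(qs.analytical_defaults(N_0=1e11))


class TestCriticalDensities:
    def test_naive_critical_density_closed_form(self):
        p = qs.analytical_defaults(N_0=1e8)
        # gamma A / (v b I_OFF) + N_0 = 0.34/4e-11 + 1e8
        assert an.critical_density_off(p) == pytest.approx(8.6e9, rel=1e-9)

    def test_overdilution_limit(self):
        p = qs.analytical_defaults(N_0=1.0)
        k = p.gamma * p.A_thresh / (p.v_cell * p.b * p.I_OFF)
        assert an.critical_density_off(p) == pytest.approx(k, rel=1e-6)

    def test_consistent_with_activation_time(self):
        p = qs.analytical_defaults(FC=1.0, N_0=1e6, horizon=2000.0)
        t_act = an.activation_time_numeric(p, initially_on=False)
        assert p.N_0 * math.exp(p.gamma * t_act) == pytest.approx(
            an.critical_density_off(p), rel=1e-3)

    def test_unit_fold_change_gives_no_memory(self):
        p = qs.analytical_defaults(FC=1.0)
        assert an.critical_density_on(p) == pytest.approx(
            an.critical_density_off(p), rel=1e-4)

    def test_memory_lowers_the_critical_density(self, analytical_params):
        assert an.critical_density_on(analytical_params) < \
            an.critical_density_off(analytical_params)

    def test_implicit_and_root_routes_agree(self):
        for fc in (2.0, 5.0, 10.0):
            for n0 in (1e7, 1e8):
                p = qs.analytical_defaults(FC=fc, N_0=n0)
                a = an.critical_density_on(p)
                b = an.critical_density_on_implicit(p)
                assert abs(a / b - 1.0) <= 1e-3


class TestMemoryZoneWidth:
    def test_zero_for_unit_fold_change(self):
        assert an.memory_zone_width(qs.analytical_defaults(FC=1.0)) == pytest.approx(0.0, abs=1e-6)

    def test_two_routes_agree(self, analytical_params):
        w1 = an.memory_zone_width(analytical_params)
        w2 = (an.critical_density_off(analytical_params)
              - an.critical_density_on(analytical_params))
        assert abs(w1 / w2 - 1.0) <= 1e-3

    def test_bounded_by_the_saturation_width(self):
        for fc in (1.0, 2.0, 10.0, 50.0):
            p = qs.analytical_defaults(FC=fc)
            k = p.gamma * p.A_thresh / (p.v_cell * p.b * p.I_OFF)
            assert 0.0 <= an.memory_zone_width(p) < k

    def test_zero_when_no_activation_in_horizon(self):
        p = qs.analytical_defaults(N_0=1e6, horizon=100.0)
        assert an.memory_zone_width(p) == 0.0

    @staticmethod
    def _log_width(p):
        ncp = an.critical_density_on(p)
        if ncp is None:
            return 0.0
        return math.log10(an.critical_density_off(p)) - math.log10(ncp)

    def test_zone_widens_with_fold_change(self):
        widths = [self._log_width(qs.analytical_defaults(FC=fc)) for fc in (1, 2, 4, 6, 8, 10)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_zone_widens_with_synthesis_rate(self):
        widths = [self._log_width(qs.analytical_defaults(b=b)) for b in (0.01, 0.02, 0.04, 0.1)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_zone_contracts_with_activation_threshold(self):
        widths = [self._log_width(qs.analytical_defaults(A_thresh=a)) for a in (10, 20, 40, 100)]
        assert all(b <= a for a, b in zip(widths, widths[1:]))


class TestPhaseDiagram:
    def test_fold_change_diagram_shows_all_regions(self, analytical_params):
        diag = an.phase_diagram(analytical_params, "FC", (1.0, 10.0), n_axis=19)
        assert diag.has_region("I") and diag.has_region("II") and \
            diag.has_region("III")

    def test_memory_region_grows_with_fold_change(self, analytical_params):
        diag = an.phase_diagram(analytical_params, "FC", (1.0, 10.0), n_axis=19)
        w = diag.zone_width_log10()
        assert w[0] == 0.0
        assert all(b >= a - 1e-12 for a, b in zip(w, w[1:]))

    def test_unit_fold_change_has_no_memory_region(self, analytical_params):
        diag = an.phase_diagram(analytical_params, "FC", (1.0, 1.0), n_axis=1)
        assert not diag.has_region("II")

    def test_overdilution_closes_the_memory_region(self, analytical_params):
        diag = an.phase_diagram(analytical_params.with_(N_0=1e6), "FC", (1.0, 10.0),
                                n_axis=19)
        assert not diag.has_region("II")

    def test_doubling_time_diagram(self, analytical_params):
        # widening holds until the lower boundary reaches the N_0 floor
        diag = an.phase_diagram(analytical_params, "doubling_time", (20.0, 60.0),
                                n_axis=13)
        w = diag.zone_width_log10()
        assert all(b >= a - 1e-12 for a, b in zip(w, w[1:]))
        nc = diag.boundaries[:, 1]
        assert all(b <= a for a, b in zip(nc, nc[1:])), \
            "higher doubling time must lower the critical density"

    def test_threshold_diagram(self, analytical_params):
        diag = an.phase_diagram(analytical_params, "A_thresh", (10.0, 100.0),
                                n_axis=10)
        nc = diag.boundaries[:, 1]
        assert all(b >= a for a, b in zip(nc, nc[1:]))
        w = diag.zone_width_log10()
        assert all(b <= a + 1e-12 for a, b in zip(w, w[1:]))

    def test_invalid_axis_rejected(self, analytical_params):
        with pytest.raises(ValueError, match="axis"):
            an.phase_diagram(analytical_params, "colour", (0.0, 1.0))
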