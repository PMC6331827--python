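"""Reactor marching: streamline closed form, mixing, recirculation balance."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from cpc_photokin.kinetics import KineticParameters
from cpc_photokin.radiation import vrpa_per_length, vrpa_total
from cpc_photokin.reactor import (
    geometry_factor,
    mixing_cup_average,
    recirculation_run,
    single_pass,
    streamline_exit_toc,
    to_local_constant,
    to_lumped_constant,
)


class TestStreamline:
    def test_dark_core_identity(self):
        p = KineticParameters(k_t=1e-4, k_r=0.07)
        assert streamline_exit_toc(213.6, 0.6, 0.0, 0.12, p) == 213.6

    def test_matches_runge_kutta_oracle(self):
        """Closed form vs fine RK integration of the frozen-denominator
        balance, to 1e-8 relative."""
        p = KineticParameters(k_t=2.7e-4, k_r=7.386e-2, m_exp=0.5)
        toc_in, v_z, lvrpa, l_j = 213.6, 0.55, 1900.0, 0.12

        def rhs(z, c):
            return -p.k_t * p.k_r * lvrpa**0.5 * c / (v_z * (1 + p.k_r * toc_in))

        sol = solve_ivp(rhs, (0, l_j), [toc_in], rtol=1e-11, atol=1e-12)
        ours = streamline_exit_toc(toc_in, v_z, lvrpa, l_j, p)
        assert ours == pytest.approx(sol.y[0, -1], rel=1e-8)
        assert ours <= toc_in

    def test_wall_velocity_rejected(self):
        p = KineticParameters(k_t=1e-4, k_r=0.07)
        with pytest.raises(ValueError):
            streamline_exit_toc(200.0, 0.0, 100.0, 0.12, p)


class TestMixingCup:
    @pytest.fixture()
    def setup(self, paper_setup):
        spec, field = paper_setup
        r = field.r_nodes[:, None] * np.ones((1, len(field.theta_nodes)))
        v_z = spec.flow.profile(r)
        return spec, field, r, v_z

    def test_uniform_field_exact(self, setup):
        spec, field, r, v_z = setup
        c = np.full_like(v_z, 123.4)
        assert mixing_cup_average(c, v_z, field.weights, spec.flow.q) == pytest.approx(
            123.4, rel=1e-12
        )

    def test_zero_field(self, setup):
        spec, field, r, v_z = setup
        assert mixing_cup_average(np.zeros_like(v_z), v_z, field.weights,
                                  spec.flow.q) == 0.0

    def test_wall_depleted_field_vs_brute_force(self, setup):
        """TOC depleted near the slow wall: flow weighting must raise the
        mean above the plain area mean; values agree with a fine 1-D
        quadrature oracle to 0.5%."""
        spec, field, r, v_z = setup
        radius = spec.geometry.tube_radius
        c_of_r = lambda rr: 200.0 - 80.0 * (rr / radius) ** 4
        c = c_of_r(r)
        ours = mixing_cup_average(c, v_z, field.weights, spec.flow.q)
        num = quad(lambda rr: c_of_r(rr) * spec.flow.profile(rr) * rr, 0, radius,
                   limit=200)[0]
        den = quad(lambda rr: spec.flow.profile(rr) * rr, 0, radius, limit=200)[0]
        oracle = num / den
        assert ours == pytest.approx(oracle, rel=5e-3)
        area_mean = float(np.sum(c * field.weights) / field.weights.sum())
        assert ours > area_mean

    def test_inconsistent_flow_rejected(self, setup):
        spec, field, r, v_z = setup
        with pytest.raises(ValueError, match="1%"):
            mixing_cup_average(np.ones_like(v_z), v_z, field.weights,
                               spec.flow.q * 1.5)


class TestSinglePass:
    def test_zero_rate_identity_any_discretisation(self, paper_setup, zero_field):
        spec, _ = paper_setup
        p = KineticParameters(k_t=1e-4, k_r=0.07)
        from dataclasses import replace

        for n_sub in (1, 100):
            s = replace(spec, n_subreactors=n_sub)
            assert single_pass(213.6, s, zero_field, p) == pytest.approx(
                213.6, rel=1e-14
            )

    def test_subreactor_convergence(self, coarse_setup, params_paper, kt_calibrated):
        """Doubling the axial resolution changes the exit by < 0.1%."""
        from dataclasses import replace

        spec, field = coarse_setup
        p_loc = to_local_constant(
            KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r),
            field, spec.geometry.total_length,
        )
        removals = []
        for n_sub in (100, 200):
            s = replace(spec, n_subreactors=n_sub)
            out = single_pass(213.6, s, field, p_loc)
            removals.append(213.6 - out)
        assert removals[0] == pytest.approx(removals[1], rel=1e-3)

    def test_matches_method_of_lines_oracle(self, coarse_setup, params_paper,
                                            kt_calibrated):
        """Full 2-D (r,theta,z) integration without the per-segment
        linearisation agrees within 1% on the pass removal."""
        spec, field = coarse_setup
        p = to_local_constant(
            KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r),
            field, spec.geometry.total_length,
        )
        r = field.r_nodes[:, None] * np.ones((1, len(field.theta_nodes)))
        v_z = spec.flow.profile(r).ravel()
        lv = field.values.ravel() ** p.m_exp
        toc_in = 213.6

        def rhs(z, c):
            return -p.k_t * p.k_r * lv * c / (v_z * (1 + p.k_r * c))

        sol = solve_ivp(rhs, (0, spec.geometry.total_length),
                        np.full(v_z.size, toc_in), rtol=1e-10, atol=1e-10)
        exit_nodes = sol.y[:, -1].reshape(field.values.shape)
        oracle = mixing_cup_average(exit_nodes, spec.flow.profile(
            field.r_nodes[:, None] * np.ones((1, len(field.theta_nodes)))),
            field.weights, spec.flow.q)
        ours = single_pass(toc_in, spec, field, p)
        assert (toc_in - ours) == pytest.approx(toc_in - oracle, rel=1e-2)


class TestRecirculation:
    def test_mass_conservation_zero_rate(self, paper_setup, zero_field):
        """Dark run: the tank concentration is conserved to 1e-12 over
        120+ passes."""
        spec, _ = paper_setup
        p = KineticParameters(k_t=1e-3, k_r=0.07)
        sim = recirculation_run(213.6, 42.0, spec, zero_field, p,
                                convention="local")
        assert sim.n_pass > 100
        np.testing.assert_allclose(sim.toc_tank_ppm, 213.6, rtol=1e-12)

    def test_pass_count_arithmetic(self, paper_setup, zero_field):
        """30.2 L/min for 42 min through 10.26 L: 123.6 passes."""
        spec, _ = paper_setup
        p = KineticParameters(k_t=1e-3, k_r=0.07)
        sim = recirculation_run(213.6, 42.0, spec, zero_field, p,
                                convention="local")
        assert sim.n_pass == pytest.approx(123.58, abs=0.05)
        assert len(sim.pass_exit_toc_ppm) == 124  # 123 full + 1 partial
        floor = recirculation_run(213.6, 42.0, spec, zero_field, p,
                                  convention="local", fractional="floor")
        assert len(floor.pass_exit_toc_ppm) == 123

    def test_monotone_and_positive(self, coarse_setup, params_paper, kt_calibrated):
        spec, field = coarse_setup
        p = KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r)
        sim = recirculation_run(213.6, 42.0, spec, field, p)
        assert np.all(np.diff(sim.toc_tank_ppm) <= 0)
        assert np.all(sim.toc_tank_ppm > 0)

    def test_more_photons_more_removal(self, coarse_setup, params_paper,
                                       kt_calibrated):
        spec, field = coarse_setup
        p = to_local_constant(
            KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r),
            field, spec.geometry.total_length,
        )
        bright = field.copy_with(field.values * 2.0)
        low = recirculation_run(213.6, 42.0, spec, field, p, convention="local")
        high = recirculation_run(213.6, 42.0, spec, bright, p, convention="local")
        assert high.removal_fraction() > low.removal_fraction()

    def test_first_order_limit(self, coarse_setup):
        """K_R*TOC << 1: the tank trajectory approaches a single exponential
        with rate k_T*K_R*sqrt(VRPA)/V_T."""
        spec, field = coarse_setup
        p = KineticParameters(k_t=0.01, k_r=1e-4)
        sim = recirculation_run(10.0, 42.0, spec, field, p)
        vrpa = vrpa_total(vrpa_per_length(field), spec.geometry.total_length)
        rate = p.k_t * p.k_r * math.sqrt(vrpa) / spec.v_t  # 1/s
        expected = 10.0 * math.exp(-rate * 42.0 * 60.0)
        assert sim.final_toc == pytest.approx(expected, rel=5e-3)

    def test_zero_order_limit(self, coarse_setup):
        """K_R*TOC >> 1: linear decay at k_T*sqrt(VRPA)/V_T."""
        spec, field = coarse_setup
        p = KineticParameters(k_t=4.3e-4, k_r=10.0)
        sim = recirculation_run(300.0, 42.0, spec, field, p)
        vrpa = vrpa_total(vrpa_per_length(field), spec.geometry.total_length)
        expected = 300.0 - p.k_t * math.sqrt(vrpa) / spec.v_t * 42.0 * 60.0
        assert p.k_r * sim.final_toc > 100  # still deep in saturation
        assert sim.final_toc == pytest.approx(expected, rel=5e-3)

    def test_percent_removal_decreases_with_toc0(self, coarse_setup, params_paper,
                                                 kt_calibrated):
        """Fixed time, rising initial TOC: percent removal strictly falls
        (the observed 31.1% > 16.9% > 14.6% pattern)."""
        spec, field = coarse_setup
        p = KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r)
        removals = [
            recirculation_run(c0, 42.0, spec, field, p).removal_fraction()
            for c0 in (213.6, 328.0, 433.0)
        ]
        assert removals[0] > removals[1] > removals[2]

    def test_initial_tank_rate_matches_lumped_law(self, coarse_setup, params_paper,
                                                  kt_calibrated):
        """Convention consistency: the detailed simulation's initial tank
        rate reproduces the lumped V_T*d[TOC]/dt = -k_T K_R C/(1+K_R C)
        *sqrt(VRPA) law it was converted from."""
        spec, field = coarse_setup
        p = KineticParameters(k_t=kt_calibrated, k_r=params_paper.k_r)
        sim = recirculation_run(213.6, 42.0, spec, field, p)
        dt_s = (sim.t30w_min[1] - sim.t30w_min[0]) * 60.0
        sim_rate = (sim.toc_tank_ppm[0] - sim.toc_tank_ppm[1]) / dt_s * spec.v_t
        vrpa = vrpa_total(vrpa_per_length(field), spec.geometry.total_length)
        law = p.k_t * p.k_r * 213.6 / (1 + p.k_r * 213.6) * math.sqrt(vrpa)
        assert sim_rate == pytest.approx(law, rel=2e-2)

    def test_conversion_roundtrip(self, coarse_setup, params_paper):
        spec, field = coarse_setup
        back = to_lumped_constant(
            to_local_constant(params_paper, field, spec.geometry.total_length),
            field, spec.geometry.total_length,
        )
        assert back.k_t == pytest.approx(params_paper.k_t, rel=1e-12)

    def test_bad_arguments(self, paper_setup, zero_field):
        spec, _ = paper_setup
        p = KineticParameters(k_t=1e-3, k_r=0.07)
        with pytest.raises(ValueError):
            recirculation_run(-5.0, 42.0, spec, zero_field, p, convention="local")
        with pytest.raises(ValueError):
            recirculation_run(213.6, 0.0, spec, zero_field, p, convention="local")
        with pytest.raises(ValueError):
            recirculation_run(213.6, 42.0, spec, zero_field, p, convention="bogus")
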