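"""Travel times, extraction, apex-angle relations, tau estimation."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from chorioflow.geometry import Opening, OpeningConfiguration
from chorioflow.transport import (
    TravelTimeDistribution,
    apex_angle_regular,
    estimate_tau,
    integrate_streamline,
    mass_extraction,
    shape_extraction_scan,
    travel_time_distribution,
    triangular_portion_travel_times,
)


def _atom_distribution(T0: float, n: int = 16) -> TravelTimeDistribution:
    """Degenerate distribution with every travel time equal to T0."""
    return TravelTimeDistribution(
        arteriole_id=0,
        theta=np.linspace(0, 2 * math.pi, n, endpoint=False),
        travel_times=np.full(n, T0),
        terminal_ids=np.ones(n, dtype=int),
        t_max=10 * T0,
        q_a=2 * math.pi,
    )


class TestIntegrateStreamline:
    def test_isolated_source_radial_closed_form(self):
        # u = k/r for a lone source: T(rim -> r_stop) = (r^2 - a^2)/2
        a = 1e-3
        cfg = OpeningConfiguration(
            (Opening(0, "arteriolar", 0, 0, 1.0, a),),
            domain="plane_with_infinity",
        )
        path = integrate_streamline(cfg, 0, theta=0.3, r_stop=1.0)
        assert path.terminal == ("radius", 1.0)
        assert path.travel_time == pytest.approx(0.5 * (1 - a**2), rel=1e-6)

    def test_release_along_separatrix_truncates(self, two_sources):
        # aimed straight at the saddle between the two sources
        path = integrate_streamline(two_sources, 0, theta=0.0, t_max=20.0)
        assert path.truncated
        assert path.travel_time == pytest.approx(20.0, rel=1e-6)

    def test_dipole_axis_matches_quadrature_oracle(self, dipole):
        a = dipole.opening(0).radius
        path = integrate_streamline(dipole, 0, theta=0.0, t_max=50.0)
        assert path.terminal == ("opening", 1)
        # independent 1-D oracle: on the axis |u| = |1/(x+1) - 1/(x-1)|
        start = -1 + 1.0001 * a

        def inv_speed(x):
            return 1.0 / abs(1.0 / (x + 1.0) - 1.0 / (x - 1.0))

        T_ref, _ = quad(inv_speed, start, 1 - a, epsabs=1e-12, epsrel=1e-12)
        assert path.travel_time == pytest.approx(T_ref, rel=1e-5)

    def test_release_must_be_arteriolar(self, dipole):
        with pytest.raises(ValueError):
            integrate_streamline(dipole, 1, theta=0.0)


class TestTravelTimeDistribution:
    def test_identical_seeds_identical_samples(self, square_lattice,
                                               central_square_segment):
        d1 = travel_time_distribution(square_lattice, central_square_segment,
                                      n_particles=300, seed=9)
        d2 = travel_time_distribution(square_lattice, central_square_segment,
                                      n_particles=300, seed=9)
        np.testing.assert_array_equal(d1.travel_times, d2.travel_times)
        np.testing.assert_array_equal(d1.theta, d2.theta)

    def test_mean_matches_residence_time(self, square_lattice,
                                         central_square_segment):
        # flux-weighted <T> = perfused volume / inflow = A_0 / Q_a here
        d = travel_time_distribution(square_lattice, central_square_segment,
                                     n_particles=4000, seed=4)
        expect = central_square_segment.area_0 / d.q_a
        assert abs(d.mean - expect) <= 3 * d.se_mean

    def test_right_skew_near_separatrix(self, square_lattice,
                                        central_square_segment):
        d = travel_time_distribution(square_lattice, central_square_segment,
                                     n_particles=2000, seed=5)
        assert d.travel_times.max() > 5 * np.median(d.travel_times)

    def test_minimum_sample_size(self, square_lattice, central_square_segment):
        with pytest.raises(ValueError):
            travel_time_distribution(square_lattice, central_square_segment,
                                     n_particles=50)


class TestMassExtraction:
    def test_degenerate_atom(self):
        d = _atom_distribution(0.5)
        res = mass_extraction(d, tau=2.0)
        assert res.eta_exact == pytest.approx(1.0 - math.exp(-0.25), rel=1e-12)

    def test_small_tau_limit_full_extraction(self):
        d = _atom_distribution(1.0)
        assert mass_extraction(d, tau=1e-4).eta_exact == pytest.approx(1.0)

    def test_monotone_decreasing_in_tau(self):
        rng = np.random.default_rng(0)
        d = _atom_distribution(1.0)
        d.travel_times[:] = rng.lognormal(0.0, 0.6, d.n)
        etas = [mass_extraction(d, tau=t).eta_exact
                for t in (0.5, 1.0, 2.0, 5.0, 20.0)]
        assert etas == sorted(etas, reverse=True)

    def test_stochastic_dominance_in_travel_times(self):
        rng = np.random.default_rng(1)
        d = _atom_distribution(1.0)
        d.travel_times[:] = rng.lognormal(0.0, 0.5, d.n)
        d_slow = _atom_distribution(1.0)
        d_slow.travel_times[:] = d.travel_times * 1.2
        assert mass_extraction(d_slow, 3.0).eta_exact \
            > mass_extraction(d, 3.0).eta_exact

    def test_posts_rescale_travel_times(self):
        d = _atom_distribution(1.0)
        res = mass_extraction(d, tau=2.0, phi=0.3)
        assert res.eta_exact == pytest.approx(1 - math.exp(-0.7 / 2.0))
        assert res.mean_travel_time == pytest.approx(0.7)

    def test_invalid_arguments(self):
        d = _atom_distribution(1.0)
        with pytest.raises(ValueError):
            mass_extraction(d, tau=0.0)
        with pytest.raises(ValueError):
            mass_extraction(d, tau=1.0, phi=1.0)

    def test_asymptotic_branch_within_one_percent(self, square_lattice,
                                                  central_square_segment):
        d = travel_time_distribution(square_lattice, central_square_segment,
                                     n_particles=2000, seed=6)
        res = mass_extraction(d, tau=100.0 * d.mean)
        gap = abs(res.eta_exact - res.eta_asymptotic) / res.eta_exact
        assert gap <= 0.01
        # the dispersion correction strictly shrinks the gap
        gap_leading = abs(res.eta_exact - res.eta_leading) / res.eta_exact
        assert gap < gap_leading


class TestApexAngle:
    @pytest.mark.parametrize("n,omega", [(3, 2 * math.pi / 3),
                                         (4, math.pi / 2),
                                         (6, math.pi / 3)])
    def test_regular_polygon_values(self, n, omega):
        assert apex_angle_regular(n) == pytest.approx(omega, rel=1e-12)

    def test_decreasing_in_sides(self):
        vals = [apex_angle_regular(n) for n in range(3, 12)]
        assert vals == sorted(vals, reverse=True)

    def test_minimum_three_sides(self):
        with pytest.raises(ValueError):
            apex_angle_regular(2)


class TestTriangularPortion:
    @pytest.mark.parametrize("omega", [math.pi / 3, math.pi / 2,
                                       2 * math.pi / 3])
    def test_mean_matches_portion_area_over_flow(self, omega):
        d = triangular_portion_travel_times(omega, n_particles=600, seed=2)
        expect = 0.5 * math.sin(omega) / d.q_a
        assert abs(d.mean - expect) <= max(3 * d.se_mean, 2e-3 * expect)

    def test_determinism(self):
        d1 = triangular_portion_travel_times(1.0, n_particles=200, seed=3)
        d2 = triangular_portion_travel_times(1.0, n_particles=200, seed=3)
        np.testing.assert_array_equal(d1.travel_times, d2.travel_times)


class TestShapeExtractionScan:
    def test_square_is_the_optimum(self):
        omegas = np.linspace(0.2 * math.pi, 0.8 * math.pi, 13)
        curve = shape_extraction_scan(omegas, tau=50.0, n_particles=400,
                                      seed=0)
        assert curve.argmax_omega == pytest.approx(math.pi / 2,
                                                   abs=omegas[1] - omegas[0])

    def test_eta_in_unit_interval_over_physiological_tau_band(self):
        # tau band 0.2e5 - 1e5 s, nondimensionalised by L/U = 0.6 s
        ts = 600e-6 / 1.0e-3
        omegas = np.array([math.pi / 3, math.pi / 2, 2 * math.pi / 3])
        for tau_s in (0.2e5, 1.0e5):
            curve = shape_extraction_scan(omegas, tau=tau_s / ts,
                                          n_particles=200, seed=1)
            assert ((curve.eta > 0) & (curve.eta < 1)).all()

    def test_smoothness_of_the_curve(self):
        omegas = np.linspace(0.25 * math.pi, 0.75 * math.pi, 41)
        curve = shape_extraction_scan(omegas, tau=50.0, n_particles=400,
                                      seed=2)
        rel_steps = np.abs(np.diff(curve.eta)) / curve.eta[:-1]
        assert (rel_steps < 0.05).all()

    def test_omega_out_of_range(self):
        with pytest.raises(ValueError):
            shape_extraction_scan([0.0, 1.0], tau=1.0)


class TestEstimateTau:
    def test_inverse_proportionality_at_leading_order(self):
        t1 = estimate_tau((0.01, 0.01001), 0.118)
        t2 = estimate_tau((0.02, 0.02001), 0.118)
        assert t2.tau_seconds[0] == pytest.approx(t1.tau_seconds[0] / 2,
                                                  rel=0.02)

    def test_round_trip_consistency(self):
        est = estimate_tau((0.01, 0.05), 0.118, U=1e-3, L=600e-6)
        ts = 600e-6 / 1e-3
        T_dimless = 0.118 / ts
        for tau_s, eta_target in zip(est.tau_seconds, (0.05, 0.01)):
            d = _atom_distribution(T_dimless)
            res = mass_extraction(d, tau=tau_s / ts)
            assert res.eta_exact == pytest.approx(eta_target, rel=0.03)

    def test_rejects_unphysical_extraction(self):
        with pytest.raises(ValueError):
            estimate_tau((0.5, 1.0), 0.118)
        with pytest.raises(ValueError):
            estimate_tau((0.01, 0.05), -1.0)
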