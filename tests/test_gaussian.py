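"""Gaussian fluctuating-membrane model: covariance, probabilities, NSE."""

import math

import numpy as np
import pytest

from memsas import rbc
from memsas.gaussian import (GaussianMembraneParams, bvn_cdf, gaussian_intensity,
                             gw_covariance, layer_probabilities,
                             membrane_correlation, nse_curve, roughness_factor)
from memsas.profiles import ValidationError, slab_amplitude
from memsas.slab import slab_intensity


class TestGwCovariance:
    def test_unit_normalization_at_origin(self, gauss_params):
        assert float(gw_covariance(0.0, 0.0, gauss_params)) == 1.0

    def test_static_limit_time_independent(self):
        g = GaussianMembraneParams(23.0, 63.0, 0.0)
        r = np.linspace(0.0, 300.0, 50)
        assert np.allclose(gw_covariance(r, 0.0, g), gw_covariance(r, 500.0, g))

    def test_amplitude_decay_and_broadening(self):
        g = GaussianMembraneParams(23.0, 63.0, 1.85)
        assert float(gw_covariance(0.0, 500.0, g)) == pytest.approx(
            1.0 / (1.0 + 1.85 * 500.0 / 63.0**2), rel=1e-12)

    def test_matches_diffusing_packet_simulation(self):
        """Empirical space-time correlation of randomly signed Gaussian wave
        packets whose centres diffuse (periodic box, FFT-free direct sums)."""
        g = GaussianMembraneParams(1.0, 63.0, 1.85)
        L, n = 1024.0, 96
        dx = L / n
        lag = 8  # 85 A
        taus = [0.0, 300.0]
        x = (np.arange(n) + 0.5) * dx
        stats = {t: ([], []) for t in taus}
        var0 = []
        for s in range(25):
            rng = np.random.default_rng(500 + s)
            N = rng.poisson(55)
            pos = rng.uniform(0, L, (N, 2))
            sign = rng.choice([-1.0, 1.0], N)

            def field(pos):
                f = np.zeros((n, n))
                for (cx, cy), sg in zip(pos, sign):
                    ddx = (x - cx + L / 2) % L - L / 2
                    ddy = (x - cy + L / 2) % L - L / 2
                    f += sg * np.exp(-(ddx[:, None] ** 2 + ddy[None, :] ** 2)
                                     / (2 * 63.0**2))
                return f

            f0 = field(pos)
            var0.append((f0 * f0).mean())
            prev = 0.0
            for t in taus:
                if t > prev:
                    pos = (pos + rng.normal(0, math.sqrt(2 * g.D * (t - prev)),
                                            (N, 2))) % L
                prev = t
                ft = field(pos)
                stats[t][0].append((f0 * ft).mean())
                stats[t][1].append((f0 * np.roll(ft, lag, axis=0)).mean())
        v0 = np.mean(var0)
        for t in taus:
            for vals, r_lag in zip(stats[t], (0.0, lag * dx)):
                emp = np.mean(vals) / v0
                se = np.std(vals, ddof=1) / v0 / math.sqrt(len(vals))
                th = float(gw_covariance(r_lag, t, g))
                assert abs(emp - th) < 3 * se + 0.01


class TestBivariateNormal:
    def test_against_scipy_reference(self):
        from scipy.stats import multivariate_normal
        rng = np.random.default_rng(0)
        for _ in range(25):
            h, k = rng.normal(0, 1.5, 2)
            rho = rng.uniform(-0.999, 0.999)
            ref = multivariate_normal(mean=[0, 0],
                                      cov=[[1, rho], [rho, 1]]).cdf([h, k])
            assert float(bvn_cdf(h, k, rho)) == pytest.approx(ref, abs=1e-8)

    def test_degenerate_correlations(self):
        from scipy.special import ndtr
        assert float(bvn_cdf(0.3, 0.8, 1.0)) == pytest.approx(ndtr(0.3), abs=1e-12)
        assert float(bvn_cdf(0.3, -0.1, -1.0)) == pytest.approx(
            max(0.0, ndtr(0.3) + ndtr(-0.1) - 1), abs=1e-12)

    def test_origin_closed_form(self):
        assert float(bvn_cdf(0.0, 0.0, 0.5)) == pytest.approx(
            0.25 + math.asin(0.5) / (2 * math.pi), rel=1e-12)


class TestLayerProbabilities:
    def test_joint_distribution_sums_to_one(self, neutron_bilayer, gauss_params):
        stack = neutron_bilayer.to_stack()
        for z1, z2, r, tau in [(0.0, 3.0, 10.0, 0.0), (-30.0, 12.0, 100.0, 50.0)]:
            p1, p2, P = layer_probabilities(stack, gauss_params, z1, z2, r, tau,
                                            include_solvent=True)
            assert p1.sum() == pytest.approx(1.0, abs=1e-9)
            assert p2.sum() == pytest.approx(1.0, abs=1e-9)
            assert P.sum() == pytest.approx(1.0, abs=1e-8)
            assert np.all(P >= -1e-12)

    def test_rigid_limit_is_indicator(self, neutron_bilayer):
        g = GaussianMembraneParams(0.0, 63.0)
        stack = neutron_bilayer.to_stack()  # H|C|C|H, boundaries +-21.3, +-16.3, 0
        p1, _, P = layer_probabilities(stack, g, 10.0, 10.0, 0.0)
        assert np.array_equal(p1, np.array([0.0, 0.0, 1.0, 0.0]))
        assert np.array_equal(P, np.outer(p1, p1))

    def test_decorrelation_at_large_distance(self, neutron_bilayer, gauss_params):
        stack = neutron_bilayer.to_stack()
        p1, p2, P = layer_probabilities(stack, gauss_params, 2.0, -5.0, 1e5, 0.0,
                                        include_solvent=True)
        assert np.allclose(P, np.outer(p1, p2), atol=1e-9)

    def test_full_correlation_collapses_to_diagonal(self, neutron_bilayer,
                                                    gauss_params):
        stack = neutron_bilayer.to_stack()
        p1, _, P = layer_probabilities(stack, gauss_params, 4.0, 4.0, 0.0, 0.0,
                                       include_solvent=True)
        assert np.allclose(np.diag(P), p1, atol=1e-9)
        assert np.abs(P - np.diag(np.diag(P))).max() < 1e-9


class TestMembraneCorrelation:
    def test_rigid_limit_matches_slab_self_convolution(self, neutron_bilayer):
        g = GaussianMembraneParams(0.0, 63.0)
        stack = neutron_bilayer.to_stack()
        C_avg, C_fl = membrane_correlation(stack, g, 5.0, 0.0)
        assert C_fl == 0.0
        z = np.linspace(-30, 30, 60001)
        prof = stack.sld_profile(z) - stack.solvent_sld
        prof2 = stack.sld_profile(z + 5.0) - stack.solvent_sld
        assert C_avg == pytest.approx(np.trapezoid(prof * prof2, z), rel=1e-3)

    def test_fluctuation_part_decorrelates_laterally(self, neutron_bilayer,
                                                     gauss_params):
        stack = neutron_bilayer.to_stack()
        _, C_near = membrane_correlation(stack, gauss_params, 0.0, 0.0)
        _, C_far = membrane_correlation(stack, gauss_params, 0.0, 1e5)
        assert abs(C_far) < 1e-6 * abs(C_near)

    def test_probability_route_matches_fourier_route(self, neutron_bilayer,
                                                     gauss_params):
        """Bivariate-normal z-quadrature vs the analytically z-transformed
        displaced-profile identity (independent 1D quadrature)."""
        stack = neutron_bilayer.to_stack()
        for r_z, r_xy, tau in [(5.0, 30.0, 0.0), (10.0, 80.0, 50.0)]:
            C_avg, C_fl = membrane_correlation(stack, gauss_params, r_z, r_xy, tau)
            qz = np.linspace(0.0, 4.0, 8000)
            amp2 = np.abs(slab_amplitude(stack, qz, stack.solvent_sld)) ** 2
            gv = float(gw_covariance(r_xy, tau, gauss_params))
            la2 = gauss_params.l_alpha**2
            full = np.trapezoid(np.cos(qz * r_z) * amp2
                                * np.exp(-qz**2 * la2 * (1 - gv)), qz) / math.pi
            avg = np.trapezoid(np.cos(qz * r_z) * amp2
                               * np.exp(-qz**2 * la2), qz) / math.pi
            assert C_avg == pytest.approx(avg, rel=1e-3)
            assert C_fl == pytest.approx(full - avg, rel=1e-3)


class TestGaussianIntensity:
    def test_total_bounded_below_by_average_term(self, neutron_bilayer,
                                                 gauss_params, fit_q):
        dec = gaussian_intensity(neutron_bilayer, gauss_params, fit_q)
        assert np.all(dec.fluctuation >= -1e-12 * dec.total.max())
        assert np.all(dec.total >= dec.average)

    def test_rigid_limit_matches_slab(self, neutron_bilayer, fit_q):
        g = GaussianMembraneParams(1e-5, 63.0)
        dec = gaussian_intensity(neutron_bilayer, g, fit_q)
        ref = slab_intensity(neutron_bilayer, fit_q).I
        assert np.max(np.abs(dec.total - ref) / ref) < 5e-3


class TestNse:
    def test_tau_zero_normalization(self, neutron_bilayer, neutron_protein):
        g = rbc.default_gaussian(D=1.85)
        s = nse_curve(neutron_bilayer, g, neutron_protein, [0.05, 0.1],
                      [0.0, 50.0])
        assert np.allclose(s.values[:, 0], 1.0, atol=1e-12)

    def test_static_membrane_shows_no_decay(self, neutron_bilayer):
        g = rbc.default_gaussian(D=0.0)
        s = nse_curve(neutron_bilayer, g, None, [0.05], [0.0, 100.0, 400.0])
        assert np.allclose(s.values, 1.0, atol=1e-12)

    def test_monotone_decay_and_plateau(self, neutron_bilayer, neutron_protein):
        g = rbc.default_gaussian(D=1.85)
        q = np.array([0.071])
        tau = np.array([0.0, 50.0, 150.0, 400.0, 3e6])
        s = nse_curve(neutron_bilayer, g, neutron_protein, q, tau)
        assert np.all(np.diff(s.values[0]) < 1e-9)
        # plateau: ratio of average term to total at tau = 0
        from memsas.gaussian import average_term, fluct_term
        from memsas.profiles import protein_corrected_slds
        stack = protein_corrected_slds(neutron_bilayer.to_stack(),
                                       neutron_protein, "average")
        avg = average_term(stack, g, q)
        tot0 = avg + fluct_term(stack, g, q, 0.0)
        assert s.values[0, -1] == pytest.approx((avg / tot0)[0], rel=2e-2,
                                                abs=2e-3)


class TestRoughness:
    def test_flat_membrane(self):
        assert roughness_factor(GaussianMembraneParams(0.0, 63.0)) == 1.0

    def test_increasing_in_amplitude(self):
        vals = [roughness_factor(GaussianMembraneParams(la, 63.0))
                for la in (5.0, 15.0, 23.0, 40.0)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))
        assert all(v >= 1.0 for v in vals)

    def test_matches_field_realization_estimate(self):
        """Closed form vs the surface-area ratio of synthesized fields."""
        from memsas.realizations import sample_height_field
        g = GaussianMembraneParams(23.0, 63.0)
        L, n = 1024.0, 256
        dx = L / n
        vals = []
        for s in range(8):
            h = sample_height_field(g, L, n, seed=900 + s)[0]
            gx = (np.roll(h, -1, 0) - np.roll(h, 1, 0)) / (2 * dx)
            gy = (np.roll(h, -1, 1) - np.roll(h, 1, 1)) / (2 * dx)
            vals.append(np.mean(np.sqrt(1.0 + gx**2 + gy**2)))
        emp, se = np.mean(vals), np.std(vals, ddof=1) / math.sqrt(8)
        assert abs(roughness_factor(g) - emp) < 3 * se + 5e-3


class TestValidation:
    def test_parameter_bounds(self):
        with pytest.raises(ValidationError):
            GaussianMembraneParams(-1.0, 63.0)
        with pytest.raises(ValidationError):
            GaussianMembraneParams(23.0, 0.0)
        with pytest.raises(ValidationError):
            GaussianMembraneParams(23.0, 63.0, -1.0)

    def test_correlation_time_formula(self):
        g = GaussianMembraneParams(23.0, 63.0, 1.85)
        assert g.correlation_time == pytest.approx(63.0**2 / (4 * 1.85))
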