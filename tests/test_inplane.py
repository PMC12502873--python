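"""In-plane protein statistics: form factors, covariograms, correlations."""

import math

import numpy as np
import pytest
from scipy.special import j1
from scipy.optimize import brentq

from memsas import inplane
from memsas.profiles import ProteinSpec, ValidationError


def boolean_disc(theta_A: float, R: float = 21.4, D_p: float = 0.0) -> ProteinSpec:
    A = math.pi * R * R
    return ProteinSpec(("disc", R), theta_p=theta_A / A,
                       lateral_model="boolean", D_p=D_p)


class TestDiscFormFactor:
    def test_limit_at_zero(self):
        assert inplane.disc_form_factor(0.0, 10.0) == 1.0

    def test_vanishes_at_first_bessel_root(self):
        root = brentq(j1, 3.0, 4.5)  # independent root finding
        assert root == pytest.approx(3.8317, abs=1e-4)
        assert inplane.disc_form_factor(root / 7.0, 7.0) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_unit_argument(self):
        # series evaluation of J1(1): sum_k (-1)^k /(k! (k+1)!) (1/2)^{2k+1}
        s = sum((-1) ** k / (math.factorial(k) * math.factorial(k + 1))
                * 0.5 ** (2 * k + 1) for k in range(20))
        assert inplane.disc_form_factor(1.0, 1.0) == pytest.approx((2 * s) ** 2,
                                                                   rel=1e-12)


class TestEllipse:
    def test_circle_degenerates_to_disc(self):
        q = np.linspace(0.0, 0.5, 40)
        assert np.allclose(inplane.ellipse_form_factor(q, 12.0, 12.0),
                           inplane.disc_form_factor(q, 12.0), atol=1e-12)
        r = np.linspace(0.0, 30.0, 40)
        assert np.allclose(inplane.ellipse_covariogram(r, 12.0, 12.0),
                           inplane.disc_covariogram(r, 12.0), rtol=1e-10)

    def test_dimer_covariogram_at_origin_is_area(self):
        """Band 3 dimer section 105 x 31 A: K(0) = pi a b."""
        assert inplane.ellipse_covariogram(0.0, 52.5, 15.5) == pytest.approx(
            math.pi * 52.5 * 15.5, rel=1e-12)

    def test_covariogram_matches_monte_carlo_intersection(self):
        """Area-sampling MC estimate of the intersection of a randomly
        oriented ellipse with its translated copy."""
        a, b, r = 52.5, 15.5, 30.0
        rng = np.random.default_rng(42)
        trials, npts = 40, 40000
        vals = []
        for _ in range(trials):
            th = rng.uniform(0, 2 * math.pi)
            ph = rng.uniform(0, 2 * math.pi)
            dx, dy = r * math.cos(ph - th), r * math.sin(ph - th)
            u = rng.uniform(0, 1, npts)
            ang = rng.uniform(0, 2 * math.pi, npts)
            xs = a * np.sqrt(u) * np.cos(ang)
            ys = b * np.sqrt(u) * np.sin(ang)
            inside = ((xs - dx) / a) ** 2 + ((ys - dy) / b) ** 2 <= 1.0
            vals.append(inside.mean() * math.pi * a * b)
        mc, se = np.mean(vals), np.std(vals, ddof=1) / math.sqrt(trials)
        assert abs(float(inplane.ellipse_covariogram(r, a, b)) - mc) < 3 * se


class TestHardDiscStructureFactor:
    def test_ideal_gas_limit(self):
        q = np.linspace(0.0, 1.0, 50)
        assert np.allclose(inplane.harddisc_structure_factor(q, 20.0, 0.0), 1.0)

    def test_compressibility_suppression_at_low_q(self):
        for phi in (0.05, 0.15, 0.3):
            S0 = float(inplane.harddisc_structure_factor(0.0, 20.0, phi))
            assert S0 < 1.0
            assert S0 == pytest.approx(1.0 / (1.0 + 4.0 * phi), rel=1e-12)

    def test_large_q_limit(self):
        S = float(inplane.harddisc_structure_factor(50.0 / 20.0, 20.0, 0.3))
        assert abs(S - 1.0) < 0.01

    def test_high_density_warns(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            inplane.harddisc_structure_factor(0.1, 20.0, 0.6)
        assert any("low-density" in r.message for r in caplog.records)


class TestDiscCovariogram:
    def test_full_overlap_is_area(self):
        assert inplane.disc_covariogram(0.0, 21.4) == pytest.approx(
            math.pi * 21.4**2, rel=1e-12)

    def test_tangent_discs_do_not_overlap(self):
        assert inplane.disc_covariogram(2 * 21.4, 21.4) == 0.0
        assert inplane.disc_covariogram(100.0, 21.4) == 0.0

    def test_half_separation_lens_area(self):
        """K(R)/R^2 = 2 (pi/3 - sqrt(3)/4), cross-checked by MC."""
        R = 1.0
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, size=(400000, 2))
        inside = (pts**2).sum(axis=1) <= 1.0
        shifted = ((pts[:, 0] - R) ** 2 + pts[:, 1] ** 2) <= 1.0
        mc = np.mean(inside & shifted) * 4.0
        val = float(inplane.disc_covariogram(R, R))
        assert val == pytest.approx(2 * (math.pi / 3 - math.sqrt(3) / 4), rel=1e-12)
        assert val == pytest.approx(mc, abs=4 * math.sqrt(mc / 400000) + 3e-3)

    def test_diffusive_smearing_matches_spectral_route(self):
        """Real-space Rician smearing vs Hankel of A^2 P e^{-q^2 D tau}."""
        R, D, tau = 21.4, 5.0, 40.0
        r = np.linspace(0.0, 120.0, 80)
        K1 = inplane.disc_covariogram(r, R, tau, D)
        q = np.linspace(1e-5, 3.0, 20000)
        from scipy.special import j0
        Kq = (math.pi * R**2 * 2 * j1(q * R) / (q * R)) ** 2
        K2 = np.trapezoid(q[None, :] * j0(np.outer(r, q))
                          * (Kq * np.exp(-(q**2) * D * tau))[None, :],
                          q, axis=1) / (2 * math.pi)
        assert np.max(np.abs(K1 - K2)) / (math.pi * R**2) < 1e-5

    def test_smearing_preserves_total_mass(self):
        R, D, tau = 10.0, 3.0, 30.0
        r = np.linspace(0.0, 200.0, 4000)
        K = inplane.disc_covariogram(r, R, tau, D)
        mass = np.trapezoid(2 * math.pi * r * K, r)
        assert mass == pytest.approx((math.pi * R**2) ** 2, rel=1e-3)


class TestBooleanCorrelation:
    def test_origin_value_phi_one_minus_phi(self):
        p = ProteinSpec.from_phi(("disc", 21.4), 0.25, lateral_model="boolean")
        assert float(inplane.boolean_correlation(0.0, p)) == pytest.approx(
            0.1875, rel=1e-12)

    def test_vanishes_beyond_disc_diameter(self):
        p = boolean_disc(0.3)
        r = np.array([2 * 21.4, 50.0, 300.0])
        assert np.allclose(inplane.boolean_correlation(r, p), 0.0)

    def test_dilute_deviation_scales_linearly_in_density(self):
        """C_p - theta K = O(theta A): the measured coefficient stays near
        its exact small-density series value 1.5 (so the deviation is below
        1% of theta A for theta A below ~6e-3)."""
        R = 21.4
        r = np.linspace(0.0, 2 * R, 200)
        K = inplane.disc_covariogram(r, R)
        for ta in (1e-3, 3e-3):
            p = boolean_disc(ta)
            dev = np.max(np.abs(inplane.boolean_correlation(r, p)
                                - p.theta_p * K)) / ta
            assert dev == pytest.approx(1.5 * ta, rel=0.05)

    def test_time_decay_towards_zero(self):
        p = boolean_disc(0.3, D_p=10.0)
        r = np.linspace(0.0, 80.0, 50)
        c0 = inplane.boolean_correlation(r, p, 0.0)
        c1 = inplane.boolean_correlation(r, p, 200.0)
        c2 = inplane.boolean_correlation(r, p, 2000.0)
        assert np.max(np.abs(c1)) < np.max(np.abs(c0))
        assert np.max(np.abs(c2)) < 0.05 * np.max(np.abs(c0))


class TestInplaneIntensity:
    def test_harddisc_rejects_dynamics(self):
        p = ProteinSpec(("disc", 20.0), theta_p=1e-5,
                        lateral_model="harddisc", D_p=1.0)
        with pytest.raises(ValidationError):
            inplane.inplane_intensity(np.array([0.1]), p, tau=10.0)

    def test_intensity_nonnegative_and_decaying(self):
        p = boolean_disc(0.26)
        q = np.linspace(1e-4, 2.0, 300)
        I = inplane.inplane_intensity(q, p)
        assert np.all(I > -1e-4 * I.max())  # quadrature-level negatives only
        assert I[-1] < 1e-3 * I.max()

    def test_parseval_consistency_at_q_zero(self):
        """I_p(0) equals the 2D integral of C_p (independent quadrature)."""
        p = boolean_disc(0.26)
        r = np.linspace(0.0, 3 * 21.4, 30001)
        ref = np.trapezoid(2 * math.pi * r * inplane.boolean_correlation(r, p), r)
        val = inplane.inplane_intensity(np.array([1e-9]), p)[0]
        assert val == pytest.approx(ref, rel=1e-4)

    def test_boolean_approaches_dilute_form(self):
        """At theta A = 1e-3 the Boolean intensity is within 0.2% of
        theta A^2 P (deviation ~1.77 * theta A)."""
        R = 21.4
        p = boolean_disc(1e-3)
        q = np.linspace(1e-5, 10.0 / R, 100)
        Ib = inplane.inplane_intensity(q, p)
        Iref = p.theta_p * p.area**2 * inplane.disc_form_factor(q, R)
        assert np.max(np.abs(Ib - Iref)) / (p.theta_p * p.area**2) < 2e-3
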