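"""In-plane statistics of the protein cylinder phase.

The proteins are cylinders normal to the membrane; their lateral statistics
are described either as non-overlapping hard discs (elastic only) or as a
Boolean model of freely overlapping discs/ellipses centred on a Poisson point
process.  The central objects are

* the cross-section form factor ``P_p(q_xy)`` and geometric covariogram
  ``K(r_xy)`` (intersection area of a shape with its own translate),
* the low-density hard-disc structure factor ``S_HD(q_xy)``,
* the Boolean phase correlation
  ``C_p(r, tau) = (1-phi_p)^2 [exp(theta_p K(r, tau)) - 1]``,
* the in-plane intensity ``I_p(q_xy, tau)``, the 2D Fourier (zero-order
  Hankel) transform of ``C_p``.

Protein mobility enters through an isotropic Gaussian displacement law with
per-axis variance ``2 D_p tau`` (2D mean-square displacement ``4 D_p tau``),
which smears the covariogram: ``K(., tau) = K(., 0) * G_{2 D_p tau}``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from dataclasses import dataclass
from scipy.special import i0e, j0, j1

from .profiles import ProteinSpec, ValidationError

__all__ = [
    "disc_form_factor",
    "ellipse_form_factor",
    "disc_covariogram",
    "ellipse_covariogram",
    "covariogram",
    "harddisc_structure_factor",
    "boolean_correlation",
    "correlation_table",
    "inplane_intensity",
    "hankel0",
    "InplaneCorrelation",
]

log = logging.getLogger(__name__)

_N_ANGLE = 96        # angular nodes for ellipse orientation averages
_N_HANKEL = 2048     # radial nodes for Hankel quadratures


def _jinc(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x with the analytic x->0 limit (=1)."""
    x = np.asarray(x, dtype=float)
    xs = np.where(x == 0.0, 1.0, x)
    return np.where(x == 0.0, 1.0, 2.0 * j1(xs) / xs)


def disc_form_factor(q_xy, R_p: float) -> np.ndarray:
    """Normalized disc form factor ``P_p(q) = [2 J1(qR)/(qR)]^2``; P_p(0)=1."""
    if R_p <= 0:
        raise ValidationError("R_p must be positive")
    return _jinc(np.asarray(q_xy, dtype=float) * R_p) ** 2


def ellipse_form_factor(q_xy, a: float, b: float) -> np.ndarray:
    """Orientation-averaged form factor of an elliptical cross-section.

    Average of the disc kernel over the angle-dependent effective radius
    ``r_e(psi) = sqrt(a^2 cos^2 psi + b^2 sin^2 psi)``; reduces to the disc
    result for a = b.
    """
    if not (a >= b > 0):
        raise ValidationError("need a >= b > 0")
    q = np.atleast_1d(np.asarray(q_xy, dtype=float))
    psi = (np.arange(_N_ANGLE) + 0.5) * (0.5 * math.pi / _N_ANGLE)
    r_e = np.sqrt((a * np.cos(psi)) ** 2 + (b * np.sin(psi)) ** 2)
    vals = _jinc(q[:, None] * r_e[None, :]) ** 2
    out = vals.mean(axis=1)
    return out.reshape(np.shape(q_xy))


def _unit_lens(u: np.ndarray) -> np.ndarray:
    """Intersection area of two unit discs at centre distance u (0 beyond 2)."""
    u = np.asarray(u, dtype=float)
    uc = np.clip(u / 2.0, 0.0, 1.0)
    return 2.0 * (np.arccos(uc) - uc * np.sqrt(1.0 - uc**2))


def _gauss_smear_radial(K0, support: float, r, s2: float) -> np.ndarray:
    """Convolve an isotropic function K0(r) (support [0, support]) with an
    isotropic 2D Gaussian of per-axis variance s2, evaluated at radii r.

    Uses the radially reduced (Rician) kernel
    ``K(r) = int_0^sup (u/s2) exp(-(u-r)^2/(2 s2)) i0e(u r / s2) K0(u) du``
    which is numerically stable at all r/s ratios.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    u = np.linspace(0.0, support, 4096)
    K0u = K0(u)
    x = u[None, :] * r[:, None] / s2
    w = (u[None, :] / s2) * np.exp(-((u[None, :] - r[:, None]) ** 2) / (2 * s2)) * i0e(x)
    return np.trapezoid(w * K0u[None, :], u, axis=1)


def disc_covariogram(r_xy, R_p: float, tau: float = 0.0, D_p: float = 0.0) -> np.ndarray:
    """Geometric covariogram of a disc, optionally smeared by diffusion.

    tau = 0 (or D_p = 0): lens area ``2 R^2 [arccos(u) - u sqrt(1-u^2)]``
    with ``u = r/(2R)``, zero beyond 2R.  Otherwise the static covariogram is
    convolved with the Gaussian displacement law of per-axis variance
    ``2 D_p tau``.
    """
    if R_p <= 0:
        raise ValidationError("R_p must be positive")
    r = np.asarray(r_xy, dtype=float)
    if tau * D_p <= 0.0:
        return R_p**2 * _unit_lens(r / R_p)
    s2 = 2.0 * D_p * tau
    out = _gauss_smear_radial(lambda u: R_p**2 * _unit_lens(u / R_p),
                              2.0 * R_p + 8.0 * math.sqrt(s2), r, s2)
    return out.reshape(np.shape(r_xy))


def ellipse_covariogram(r_xy, a: float, b: float,
                        tau: float = 0.0, D_p: float = 0.0) -> np.ndarray:
    """Isotropized covariogram of a randomly oriented ellipse.

    The covariogram of an ellipse with semi-axes (a, b) displaced by vector r
    is ``ab * k(|T^-1 r|)`` with ``T = diag(a, b)`` and k the unit-disc lens;
    averaging over orientations of r gives the isotropized form.  K(0) = pi
    a b.  Diffusion smears it exactly as for discs.
    """
    if not (a >= b > 0):
        raise ValidationError("need a >= b > 0")
    phi = (np.arange(_N_ANGLE) + 0.5) * (0.5 * math.pi / _N_ANGLE)
    inv_r = np.sqrt((np.cos(phi) / a) ** 2 + (np.sin(phi) / b) ** 2)

    def K0(u):
        u = np.atleast_1d(np.asarray(u, dtype=float))
        return a * b * _unit_lens(u[:, None] * inv_r[None, :]).mean(axis=1)

    r = np.asarray(r_xy, dtype=float)
    if tau * D_p <= 0.0:
        return K0(np.atleast_1d(r)).reshape(np.shape(r_xy))
    s2 = 2.0 * D_p * tau
    out = _gauss_smear_radial(K0, 2.0 * a + 8.0 * math.sqrt(s2), r, s2)
    return out.reshape(np.shape(r_xy))


def covariogram(p: ProteinSpec, r_xy, tau: float = 0.0) -> np.ndarray:
    """Covariogram of the protein cross-section at lag tau (A^2)."""
    if p.shape[0] == "disc":
        return disc_covariogram(r_xy, p.shape[1], tau, p.D_p)
    return ellipse_covariogram(r_xy, p.shape[1], p.shape[2], tau, p.D_p)


def form_factor(p: ProteinSpec, q_xy) -> np.ndarray:
    """Orientation-averaged cross-section form factor of the protein."""
    if p.shape[0] == "disc":
        return disc_form_factor(q_xy, p.shape[1])
    return ellipse_form_factor(q_xy, p.shape[1], p.shape[2])


def harddisc_structure_factor(q_xy, R_hd: float, phi_p: float) -> np.ndarray:
    """Low-density 2D hard-disc structure factor.

    First-order closure ``S(q) = 1 / [1 + 4 phi_p 2J1(2qR)/(2qR)]``: the
    direct correlation function is minus the overlap (Mayer) function of the
    exclusion disc of radius 2R.  Exact limits: S -> 1 as phi_p -> 0 and as
    q -> infinity; S(0) = 1/(1+4 phi_p) < 1 (reduced compressibility).
    Adequate at low densities; a warning is logged for phi_p >= 0.5.
    """
    if R_hd <= 0:
        raise ValidationError("R_hd must be positive")
    if not 0 <= phi_p < 1:
        raise ValidationError("phi_p must lie in [0, 1)")
    if phi_p >= 0.5:
        log.warning("hard-disc structure factor used outside its low-density "
                    "regime (phi_p = %.3f >= 0.5)", phi_p)
    q = np.asarray(q_xy, dtype=float)
    return 1.0 / (1.0 + 4.0 * phi_p * _jinc(2.0 * q * R_hd))


def boolean_correlation(r_xy, p: ProteinSpec, tau: float = 0.0) -> np.ndarray:
    """Correlation of the Boolean protein phase.

    ``C_p(r, tau) = (1 - phi_p)^2 [exp(theta_p K(r, tau)) - 1]``;
    C_p(0,0) = phi_p (1-phi_p), decays to 0 with K, and reduces to
    ``theta_p K`` in the dilute limit.
    """
    if p.lateral_model != "boolean":
        raise ValidationError("boolean_correlation requires a Boolean-model spec")
    phi = p.phi_p
    K = covariogram(p, r_xy, tau)
    return (1.0 - phi) ** 2 * np.expm1(p.theta_p * K)


@dataclass
class InplaneCorrelation:
    """Tabulated in-plane correlation C_p(r_xy, tau) on a radial grid."""

    r_grid: np.ndarray
    values: np.ndarray
    phi_p: float
    theta_p: float
    tau: float = 0.0


def _r_support(p: ProteinSpec, tau: float) -> float:
    two_R = 2.0 * (p.shape[1] if p.shape[0] == "disc" else p.shape[1])
    broad = math.sqrt(2.0 * p.D_p * tau) if p.D_p * tau > 0 else 0.0
    return max(6.0 * two_R, 6.0 * broad + two_R)


def correlation_table(p: ProteinSpec, tau: float = 0.0,
                      n: int = _N_HANKEL) -> InplaneCorrelation:
    """Tabulate C_p on the truncated radial grid used for Hankel transforms."""
    r = np.linspace(0.0, _r_support(p, tau), n)
    return InplaneCorrelation(r, boolean_correlation(r, p, tau), p.phi_p,
                              p.theta_p, tau)


def hankel0(q, r: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Zero-order Hankel transform ``2 pi int_0^inf r J0(q r) f(r) dr``.

    Trapezoidal quadrature on the tabulated radial grid; f must decay to ~0
    before the end of the grid.  f may carry leading batch dimensions
    (..., len(r)); the transform is applied along the last axis for every q.
    Returns shape (..., len(q)).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    w = np.gradient(r) * r
    kern = j0(np.multiply.outer(q, r)) * w  # (nq, nr)
    return 2.0 * math.pi * np.tensordot(f, kern, axes=([-1], [1]))


def inplane_intensity(q_xy, p: ProteinSpec, tau: float = 0.0) -> np.ndarray:
    """In-plane protein intensity per unit area, I_p(q_xy, tau) (A^2).

    Hard-disc path (static only): ``theta_p A_p^2 P_p(q) S_HD(q)``.
    Boolean path: zero-order Hankel transform of C_p(r, tau).
    """
    q = np.asarray(q_xy, dtype=float)
    if p.lateral_model == "harddisc":
        if tau > 0 and p.D_p > 0:
            raise ValidationError(
                "hard-disc model has no dynamic extension; use the Boolean model"
            )
        S = harddisc_structure_factor(q, p.harddisc_radius, p.phi_p)
        return p.theta_p * p.area**2 * form_factor(p, q) * S
    tab = correlation_table(p, tau)
    out = hankel0(np.ravel(q), tab.r_grid, tab.values)
    return out.reshape(np.shape(q_xy))
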