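"""Gaussian fluctuating-membrane model (bending fluctuations only).

The rigid layer stack is displaced vertically by a stationary Gaussian
height field ``h(x, y, t) = l_alpha W``, where W has unit variance and the
normalized space-time covariance

    g_W(r, tau) = (1 + D tau / l_xy^2)^-1
                  * exp[ -r^2 / (4 l_xy^2 (1 + D tau / l_xy^2)) ]

— the covariance of Gaussian wave packets of lateral size ``l_xy`` whose
centres diffuse in the plane with coefficient ``D`` and overlap with random
signs.  ``l_alpha`` is the r.m.s. vertical displacement; ``l_alpha -> 0``
recovers the static slab.

Because the displacement is rigid, the scattering correlation function of
the membrane follows from the profile amplitude alone:

    FT_{r_z} C(r_z, r_xy, tau) = |rho(q_z)|^2
                                 exp[-q_z^2 l_alpha^2 (1 - g_W(r_xy, tau))]

whose large-``r_xy`` limit (g_W -> 0) is the *average-structure* term — the
slab intensity of the smeared profile — while the remainder is the
*fluctuation* term, transformed to reciprocal space by a zero-order Hankel
transform in r_xy and rotationally averaged exactly as the slab protein
term.  The same statistics can be written through bivariate-normal layer
occupation probabilities; both routes are implemented (the probability
route, :func:`layer_probabilities` / :func:`membrane_correlation`, serves
as an independent real-space check) and agree to quadrature accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx, j0, ndtr, owens_t

from .curves import ISFSurface, ScatteringCurve
from .profiles import (LayerStack, ProteinSpec, SymmetricBilayer,
                       ValidationError, expand_bilayer, protein_corrected_slds,
                       slab_amplitude)
from .slab import MU_ORDER, _as_stack, _mu_nodes, slab_intensity

__all__ = [
    "GaussianMembraneParams",
    "gw_covariance",
    "bvn_cdf",
    "layer_probabilities",
    "membrane_correlation",
    "gaussian_intensity",
    "GaussianDecomposition",
    "nse_curve",
    "roughness_factor",
]

N_HANKEL_R = 2048


@dataclass(frozen=True)
class GaussianMembraneParams:
    """Bending-fluctuation parameters.

    l_alpha : r.m.s. vertical displacement (A); 0 recovers the slab model.
    l_xy    : lateral size of the deformations (A); > 0.
    D       : wave-packet diffusion coefficient (A^2/ns); >= 0.
    """

    l_alpha: float
    l_xy: float
    D: float = 0.0

    def __post_init__(self) -> None:
        if self.l_alpha < 0:
            raise ValidationError("l_alpha must be nonnegative")
        if self.l_xy <= 0:
            raise ValidationError("l_xy must be positive")
        if self.D < 0:
            raise ValidationError("D must be nonnegative")

    @property
    def correlation_time(self) -> float:
        """tau_c = l_xy^2 / (4 D): time for a packet to diffuse over its own
        size (2D mean-square displacement 4 D tau)."""
        if self.D == 0:
            return math.inf
        return self.l_xy**2 / (4.0 * self.D)


def gw_covariance(r_xy, tau, g: GaussianMembraneParams) -> np.ndarray:
    """Normalized space-time covariance of the unit-variance height field."""
    if np.any(np.asarray(tau) < 0):
        raise ValidationError("tau must be nonnegative")
    r = np.asarray(r_xy, dtype=float)
    stretch = 1.0 + np.asarray(tau, dtype=float) * g.D / g.l_xy**2
    return np.exp(-r**2 / (4.0 * g.l_xy**2 * stretch)) / stretch


# ---------------------------------------------------------------------------
# bivariate normal probabilities

_BIG = 1e15


def bvn_cdf(h, k, rho) -> np.ndarray:
    """Standard bivariate normal CDF P[X <= h, Y <= k; rho], vectorized.

    Owen's-T decomposition; accurate to ~1e-14 away from |rho| = 1, with the
    degenerate |rho| -> 1 limits handled explicitly.  Infinite bounds are
    supported.
    """
    h, k, rho = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float),
                                    np.asarray(rho, float))
    out = np.empty(h.shape)
    one = np.abs(rho) >= 1.0 - 1e-12
    if one.any():
        hi, ki, ri = h[one], k[one], rho[one]
        pos = np.minimum(ndtr(hi), ndtr(ki))
        neg = np.maximum(0.0, ndtr(hi) + ndtr(ki) - 1.0)
        out[one] = np.where(ri > 0, pos, neg)
    gen = ~one
    if gen.any():
        hg, kg, rg = h[gen], k[gen], rho[gen]
        s = np.sqrt(1.0 - rg**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ah = (kg - rg * hg) / (hg * s)
            ak = (hg - rg * kg) / (kg * s)
        ah = np.where(hg == 0.0, np.sign(kg) * _BIG, ah)
        ak = np.where(kg == 0.0, np.sign(hg) * _BIG, ak)
        # clip infinities from infinite bounds; T terms vanish there anyway
        ah = np.clip(np.nan_to_num(ah, nan=0.0, posinf=_BIG, neginf=-_BIG), -_BIG, _BIG)
        ak = np.clip(np.nan_to_num(ak, nan=0.0, posinf=_BIG, neginf=-_BIG), -_BIG, _BIG)
        with np.errstate(invalid="ignore"):
            hk = hg * kg
            beta = np.where((hk < 0) | ((hk == 0) & (hg + kg < 0)), 0.5, 0.0)
        finite_h = np.isfinite(hg)
        finite_k = np.isfinite(kg)
        th = np.where(finite_h, owens_t(np.where(finite_h, hg, 0.0), ah), 0.0)
        tk = np.where(finite_k, owens_t(np.where(finite_k, kg, 0.0), ak), 0.0)
        val = 0.5 * (ndtr(hg) + ndtr(kg)) - th - tk - beta
        # exact special case h = k = 0
        both0 = (hg == 0.0) & (kg == 0.0)
        val = np.where(both0, 0.25 + np.arcsin(rg) / (2.0 * math.pi), val)
        # infinite bounds
        val = np.where(np.isneginf(hg) | np.isneginf(kg), 0.0, val)
        val = np.where(np.isposinf(hg), ndtr(kg), val)
        val = np.where(np.isposinf(kg) & np.isfinite(hg), ndtr(hg), val)
        val = np.where(np.isposinf(hg) & np.isposinf(kg), 1.0, val)
        out[gen] = val
    return np.clip(out, 0.0, 1.0)


def _rect_prob(xlo, xhi, ylo, yhi, rho) -> np.ndarray:
    """P[x in (xlo, xhi], y in (ylo, yhi]] for standard bivariate normal."""
    return (bvn_cdf(xhi, yhi, rho) - bvn_cdf(xlo, yhi, rho)
            - bvn_cdf(xhi, ylo, rho) + bvn_cdf(xlo, ylo, rho))


def _intervals(stack: LayerStack, include_solvent: bool):
    b = list(stack.boundaries)
    iv = list(zip(b[:-1], b[1:]))
    if include_solvent:
        iv = [(-math.inf, b[0])] + iv + [(b[-1], math.inf)]
    return iv


def layer_probabilities(stack: LayerStack, g: GaussianMembraneParams,
                        z1: float, z2: float, r_xy: float, tau: float = 0.0,
                        include_solvent: bool = False):
    """One-point p_n(z) and two-point P_nm layer-occupation probabilities.

    Point z is in layer n when ``z - h`` lies in the layer interval, i.e.
    ``h in (z - a_{n+1}, z - a_n]`` with ``h ~ N(0, l_alpha^2)``; pairs of
    points use the bivariate normal with correlation ``g_W(r_xy, tau)``.
    With ``include_solvent`` the two semi-infinite solvent intervals are
    appended, making (p_n) and (P_nm) proper distributions (sum to 1).

    Returns ``(p1, p2, P)`` with P of shape (n_intervals, n_intervals).
    """
    iv = _intervals(stack, include_solvent)
    la = g.l_alpha
    if la == 0.0:
        p1 = np.array([1.0 if lo <= z1 < hi else 0.0 for lo, hi in iv])
        p2 = np.array([1.0 if lo <= z2 < hi else 0.0 for lo, hi in iv])
        return p1, p2, np.outer(p1, p2)
    rho = float(gw_covariance(r_xy, tau, g))
    lo = np.array([l for l, _ in iv])
    hi = np.array([h for _, h in iv])
    p1 = ndtr((z1 - lo) / la) - ndtr((z1 - hi) / la)
    p2 = ndtr((z2 - lo) / la) - ndtr((z2 - hi) / la)
    xlo, xhi = (z1 - hi) / la, (z1 - lo) / la
    ylo, yhi = (z2 - hi) / la, (z2 - lo) / la
    P = _rect_prob(xlo[:, None], xhi[:, None], ylo[None, :], yhi[None, :], rho)
    return p1, p2, P


def _contrast_slds(stack: LayerStack) -> np.ndarray:
    return np.asarray(stack.slds) - stack.solvent_sld


def membrane_correlation(stack: LayerStack, g: GaussianMembraneParams,
                         r_z: float, r_xy: float, tau: float = 0.0,
                         dz: float | None = None):
    """Real-space correlation of the fluctuating membrane (solvent-contrasted).

    Returns ``(C_avg, C_fluct)`` in A^-4 * A = A^-3 per-unit-area units:
    C_avg(r_z) is the self-convolution of the mean profile
    ``<rho>(z) = sum_n rho_n p_n(z)`` and C_fluct the z-integral of
    ``sum_nm rho_n rho_m [P_nm - p_n p_m]``, by direct z quadrature on a grid
    extending 5 l_alpha beyond the stack.

    This is the slow reference route; intensities use the analytically
    z-transformed equivalent.
    """
    rho = _contrast_slds(stack)
    la = g.l_alpha
    b = np.asarray(stack.boundaries)
    if la == 0.0:
        # sharp rigid profile: midpoint rule needs a fine grid at the jumps
        zg, dzv = _zgrid(stack, g, abs(r_z), dz if dz is not None else 0.02)
        prof = stack.sld_profile(zg) - stack.solvent_sld
        prof2 = stack.sld_profile(zg + r_z) - stack.solvent_sld
        return float(np.sum(prof * prof2) * dzv), 0.0
    zg, dzv = _zgrid(stack, g, abs(r_z), dz)
    lo = b[:-1][None, :]
    hi = b[1:][None, :]
    p1 = ndtr((zg[:, None] - lo) / la) - ndtr((zg[:, None] - hi) / la)
    z2 = zg + r_z
    p2 = ndtr((z2[:, None] - lo) / la) - ndtr((z2[:, None] - hi) / la)
    mean1 = p1 @ rho
    mean2 = p2 @ rho
    C_avg = float(np.sum(mean1 * mean2) * dzv)
    rho_corr = float(gw_covariance(r_xy, tau, g))
    n = stack.n_layers
    xlo = (zg[:, None] - hi) / la
    xhi = (zg[:, None] - lo) / la
    ylo = (z2[:, None] - hi) / la
    yhi = (z2[:, None] - lo) / la
    acc = np.zeros(zg.size)
    for i in range(n):
        for j in range(n):
            Pij = _rect_prob(xlo[:, i], xhi[:, i], ylo[:, j], yhi[:, j], rho_corr)
            acc += rho[i] * rho[j] * (Pij - p1[:, i] * p2[:, j])
    return C_avg, float(np.sum(acc) * dzv)


def _zgrid(stack: LayerStack, g: GaussianMembraneParams, extra: float,
           dz: float | None):
    b = np.asarray(stack.boundaries)
    if dz is None:
        thick = np.min(np.diff(b)) if stack.n_layers else 1.0
        cand = [thick / 4.0]
        if g.l_alpha > 0:
            cand.append(g.l_alpha / 4.0)
        dz = max(min(cand), 1e-3)
    lo = b[0] - 5.0 * g.l_alpha - extra
    hi = b[-1] + 5.0 * g.l_alpha + extra
    npts = max(int(math.ceil((hi - lo) / dz)), 16)
    zg = lo + (np.arange(npts) + 0.5) * (hi - lo) / npts
    return zg, (hi - lo) / npts


# ---------------------------------------------------------------------------
# intensities (reciprocal-space route)


def _r_grid(g: GaussianMembraneParams, tau: float, n: int = N_HANKEL_R) -> np.ndarray:
    stretch = 1.0 + tau * g.D / g.l_xy**2
    r_max = 8.0 * g.l_xy * math.sqrt(stretch)
    return np.linspace(0.0, r_max, n)


def fluct_term(stack: LayerStack, g: GaussianMembraneParams, q,
               tau: float = 0.0, order: int = MU_ORDER,
               reference_sld: float | None = None) -> np.ndarray:
    """Fluctuation addend of the rotationally averaged intensity.

    ``int_0^1 dmu |rho(q mu)|^2 H(q mu, q sqrt(1-mu^2), tau)`` with
    ``H(q_z, q_xy, tau) = 2 pi int r J0(q_xy r)
    [e^{-q_z^2 l_a^2 (1 - g_W(r, tau))} - e^{-q_z^2 l_a^2}] dr``.
    """
    q = np.asarray(q, dtype=float)
    if g.l_alpha == 0.0:
        return np.zeros(q.shape)
    ref = stack.solvent_sld if reference_sld is None else reference_sld
    mu, w = _mu_nodes(order)
    r = _r_grid(g, tau)
    gv = gw_covariance(r, tau, g)
    la2 = g.l_alpha**2
    wr = np.gradient(r) * r
    out = np.zeros(q.size)
    for i, qi in enumerate(q):
        qz = qi * mu
        qxy = qi * np.sqrt(1.0 - mu**2)
        amp2 = np.abs(slab_amplitude(stack, qz, ref)) ** 2
        expo = np.exp(-np.outer(qz**2 * la2, 1.0 - gv)) \
            - np.exp(-(qz**2 * la2))[:, None]
        kern = j0(np.outer(qxy, r)) * wr[None, :]
        H = 2.0 * math.pi * np.sum(expo * kern, axis=1)
        out[i] = np.sum(w * amp2 * H)
    return out


@dataclass
class GaussianDecomposition:
    """Average-structure and fluctuation addends of the intensity."""

    q: np.ndarray
    average: np.ndarray
    fluctuation: np.ndarray
    radiation: str = "neutron"

    @property
    def total(self) -> np.ndarray:
        return self.average + self.fluctuation

    def curve(self) -> ScatteringCurve:
        return ScatteringCurve(self.q, self.total, radiation=self.radiation)


def average_term(stack: LayerStack, g: GaussianMembraneParams, q,
                 reference_sld: float | None = None) -> np.ndarray:
    """Slab-like intensity of the smeared mean profile:
    ``2 pi |rho(q)|^2 e^{-q^2 l_alpha^2} / q^2``."""
    stack = _as_stack(stack)
    q = np.asarray(q, dtype=float)
    ref = stack.solvent_sld if reference_sld is None else reference_sld
    amp2 = np.abs(slab_amplitude(stack, q, ref)) ** 2
    return 2.0 * math.pi * amp2 * np.exp(-(q * g.l_alpha) ** 2) / q**2


def gaussian_intensity(stack: LayerStack | SymmetricBilayer,
                       g: GaussianMembraneParams, q, tau: float = 0.0,
                       order: int = MU_ORDER,
                       radiation: str = "neutron") -> GaussianDecomposition:
    """Rotationally averaged intensity of the bare Gaussian membrane."""
    stack = _as_stack(stack)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValidationError("q grid must be strictly positive")
    avg = average_term(stack, g, q)
    fl = fluct_term(stack, g, q, tau, order)
    return GaussianDecomposition(q, avg, fl, radiation)


def nse_curve(stack: LayerStack | SymmetricBilayer, g: GaussianMembraneParams,
              p: ProteinSpec | None, q, tau, order: int = MU_ORDER) -> ISFSurface:
    """Normalized intermediate scattering function I(q,tau)/I(q,0).

    Computed from the average-SLD membrane term alone: for neutron contrasts
    the protein addend is negligible and proteins enter only through the
    protein-corrected average SLDs.  Monotone non-increasing in tau; the
    large-tau plateau is (average term)/(total at tau = 0).
    """
    stack = _as_stack(stack)
    if p is not None:
        stack = protein_corrected_slds(stack, p, "average")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise ValidationError("tau must be nonnegative")
    vals = np.empty((q.size, tau.size))
    avg = average_term(stack, g, q)
    for j, t in enumerate(tau):
        vals[:, j] = avg + fluct_term(stack, g, q, t, order)
    norm = avg + fluct_term(stack, g, q, 0.0, order)
    vals = vals / norm[:, None]
    return ISFSurface(q, tau, vals, meta={"l_alpha_A": g.l_alpha,
                                          "l_xy_A": g.l_xy, "D_A2_ns": g.D})


def roughness_factor(g: GaussianMembraneParams) -> float:
    """Mean ratio of true to projected membrane area, E[sqrt(1+|grad h|^2)].

    The gradient variance per axis implied by g_W is
    ``l_alpha^2 / (2 l_xy^2)``, so |grad h|^2 is exponential with mean
    ``m = l_alpha^2 / l_xy^2`` and the closed form is
    ``1 + (sqrt(pi)/2) sqrt(m) erfcx(1/sqrt(m))``; equals 1 at l_alpha = 0
    and increases with l_alpha at fixed l_xy.
    """
    if g.l_alpha == 0.0:
        return 1.0
    m = (g.l_alpha / g.l_xy) ** 2
    return 1.0 + 0.5 * math.sqrt(math.pi * m) * erfcx(1.0 / math.sqrt(m))
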