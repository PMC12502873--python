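"""Elastic/inelastic intensity of the static slab membrane.

The bare membrane is a deterministic SLD profile rho(z); its per-unit-area,
rotationally averaged intensity is ``I(q) = 2 pi |rho(q)|^2 / q^2`` where
rho(q) is the 1D Fourier amplitude of the solvent-contrasted profile.  With
protein cylinders the intensity splits exactly into

* a membrane term: the same expression with each layer SLD replaced by the
  protein-corrected average ``(1-phi_p) rho + phi_p rho_p``, and
* a protein term: ``int_0^1 dmu |rho^c(q mu)|^2 I_p(q sqrt(1-mu^2), tau)``
  (the half-sum over mu in [-1, 1] of the rotational average; the integrand
  is even in mu), where rho^c uses the contrast SLDs ``rho - rho_p`` and
  I_p is the in-plane protein intensity.

The per-unit-area intensity carries an arbitrary scale when compared with
data; scale and background factors live in :mod:`memsas.fitting`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss

from . import inplane
from .curves import ScatteringCurve
from .profiles import (LayerStack, ProteinSpec, SymmetricBilayer,
                       ValidationError, expand_bilayer, protein_corrected_slds,
                       slab_amplitude)

__all__ = ["slab_intensity", "slab_intensity_with_proteins", "ElasticDecomposition"]

MU_ORDER = 64          # Gauss-Legendre order for the rotational average
QUAD_RTOL = 1e-4       # relative tolerance of the order-doubling check


def _as_stack(m) -> LayerStack:
    return expand_bilayer(m) if isinstance(m, SymmetricBilayer) else m


def slab_intensity(stack: LayerStack | SymmetricBilayer, q,
                   reference_sld: float | None = None,
                   radiation: str = "neutron") -> ScatteringCurve:
    """Rotationally averaged per-unit-area intensity of a static slab stack.

    ``I(q) = 2 pi |rho(q)|^2 / q^2`` with rho(q) the amplitude of the profile
    contrasted with ``reference_sld`` (default: the solvent).  q = 0 is
    excluded (the per-area convention diverges there); the low-q log-log
    slope is -2 for any finite-thickness stack with net contrast.
    """
    stack = _as_stack(stack)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValidationError("q grid must be strictly positive")
    ref = stack.solvent_sld if reference_sld is None else reference_sld
    amp = slab_amplitude(stack, q, ref)
    I = 2.0 * np.pi * np.abs(amp) ** 2 / q**2
    return ScatteringCurve(q, I, radiation=radiation)


def _mu_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(order)
    return 0.5 * (x + 1.0), 0.5 * w  # map to [0, 1]


@dataclass
class ElasticDecomposition:
    """Total intensity and its membrane/protein additive terms."""

    q: np.ndarray
    membrane: np.ndarray
    protein: np.ndarray
    radiation: str = "neutron"

    @property
    def total(self) -> np.ndarray:
        return self.membrane + self.protein

    def curve(self) -> ScatteringCurve:
        return ScatteringCurve(self.q, self.total, radiation=self.radiation)


def protein_term_slab(contrast_stack: LayerStack, p: ProteinSpec, q,
                      tau: float = 0.0, order: int = MU_ORDER,
                      Ip_grid: np.ndarray | None = None) -> np.ndarray:
    """Protein addend of the slab intensity at scattering moduli q.

    ``int_0^1 dmu |rho^c(q mu)|^2 I_p(q sqrt(1-mu^2), tau)`` by fixed-order
    Gauss-Legendre quadrature.  ``Ip_grid`` may supply the precomputed
    in-plane intensity on the (q, mu) node grid (it is independent of the
    membrane geometry, so fits cache it).
    """
    q = np.asarray(q, dtype=float)
    mu, w = _mu_nodes(order)
    qz = q[:, None] * mu[None, :]
    if Ip_grid is None:
        qxy = q[:, None] * np.sqrt(1.0 - mu[None, :] ** 2)
        Ip_grid = inplane.inplane_intensity(qxy, p, tau)
    amp2 = np.abs(slab_amplitude(contrast_stack, qz, 0.0)) ** 2
    return (amp2 * Ip_grid) @ w


def slab_intensity_with_proteins(membrane: SymmetricBilayer | LayerStack,
                                 p: ProteinSpec, q, tau: float = 0.0,
                                 order: int = MU_ORDER,
                                 check_quadrature: bool = True,
                                 radiation: str = "neutron") -> ElasticDecomposition:
    """Slab intensity with protein inclusions, decomposed into its two terms.

    The membrane term is :func:`slab_intensity` of the average-SLD stack; the
    protein term couples the contrast amplitude with the in-plane protein
    intensity.  An order-doubling check guards the mu quadrature; failure to
    converge raises with diagnostics.
    """
    stack = _as_stack(membrane)
    q = np.asarray(q, dtype=float)
    avg = protein_corrected_slds(stack, p, "average")
    con = protein_corrected_slds(stack, p, "contrast")
    mem = slab_intensity(avg, q, radiation=radiation).I
    prot = protein_term_slab(con, p, q, tau, order)
    if check_quadrature:
        prot2 = protein_term_slab(con, p, q, tau, 2 * order)
        scale = np.max(np.abs(prot2)) + 1e-300
        err = np.max(np.abs(prot - prot2)) / scale
        if err > QUAD_RTOL:
            raise ValidationError(
                f"mu-quadrature not converged: rel. change {err:.2e} on doubling "
                f"order {order} -> {2*order} (q in [{q.min():.3g}, {q.max():.3g}])"
            )
        prot = prot2
    return ElasticDecomposition(q, mem, prot, radiation)
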