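"""Composition of a membrane model with an in-plane protein model.

For statistically independent membrane and protein structures the combined
correlation function is exactly

    C_rho(r, tau) = C^(a)(r, tau) + C_p(r_xy, tau) * C^(c)(r, tau)

where C^(a)/C^(c) are the membrane correlations computed with the
protein-corrected *average* and *contrast* SLDs and C_p is the correlation
of the protein cylinder phase.  In reciprocal space this yields a membrane
term (the bare model with averaged SLDs) plus a protein term; for the slab
the protein term can be evaluated entirely in reciprocal space, while for
the Gaussian membrane the product C_p * C^(c) is formed in real r_xy space
and Hankel-transformed.  The two paths agree when l_alpha = 0.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import j0

from . import inplane
from .gaussian import (GaussianDecomposition, GaussianMembraneParams,
                       average_term, fluct_term, gw_covariance)
from .profiles import (LayerStack, ProteinSpec, SymmetricBilayer,
                       ValidationError, expand_bilayer, protein_corrected_slds,
                       slab_amplitude)
from .slab import (ElasticDecomposition, MU_ORDER, _as_stack, _mu_nodes,
                   slab_intensity, slab_intensity_with_proteins)

__all__ = ["correlation_with_proteins", "protein_term_gaussian",
           "intensity_with_proteins"]


def correlation_with_proteins(membrane_corr_avg, membrane_corr_contrast,
                              C_p) -> np.ndarray:
    """Combine membrane and protein correlations on matching grids.

    ``C_rho = C^(a) + C_p * C^(c)``; inputs must broadcast against each
    other (mismatched grids raise).
    """
    a = np.asarray(membrane_corr_avg, dtype=float)
    c = np.asarray(membrane_corr_contrast, dtype=float)
    cp = np.asarray(C_p, dtype=float)
    try:
        return a + cp * c
    except ValueError as exc:  # pragma: no cover - numpy message wrapped
        raise ValidationError(f"mismatched correlation grids: {exc}") from exc


def protein_term_gaussian(contrast_stack: LayerStack, g: GaussianMembraneParams,
                          p: ProteinSpec, q, tau: float = 0.0,
                          order: int = MU_ORDER) -> np.ndarray:
    """Protein addend for the Gaussian membrane.

    Real-space product route: for each (q, mu) node,
    ``H(q_z, q_xy) = 2 pi int r J0(q_xy r) C_p(r, tau)
    |rho^c(q_z)|^2 e^{-q_z^2 l_a^2 (1 - g_W(r, tau))} dr``
    followed by the mu rotational average.  The radial grid follows the
    compact support of C_p.
    """
    if p.lateral_model != "boolean":
        raise ValidationError("the Gaussian-membrane protein term requires the "
                              "Boolean in-plane model (real-space correlation)")
    q = np.asarray(q, dtype=float)
    mu, w = _mu_nodes(order)
    r = np.linspace(0.0, inplane._r_support(p, tau), inplane._N_HANKEL)
    cp = inplane.boolean_correlation(r, p, tau)
    gv = gw_covariance(r, tau, g)
    la2 = g.l_alpha**2
    wr = np.gradient(r) * r
    out = np.zeros(q.size)
    for i, qi in enumerate(q):
        qz = qi * mu
        qxy = qi * np.sqrt(1.0 - mu**2)
        amp2 = np.abs(slab_amplitude(contrast_stack, qz, 0.0)) ** 2
        expo = np.exp(-np.outer(qz**2 * la2, 1.0 - gv))
        kern = j0(np.outer(qxy, r)) * (wr * cp)[None, :]
        H = 2.0 * math.pi * np.sum(expo * kern, axis=1)
        out[i] = np.sum(w * amp2 * H)
    return out


def intensity_with_proteins(membrane_model: str,
                            membrane: SymmetricBilayer | LayerStack,
                            g: GaussianMembraneParams | None,
                            p: ProteinSpec, q, tau: float = 0.0,
                            order: int = MU_ORDER,
                            radiation: str = "neutron") -> ElasticDecomposition:
    """Intensity of a membrane with included proteins.

    membrane_model = "slab": reciprocal-space shortcut.
    membrane_model = "gaussian": membrane term from the Gaussian model with
    average SLDs (average + fluctuation parts) plus the real-space-product
    protein term.  Returns the additive decomposition.
    """
    stack = _as_stack(membrane)
    q = np.asarray(q, dtype=float)
    if membrane_model == "slab":
        return slab_intensity_with_proteins(stack, p, q, tau, order,
                                            radiation=radiation)
    if membrane_model != "gaussian":
        raise ValidationError(f"unknown membrane model {membrane_model!r}")
    if g is None:
        raise ValidationError("gaussian path requires GaussianMembraneParams")
    avg = protein_corrected_slds(stack, p, "average")
    con = protein_corrected_slds(stack, p, "contrast")
    mem = average_term(avg, g, q) + fluct_term(avg, g, q, tau, order)
    prot = protein_term_gaussian(con, g, p, q, tau, order)
    return ElasticDecomposition(q, mem, prot, radiation)
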