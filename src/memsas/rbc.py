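"""Reference constants for red-blood-cell membranes and the band 3 protein.

The values gather published compositional estimates used as fixed inputs:
SLD tables for X-rays and neutrons (heavy-water solvent), the cryo-EM
cross-section of the band 3 anion transporter (the predominant RBC
transmembrane protein, used as representative of all of them), and the
liquid-ordered / liquid-disordered lipid-phase thicknesses of oriented RBC
membrane stacks.  Small analytic helpers derive the quantities the models
consume (equivalent cylinder radius, phase-weighted thickness, Boolean
overlap bookkeeping).
"""

from __future__ import annotations

import math

from .gaussian import GaussianMembraneParams
from .profiles import ProteinSpec, SymmetricBilayer

__all__ = [
    "SLD_TABLES",
    "BAND3_MONOMER_SEMIAXES",
    "BAND3_DIMER_SEMIAXES",
    "TRANSMEMBRANE_FRACTION",
    "LIPID_PHASES",
    "equivalent_disc_radius",
    "phase_weighted_thickness",
    "multiply_covered_fraction",
    "default_bilayer",
    "default_protein",
    "default_gaussian",
]

#: SLDs in 1/A^2 for the lipid chains (C), heads (H) and heavy-water solvent
#: (W), plus the homogeneous band 3 protein SLD (p), per radiation.
SLD_TABLES: dict[str, dict[str, float]] = {
    "xray": {"rho_C": 8.1e-6, "rho_H": 14.2e-6, "rho_W": 9.37e-6,
             "rho_p": 12.062e-6},
    "neutron": {"rho_C": -0.07e-6, "rho_H": 1.87e-6, "rho_W": 6.37e-6,
                "rho_p": 1.685e-6},
}

#: Band 3 monomer elliptical cross-section, semi-axes in A (59 x 31 A axes).
BAND3_MONOMER_SEMIAXES: tuple[float, float] = (29.5, 15.5)
#: Band 3 dimer cross-section, semi-axes in A (105 x 31 A axes).
BAND3_DIMER_SEMIAXES: tuple[float, float] = (52.5, 15.5)
#: Transmembrane protein area fraction of the RBC membrane.
TRANSMEMBRANE_FRACTION: float = 0.23

#: (thickness A, fraction %) of the liquid-ordered and liquid-disordered
#: lipid phases in oriented RBC membrane stacks.
LIPID_PHASES: tuple[tuple[float, float], ...] = ((48.0, 30.2), (41.0, 45.0))

#: Reference structural/dynamic fit values used as synthetic-data truths.
DEFAULT_L_C = 16.3
DEFAULT_L_H = 5.0
DEFAULT_L_ALPHA = 23.0
DEFAULT_L_XY = 63.0
DEFAULT_D = 1.85


def equivalent_disc_radius(semi_major: float, semi_minor: float) -> float:
    """Radius of the circle with the same area as the ellipse (geometric
    mean of the semi-axes).  For the band 3 monomer this gives ~21.4 A."""
    if not semi_major >= semi_minor > 0:
        raise ValueError("need semi_major >= semi_minor > 0")
    return math.sqrt(semi_major * semi_minor)


def phase_weighted_thickness(phases=LIPID_PHASES) -> float:
    """Renormalized fraction-weighted mean thickness of the lipid phases.

    The phase fractions need not sum to 100% (the remainder being protein);
    they are renormalized over the listed lipid phases.
    """
    wsum = sum(f for _, f in phases)
    return sum(t * f for t, f in phases) / wsum


def multiply_covered_fraction(phi_p: float) -> float:
    """Expected fraction of the plane covered by more than one Boolean disc.

    With covered fraction ``phi = 1 - exp(-theta A)``, the mean total disc
    area per unit plane area is ``theta A``; the excess over the covered
    fraction, ``theta A - phi``, is the expected multiply-covered area
    (every extra layer of overlap counts the area again).  Below ~4% of
    space at phi = 0.25.
    """
    if not 0 <= phi_p < 1:
        raise ValueError("phi_p must lie in [0, 1)")
    theta_A = -math.log1p(-phi_p)
    return theta_A - phi_p


def default_bilayer(radiation: str, l_C: float = DEFAULT_L_C,
                    l_H: float = DEFAULT_L_H) -> SymmetricBilayer:
    """Reference RBC bilayer (l_S = 0: the protein spans the membrane)."""
    t = SLD_TABLES[radiation]
    return SymmetricBilayer(l_C=l_C, l_H=l_H, l_S=0.0, rho_C=t["rho_C"],
                            rho_H=t["rho_H"], rho_S=t["rho_W"], rho_W=t["rho_W"])


def default_protein(radiation: str, lateral_model: str = "boolean",
                    phi_p: float = TRANSMEMBRANE_FRACTION,
                    D_p: float = 0.0,
                    dimer: bool = False) -> ProteinSpec:
    """Band 3 as an equivalent cylinder (or dimer ellipse) at fraction phi_p."""
    if dimer:
        shape = ("ellipse",) + BAND3_DIMER_SEMIAXES
    else:
        shape = ("disc", equivalent_disc_radius(*BAND3_MONOMER_SEMIAXES))
    return ProteinSpec.from_phi(shape, phi_p, slds=SLD_TABLES[radiation]["rho_p"],
                                lateral_model=lateral_model, D_p=D_p)


def default_gaussian(l_alpha: float = DEFAULT_L_ALPHA,
                     l_xy: float = DEFAULT_L_XY,
                     D: float = 0.0) -> GaussianMembraneParams:
    return GaussianMembraneParams(l_alpha, l_xy, D)
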