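"""Membrane scattering-length-density profiles.

A membrane is described as a stack of homogeneous slabs along the normal
direction ``z``.  Each slab has a scattering length density (SLD, units
1/Angstrom^2) and the stack is bounded by strictly increasing z coordinates.
Everything outside the stack is solvent.  The 1D Fourier amplitude of the
profile (contrasted either with the void or with the solvent) is available in
closed form and is the basic ingredient of every intensity in this package.

Transmembrane proteins are represented as cylinders normal to the membrane
plane; within layer ``n`` the cylinder interior carries its own SLD
``rho_p^(n)``.  Their only effect on the 1D profile is to replace each layer
SLD either by an *average* value ``(1-phi_p) rho + phi_p rho_p`` or by its
*contrast* ``rho - rho_p`` with the protein; both replacements are provided
here and consumed by the intensity modules.

Units package-wide: Angstrom (A), A^-1, A^-2, ns, A^2/ns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LayerStack",
    "SymmetricBilayer",
    "ProteinSpec",
    "expand_bilayer",
    "slab_amplitude",
    "protein_corrected_slds",
    "phi_theta_convert",
]


class ValidationError(ValueError):
    """Raised when a geometric or physical precondition is violated."""


@dataclass(frozen=True)
class LayerStack:
    """Piecewise-constant SLD profile.

    Parameters
    ----------
    boundaries : sequence of float
        Strictly increasing z coordinates ``a_0 < a_1 < ... < a_N`` (A).
        There are ``N`` layers, layer ``n`` occupying ``[a_n, a_{n+1})``.
    slds : sequence of float
        One SLD (A^-2) per layer.  A "bogus" layer with the solvent SLD may
        be appended on either side to host protruding protein parts.
    solvent_sld : float
        SLD of the solvent filling all space outside the stack.
    """

    boundaries: tuple[float, ...]
    slds: tuple[float, ...]
    solvent_sld: float = 0.0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        s = np.asarray(self.slds, dtype=float)
        object.__setattr__(self, "boundaries", tuple(b.tolist()))
        object.__setattr__(self, "slds", tuple(s.tolist()))
        if b.size != s.size + 1:
            raise ValidationError(
                f"need len(boundaries) == len(slds)+1, got {b.size} and {s.size}"
            )
        if s.size and np.any(np.diff(b) <= 0):
            raise ValidationError("boundaries must be strictly increasing")

    @property
    def n_layers(self) -> int:
        return len(self.slds)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.diff(np.asarray(self.boundaries))

    def sld_profile(self, z: np.ndarray) -> np.ndarray:
        """Evaluate rho(z) (solvent outside the stack)."""
        z = np.asarray(z, dtype=float)
        out = np.full(z.shape, self.solvent_sld)
        b = np.asarray(self.boundaries)
        for n, rho in enumerate(self.slds):
            out = np.where((z >= b[n]) & (z < b[n + 1]), rho, out)
        return out

    def cumulative_contrast(self, z: np.ndarray, reference_sld: float) -> np.ndarray:
        """Integral of ``rho(z') - reference_sld`` over the stack up to z.

        Only the stack's interior contributes (outside, the profile is the
        solvent, which is *not* included; callers wanting solvent contrast
        pass ``reference_sld = solvent_sld`` so the exterior vanishes anyway).
        Piecewise linear in z; exact.
        """
        z = np.asarray(z, dtype=float)
        b = np.asarray(self.boundaries)
        out = np.zeros(z.shape)
        for n, rho in enumerate(self.slds):
            lo, hi = b[n], b[n + 1]
            out += (rho - reference_sld) * (np.clip(z, lo, hi) - lo)
        return out

    def with_slds(self, slds: Sequence[float]) -> "LayerStack":
        return LayerStack(self.boundaries, tuple(float(s) for s in slds), self.solvent_sld)


@dataclass(frozen=True)
class SymmetricBilayer:
    """Symmetric bilayer: chain half-layer l_C, head l_H, protruding solvated
    layer l_S on each side, with SLDs rho_C, rho_H, rho_S and solvent rho_W.

    Expands to a 6-layer stack S|H|C|C|H|S spanning ``[-(l_C+l_H+l_S),
    +(l_C+l_H+l_S)]`` with z=0 at the bilayer midplane.
    """

    l_C: float
    l_H: float
    l_S: float = 0.0
    rho_C: float = 0.0
    rho_H: float = 0.0
    rho_S: float = 0.0
    rho_W: float = 0.0

    def __post_init__(self) -> None:
        if self.l_C < 0 or self.l_H < 0 or self.l_S < 0:
            raise ValidationError("layer thicknesses must be nonnegative")

    @property
    def half_thickness(self) -> float:
        return self.l_C + self.l_H + self.l_S

    def to_stack(self) -> "LayerStack":
        return expand_bilayer(self)


def expand_bilayer(b: SymmetricBilayer) -> LayerStack:
    """Expand a symmetric bilayer into an explicit :class:`LayerStack`.

    Zero-thickness layers are dropped so the stack stays valid; with all
    thicknesses zero the result is solvent only.
    """
    half = [(b.l_S, b.rho_S), (b.l_H, b.rho_H), (b.l_C, b.rho_C)]
    # build outward-in for z<0, then mirror
    layers: list[tuple[float, float]] = [(t, r) for t, r in half if t > 0]
    layers = layers + [(t, r) for t, r in reversed(layers)]
    z = -sum(t for t, _ in layers) / 2.0
    boundaries = [z]
    slds = []
    for t, r in layers:
        z += t
        boundaries.append(z)
        slds.append(r)
    if not slds:  # fully degenerate membrane: solvent everywhere
        return LayerStack((0.0,), (), b.rho_W)
    return LayerStack(tuple(boundaries), tuple(slds), b.rho_W)


@dataclass(frozen=True)
class ProteinSpec:
    """Transmembrane protein treated as a homogeneous cylinder.

    Parameters
    ----------
    shape : ("disc", R_p) or ("ellipse", a, b)
        Cross-section.  Ellipses (semi-axes a >= b, A) are randomly oriented
        in the membrane plane.
    slds : float or sequence of float
        Protein SLD per membrane layer (A^-2).  A scalar is broadcast to all
        layers; per-layer values let protruding solvated parts have their own
        (lower) contrast.
    theta_p : float
        Number of proteins per unit area of the membrane plane (A^-2).
    lateral_model : "boolean" or "harddisc"
        In-plane statistics: freely overlapping discs on a Poisson process,
        or non-overlapping hard discs (elastic scattering only).
    D_p : float
        In-plane diffusion coefficient (A^2/ns); 0 means static.
    """

    shape: tuple
    slds: float | tuple[float, ...] = 0.0
    theta_p: float = 0.0
    lateral_model: Literal["boolean", "harddisc"] = "boolean"
    D_p: float = 0.0

    def __post_init__(self) -> None:
        kind = self.shape[0]
        if kind == "disc":
            if self.shape[1] <= 0:
                raise ValidationError("disc radius must be positive")
        elif kind == "ellipse":
            a, bb = self.shape[1], self.shape[2]
            if not (a >= bb > 0):
                raise ValidationError("ellipse semi-axes must satisfy a >= b > 0")
        else:
            raise ValidationError(f"unknown shape {kind!r}")
        if self.theta_p < 0:
            raise ValidationError("theta_p must be nonnegative")
        if self.D_p < 0:
            raise ValidationError("D_p must be nonnegative")
        if self.lateral_model not in ("boolean", "harddisc"):
            raise ValidationError(f"unknown lateral model {self.lateral_model!r}")
        if self.phi_p >= 1.0:
            raise ValidationError("protein volume fraction must be < 1")

    @property
    def area(self) -> float:
        """Cross-sectional area A_p (A^2)."""
        if self.shape[0] == "disc":
            return math.pi * self.shape[1] ** 2
        return math.pi * self.shape[1] * self.shape[2]

    @property
    def radius_equivalent(self) -> float:
        """Radius of the disc with the same area as the cross-section."""
        return math.sqrt(self.area / math.pi)

    @property
    def harddisc_radius(self) -> float:
        """Radius entering the hard-disc structure factor.

        For ellipses the exclusion radius is identified with the semi-major
        axis (the in-plane footprint that governs close approach).
        """
        if self.shape[0] == "disc":
            return self.shape[1]
        return self.shape[1]

    @property
    def phi_p(self) -> float:
        """Protein area (volume) fraction implied by theta_p and the model."""
        return phi_theta_convert(self.theta_p, self.area, "phi",
                                 model=self.lateral_model)

    def layer_slds(self, stack: LayerStack) -> np.ndarray:
        """Protein SLD per layer of *stack* (scalar broadcast if needed)."""
        if np.isscalar(self.slds):
            return np.full(stack.n_layers, float(self.slds))
        s = np.asarray(self.slds, dtype=float)
        if s.size != stack.n_layers:
            raise ValidationError(
                f"protein has {s.size} layer SLDs but stack has {stack.n_layers} layers"
            )
        return s

    @staticmethod
    def from_phi(shape: tuple, phi_p: float, *, slds=0.0,
                 lateral_model: str = "boolean", D_p: float = 0.0) -> "ProteinSpec":
        """Build a spec from a target area fraction instead of theta_p."""
        if shape[0] == "disc":
            area = math.pi * shape[1] ** 2
        else:
            area = math.pi * shape[1] * shape[2]
        theta = phi_theta_convert(phi_p, area, "theta", model=lateral_model)
        return ProteinSpec(shape, slds=slds, theta_p=theta,
                           lateral_model=lateral_model, D_p=D_p)


def slab_amplitude(stack: LayerStack, q_z, reference_sld: float = 0.0) -> np.ndarray:
    """1D Fourier amplitude per unit area of the contrasted profile.

    rho(q_z) = sum_n (rho_n - reference_sld) * int_{a_n}^{a_{n+1}} e^{i q_z z} dz

    ``reference_sld`` is the density subtracted before transforming: 0 for
    contrast with the void, the solvent SLD for contrast with the solvent.
    Only the stack interior contributes (with solvent reference the exterior
    is identically zero; with void reference the exterior is ignored, which
    is the standard finite-film convention).

    Returns a complex array, shape of ``q_z``.  For a profile symmetric about
    z = 0 the imaginary part is identically zero (up to rounding).
    """
    q = np.asarray(q_z, dtype=float)
    b = np.asarray(stack.boundaries)
    rho = np.asarray(stack.slds) - reference_sld
    out = np.zeros(np.broadcast(q, 0.0).shape, dtype=complex)
    qs = np.where(q == 0.0, 1.0, q)  # placeholder, q=0 handled analytically
    for n in range(stack.n_layers):
        seg = (np.exp(1j * qs * b[n + 1]) - np.exp(1j * qs * b[n])) / (1j * qs)
        seg = np.where(q == 0.0, b[n + 1] - b[n], seg)
        out = out + rho[n] * seg
    return out


def protein_corrected_slds(stack: LayerStack, p: ProteinSpec,
                           mode: Literal["average", "contrast"]) -> LayerStack:
    """Replace each layer SLD by its protein-corrected value.

    mode="average":  rho^(a)_n = (1 - phi_p) rho_n + phi_p rho_p^(n)
    mode="contrast": rho^(c)_n = rho_n - rho_p^(n)

    Geometry is unchanged.  The averaged stack keeps the solvent SLD (proteins
    confined to the stack do not alter the solvent; protruding parts are
    modelled with explicit bogus layers).  The contrast stack is referenced to
    zero outside the membrane, so its solvent SLD is set to 0.
    """
    rho = np.asarray(stack.slds)
    rho_p = p.layer_slds(stack)
    if mode == "average":
        phi = p.phi_p
        out = LayerStack(stack.boundaries, tuple((1 - phi) * rho + phi * rho_p),
                         stack.solvent_sld)
    elif mode == "contrast":
        out = LayerStack(stack.boundaries, tuple(rho - rho_p), 0.0)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return out


def phi_theta_convert(value: float, A_p: float,
                      to: Literal["phi", "theta"],
                      model: Literal["boolean", "harddisc"] = "boolean") -> float:
    """Convert between number density theta_p and area fraction phi_p.

    Boolean (overlapping) model: phi = 1 - exp(-theta A); hard discs cannot
    overlap, so phi = theta A.  The inverse Boolean relation requires
    phi < 1.
    """
    if A_p <= 0:
        raise ValidationError("A_p must be positive")
    if value < 0:
        raise ValidationError("densities and fractions are nonnegative")
    if to == "phi":
        ta = value * A_p
        return 1.0 - math.exp(-ta) if model == "boolean" else ta
    if to == "theta":
        if model == "boolean":
            if value >= 1.0:
                raise ValidationError("Boolean inverse needs phi < 1")
            return -math.log1p(-value) / A_p
        return value / A_p
    raise ValidationError(f"unknown direction {to!r}")
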