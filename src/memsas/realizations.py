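"""Voxelized space(-time) realizations of the model and an FFT oracle.

The simulator draws periodic realizations of (i) the Gaussian height field
with covariance ``l_alpha^2 g_W`` by spectral synthesis (each Fourier mode
is an independent complex Gaussian whose time evolution is an AR(1) process
with per-mode correlation ``exp(-q^2 D tau)``, the spectral transcription of
the diffusing-wave-packet covariance) and (ii) Boolean disc centres on a
Poisson point process performing 2D Brownian motion.  A 3D voxel grid then
receives the solvent-contrasted SLD: every column takes the membrane (or,
where covered by a disc, the protein) profile rigidly shifted by the local
height, voxel-averaged exactly along z.  The squared FFT modulus per unit
area, shell-binned with shell width equal to the vertical mode spacing
``2 pi / L_z``, is an unbiased numerical estimate of the rotationally
averaged per-unit-area intensity; :func:`lattice_expected_intensity` bins
the analytic model over the identical reciprocal lattice so the two can be
compared mode-for-mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import j0

from . import inplane
from .curves import ScatteringCurve
from .gaussian import GaussianMembraneParams, gw_covariance
from .profiles import (LayerStack, ProteinSpec, SymmetricBilayer,
                       ValidationError, expand_bilayer, protein_corrected_slds,
                       slab_amplitude)
from .slab import _as_stack

log = logging.getLogger(__name__)

__all__ = [
    "sample_height_field",
    "sample_boolean_discs",
    "coverage_mask",
    "voxelize",
    "voxelize_and_fft_intensity",
    "lattice_expected_intensity",
    "fft_intensity_ensemble",
]


def _lateral_wavenumbers(L: float, n: int) -> np.ndarray:
    return 2.0 * math.pi * np.fft.fftfreq(n, d=L / n)


def sample_height_field(g: GaussianMembraneParams, L: float, n: int,
                        seed: int, times=None) -> np.ndarray:
    """Periodic Gaussian height field(s) with covariance l_alpha^2 g_W.

    Returns an array of shape (len(times), n, n) (times defaults to [0]).
    Spectral synthesis on the torus: mode variances are the DFT of the
    wrapped covariance, so the sample covariance is exact at every lattice
    lag; successive times share modes through AR(1) factors exp(-q^2 D dt).
    Deterministic for a given seed.
    """
    if n & (n - 1):
        raise ValidationError("n must be a power of two")
    if L < 8.0 * g.l_xy:
        log.warning("box L = %.0f A < 8 l_xy = %.0f A: covariance truncation",
                    L, 8.0 * g.l_xy)
    times = np.atleast_1d(np.asarray([0.0] if times is None else times, float))
    rng = np.random.default_rng(seed)
    k = _lateral_wavenumbers(L, n)
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    # per-mode eigenvalues from the analytic spectrum of g_W (the 2D FT of
    # the covariance); positive and smooth, unlike the DFT of the wrapped
    # covariance whose seam kink leaks spurious high-k power
    dx2 = (L / n) ** 2
    lam = (g.l_alpha**2 * 4.0 * math.pi * g.l_xy**2
           * np.exp(-k2 * g.l_xy**2) / dx2)
    Y = np.sqrt(lam) * np.fft.fft2(rng.standard_normal((n, n)))
    out = np.empty((times.size, n, n))
    t_prev = times[0]
    out[0] = np.fft.ifft2(Y).real
    for j in range(1, times.size):
        dt = times[j] - t_prev
        if dt < 0:
            raise ValidationError("times must be nondecreasing")
        r = np.exp(-k2 * g.D * dt)
        Y = r * Y + np.sqrt(lam * (1.0 - r**2)) * np.fft.fft2(
            rng.standard_normal((n, n)))
        out[j] = np.fft.ifft2(Y).real
        t_prev = times[j]
    return out


def sample_boolean_discs(p: ProteinSpec, L: float, seed: int,
                         times=None) -> np.ndarray:
    """Poisson disc centres (mean theta_p L^2) with Brownian motion.

    Returns (len(times), N, 2) positions wrapped into [0, L).
    """
    if p.lateral_model != "boolean":
        raise ValidationError("realizations use the Boolean (overlapping) model")
    times = np.atleast_1d(np.asarray([0.0] if times is None else times, float))
    rng = np.random.default_rng(seed)
    N = rng.poisson(p.theta_p * L * L)
    pos = rng.uniform(0.0, L, size=(N, 2))
    out = np.empty((times.size, N, 2))
    out[0] = pos
    for j in range(1, times.size):
        dt = times[j] - times[j - 1]
        if dt < 0:
            raise ValidationError("times must be nondecreasing")
        step = rng.normal(0.0, math.sqrt(2.0 * p.D_p * dt), size=(N, 2))
        pos = (pos + step) % L
        out[j] = pos
    return out


def coverage_mask(centers: np.ndarray, L: float, n: int, R: float) -> np.ndarray:
    """Boolean (n, n) mask of grid columns covered by >= 1 disc (periodic)."""
    xs = (np.arange(n) + 0.5) * (L / n)
    mask = np.zeros((n, n), dtype=bool)
    for cx, cy in np.atleast_2d(centers):
        dx = (xs - cx + 0.5 * L) % L - 0.5 * L
        dy = (xs - cy + 0.5 * L) % L - 0.5 * L
        mask |= dx[:, None] ** 2 + dy[None, :] ** 2 <= R * R
    return mask


def _cum_contrast(stack: LayerStack, slds: np.ndarray):
    """Breakpoints and cumulative integral of (slds - solvent) for interp."""
    b = np.asarray(stack.boundaries)
    contr = np.asarray(slds) - stack.solvent_sld
    cum = np.concatenate([[0.0], np.cumsum(contr * np.diff(b))])
    return b, cum


def _smooth_profile(stack: LayerStack, slds: np.ndarray, z: np.ndarray,
                    sigma: float) -> np.ndarray:
    """Solvent-contrasted profile convolved with a Gaussian of width sigma."""
    from scipy.special import ndtr
    b = np.asarray(stack.boundaries)
    contr = np.asarray(slds) - stack.solvent_sld
    out = np.zeros(z.shape)
    for nlay in range(stack.n_layers):
        out += contr[nlay] * (ndtr((z - b[nlay]) / sigma)
                              - ndtr((z - b[nlay + 1]) / sigma))
    return out


def voxelize(height: np.ndarray, covered: np.ndarray | None,
             stack: LayerStack, p: ProteinSpec | None,
             Lz: float, nz: int, smear_z: float | None = None) -> np.ndarray:
    """Solvent-contrasted SLD on an (n, n, nz) voxel grid.

    Each lateral column carries the membrane (or protein, where covered)
    profile rigidly shifted by the local height.  By default the profile is
    apodized with a Gaussian of width ``smear_z = 1.25 dz`` before point
    sampling: the sampled field is then an analytic function of the height
    (no staircase artefacts in the lateral spectrum) and z-aliasing is
    suppressed to ~e^-30; the companion analytic expectation carries the
    identical exp(-q_z^2 smear_z^2) intensity factor, so comparisons remain
    exact.  ``smear_z = 0`` switches to exact voxel averages of the sharp
    profile (appropriate for static, height-free fields).
    """
    stack = _as_stack(stack)
    n = height.shape[0]
    dz = Lz / nz
    if stack.n_layers and dz > np.min(stack.thicknesses) / 2.0:
        raise ValidationError(
            f"voxel dz = {dz:.2f} A under-resolves the thinnest layer "
            f"({np.min(stack.thicknesses):.2f} A); decrease dz below half of it"
        )
    if smear_z is None:
        smear_z = 1.25 * dz
    z_edges = -0.5 * Lz + dz * np.arange(nz + 1)
    z_mid = z_edges[:-1] + 0.5 * dz
    out = np.empty((n, n, nz))
    if smear_z > 0:
        mem_slds = np.asarray(stack.slds)
        prot_slds = p.layer_slds(stack) if p is not None else None
        if not height.any():  # static slab: only two distinct column profiles
            prof_m = _smooth_profile(stack, mem_slds, z_mid, smear_z)
            if p is not None and covered is not None:
                prof_p = _smooth_profile(stack, prot_slds, z_mid, smear_z)
                return np.where(covered[:, :, None], prof_p[None, None, :],
                                prof_m[None, None, :])
            out[:] = prof_m[None, None, :]
            return out
        for i in range(n):
            zloc = z_mid[None, :] - height[i][:, None]  # (n, nz)
            col = _smooth_profile(stack, mem_slds, zloc, smear_z)
            if p is not None and covered is not None and covered[i].any():
                colp = _smooth_profile(stack, prot_slds, zloc, smear_z)
                col = np.where(covered[i][:, None], colp, col)
            out[i] = col
        return out
    mem_bp, mem_cum = _cum_contrast(stack, np.asarray(stack.slds))
    if p is not None:
        prot_bp, prot_cum = _cum_contrast(stack, p.layer_slds(stack))
    for i in range(n):
        edges = z_edges[None, :] - height[i][:, None]  # (n, nz+1)
        cm = np.interp(edges, mem_bp, mem_cum)
        col = np.diff(cm, axis=1) / dz
        if p is not None and covered is not None and covered[i].any():
            cp_ = np.interp(edges, prot_bp, prot_cum)
            colp = np.diff(cp_, axis=1) / dz
            col = np.where(covered[i][:, None], colp, col)
        out[i] = col
    return out


def _shell_bin(I_mode: np.ndarray, qmag: np.ndarray, L: float, Lz: float,
               q_max: float):
    """Bin per-mode intensities into isotropic shells of width 2 pi / Lz.

    Returns (q_centers, I) where I approximates the rotationally averaged
    per-unit-area intensity: shell sums are multiplied by the reciprocal
    cell volume and divided by the shell volume 4 pi q^2 dq.
    """
    dq = 2.0 * math.pi / Lz
    dk_cell = (2.0 * math.pi / L) ** 2 * dq
    idx = np.rint(qmag / dq).astype(np.int64)
    mmax = int(q_max / dq)
    sums = np.bincount(idx.ravel(), weights=I_mode.ravel(),
                       minlength=mmax + 1)[: mmax + 1]
    m = np.arange(1, mmax + 1)
    q = m * dq
    I = dk_cell * sums[1:] / (4.0 * math.pi * q**2 * dq)
    return q, I


def _qmag_grid(L: float, n: int, Lz: float, nz: int):
    k = _lateral_wavenumbers(L, n)
    kz = 2.0 * math.pi * np.fft.fftfreq(nz, d=Lz / nz)
    return np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2
                   + kz[None, None, :] ** 2), kz


def voxelize_and_fft_intensity(height: np.ndarray, covered: np.ndarray | None,
                               stack: LayerStack, p: ProteinSpec | None,
                               L: float, Lz: float, nz: int,
                               q_max: float = 0.5,
                               smear_z: float | None = None) -> ScatteringCurve:
    """Shell-binned per-unit-area intensity of one voxelized realization."""
    stack = _as_stack(stack)
    n = height.shape[0]
    field = voxelize(height, covered, stack, p, Lz, nz, smear_z)
    dV = (L / n) ** 2 * (Lz / nz)
    amp = np.fft.fftn(field) * dV
    I_mode = np.abs(amp) ** 2 / (L * L)
    qmag, _ = _qmag_grid(L, n, Lz, nz)
    q, I = _shell_bin(I_mode, qmag, L, Lz, q_max)
    return ScatteringCurve(q, I)


def _sinc(x: np.ndarray) -> np.ndarray:
    return np.sinc(x / math.pi)


def _lattice_amp2(stack: LayerStack, reference_sld: float, kz_abs: np.ndarray,
                  Lz: float, nz: int, smear_z: float) -> np.ndarray:
    """|amplitude|^2 of the discretized profile on the vertical mode grid."""
    dz = Lz / nz
    if smear_z > 0:
        amp = slab_amplitude(stack, kz_abs, reference_sld)
        return np.abs(amp) ** 2 * np.exp(-(kz_abs * smear_z) ** 2)
    # exact voxel-average route: discrete transform of the averaged profile
    ref_stack = LayerStack(stack.boundaries, stack.slds, reference_sld)
    vox = voxelize(np.zeros((1, 1)), None, ref_stack, None, Lz, nz, 0.0)[0, 0]
    return np.abs(np.fft.fft(vox) * dz) ** 2


def lattice_expected_intensity(stack: LayerStack | SymmetricBilayer,
                               g: GaussianMembraneParams | None,
                               p: ProteinSpec | None,
                               L: float, n: int, Lz: float, nz: int,
                               tau: float = 0.0,
                               q_max: float = 0.5,
                               smear_z: float | None = None) -> ScatteringCurve:
    """Analytic expectation of the FFT estimator, binned identically.

    Evaluates the model's expected per-mode intensity on the same discrete
    reciprocal lattice as the simulation (including the z apodization
    factor and the q_xy = 0 mean-structure modes) and applies the same
    shell binning, making analytic-vs-realization comparisons free of
    binning bias.
    """
    stack = _as_stack(stack)
    dz = Lz / nz
    if smear_z is None:
        smear_z = 1.25 * dz
    if p is not None:
        avg = protein_corrected_slds(stack, p, "average")
        con = protein_corrected_slds(stack, p, "contrast")
    else:
        avg, con = stack, None
    la = 0.0 if g is None else g.l_alpha
    qmag, kz = _qmag_grid(L, n, Lz, nz)
    kz_abs = np.abs(kz)
    amp2_a = _lattice_amp2(avg, avg.solvent_sld, kz_abs, Lz, nz, smear_z)
    # radial grids and correlation tables for the continuum (fluctuation) part
    S_planes = np.zeros((nz, 1))
    qxy_fine = None
    need_fluct = (g is not None and la > 0.0) or p is not None
    if need_fluct:
        supports = []
        if g is not None and la > 0.0:
            supports.append(8.0 * g.l_xy * math.sqrt(1.0 + tau * g.D / g.l_xy**2))
        if p is not None:
            supports.append(inplane._r_support(p, tau))
        r = np.linspace(0.0, max(supports), 4096)
        wr = np.gradient(r) * r
        gv = gw_covariance(r, tau, g) if g is not None else np.zeros_like(r)
        cp = inplane.boolean_correlation(r, p, tau) if p is not None else None
        if con is not None:
            amp2_c = _lattice_amp2(con, 0.0, kz_abs, Lz, nz, smear_z)
        qxy_max = min(q_max, qmag[..., 0].max()) + 2.0 * math.pi / L
        qxy_fine = np.linspace(0.0, qxy_max, 512)
        kern = j0(np.outer(qxy_fine, r)) * wr[None, :]  # (nqxy, nr)
        S_planes = np.zeros((nz, qxy_fine.size))
        for iz in range(nz):
            if kz_abs[iz] > q_max + 2.0 * math.pi / Lz:
                continue
            e_full = np.exp(-(kz[iz] * la) ** 2 * (1.0 - gv))
            f = np.zeros_like(r)
            if la > 0.0:
                f += amp2_a[iz] * (e_full - math.exp(-(kz[iz] * la) ** 2))
            if p is not None:
                f += amp2_c[iz] * cp * e_full
            S_planes[iz] = 2.0 * math.pi * (kern @ f)
    # assemble per-mode expectation
    I_mode = np.zeros((n, n, nz))
    if need_fluct:
        k = _lateral_wavenumbers(L, n)
        qxy_mag = np.hypot(k[:, None], k[None, :])
        flat = qxy_mag.ravel()
        for iz in range(nz):
            if kz_abs[iz] > q_max + 2.0 * math.pi / Lz:
                continue
            I_mode[:, :, iz] = np.interp(flat, qxy_fine, S_planes[iz],
                                         right=0.0).reshape(n, n)
    I_mode[0, 0, :] += (L * L) * amp2_a * np.exp(-((kz_abs * la) ** 2))
    q, I = _shell_bin(I_mode, qmag, L, Lz, q_max)
    return ScatteringCurve(q, I)


@dataclass
class EnsembleIntensity:
    """Seed-averaged FFT intensity with its Monte-Carlo standard error."""

    q: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_seeds: int


def fft_intensity_ensemble(stack: LayerStack | SymmetricBilayer,
                           g: GaussianMembraneParams | None,
                           p: ProteinSpec | None,
                           L: float, n: int, Lz: float, nz: int,
                           seeds: int, base_seed: int = 0,
                           q_max: float = 0.5,
                           smear_z: float | None = None) -> EnsembleIntensity:
    """Average :func:`voxelize_and_fft_intensity` over independent seeds."""
    stack = _as_stack(stack)
    acc = []
    q = None
    for s in range(seeds):
        seed = base_seed + s
        if g is not None and g.l_alpha > 0:
            h = sample_height_field(g, L, n, seed)[0]
        else:
            h = np.zeros((n, n))
        cov = None
        if p is not None:
            centers = sample_boolean_discs(p, L, seed + 10_000)[0]
            cov = coverage_mask(centers, L, n, p.radius_equivalent)
        curve = voxelize_and_fft_intensity(h, cov, stack, p, L, Lz, nz, q_max,
                                           smear_z)
        q = curve.q
        acc.append(curve.I)
    arr = np.asarray(acc)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / math.sqrt(seeds) if seeds > 1 else np.zeros_like(mean)
    return EnsembleIntensity(q, mean, se, seeds)
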