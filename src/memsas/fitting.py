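"""Weighted least-squares fitting of elastic curves and NSE surfaces.

The interface follows the Model/Results convention of statistical modelling
packages: a model object is built from data plus fixed structural inputs,
``fit()`` runs bounded least squares (multi-start, seeded) and returns a
results object carrying parameter estimates, curvature-based uncertainties,
goodness of fit and a ``summary()`` table.

Elastic fits share the membrane geometry (l_C, l_H, and for the Gaussian
membrane l_alpha, l_xy) across datasets while each dataset keeps its own
radiation-specific SLD table, free intensity scale and optional flat
background.  Residuals are weighted by 1/sigma when uncertainties are
supplied and by 1/I otherwise (Poisson-like).  NSE fits hold every
structural parameter fixed and adjust the single wave-packet diffusion
coefficient D against the full (q, tau) surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.special import j0

from . import inplane, rbc
from .curves import ISFSurface, ScatteringCurve
from .gaussian import (GaussianMembraneParams, average_term, gw_covariance)
from .profiles import (ProteinSpec, SymmetricBilayer, ValidationError,
                       protein_corrected_slds, slab_amplitude)
from .slab import MU_ORDER, _mu_nodes, slab_intensity

__all__ = ["ElasticModel", "ElasticResults", "NSEModel", "NSEResults",
           "fit_elastic", "fit_nse"]

DEFAULT_Q_RANGE = (8e-3, 0.5)


def _chunks(n: int, size: int):
    for i in range(0, n, size):
        yield slice(i, min(i + size, n))


def _weights(curve: ScatteringCurve) -> np.ndarray:
    if curve.sigma is not None:
        return 1.0 / curve.sigma
    return 1.0 / np.abs(curve.I)


def _protein_for(radiation: str, lateral_model: str, phi_p: float,
                 dimer: bool, table: dict) -> ProteinSpec:
    if dimer:
        shape = ("ellipse",) + rbc.BAND3_DIMER_SEMIAXES
    else:
        shape = ("disc", rbc.equivalent_disc_radius(*rbc.BAND3_MONOMER_SEMIAXES))
    return ProteinSpec.from_phi(shape, phi_p, slds=table["rho_p"],
                                lateral_model=lateral_model)


class _SlabEvaluator:
    """Per-dataset slab intensity with the protein in-plane grid cached."""

    def __init__(self, q: np.ndarray, table: dict, protein: ProteinSpec | None,
                 order: int = MU_ORDER):
        self.q = q
        self.table = table
        self.protein = protein
        self.mu, self.w = _mu_nodes(order)
        if protein is not None:
            qxy = q[:, None] * np.sqrt(1.0 - self.mu[None, :] ** 2)
            self.Ip = inplane.inplane_intensity(qxy, protein, 0.0)
        else:
            self.Ip = None

    def _bilayer(self, l_C: float, l_H: float) -> SymmetricBilayer:
        t = self.table
        return SymmetricBilayer(l_C, l_H, 0.0, t["rho_C"], t["rho_H"],
                                t["rho_W"], t["rho_W"])

    def __call__(self, l_C: float, l_H: float, **_) -> np.ndarray:
        stack = self._bilayer(l_C, l_H).to_stack()
        if self.protein is None:
            return slab_intensity(stack, self.q).I
        avg = protein_corrected_slds(stack, self.protein, "average")
        con = protein_corrected_slds(stack, self.protein, "contrast")
        mem = slab_intensity(avg, self.q).I
        qz = self.q[:, None] * self.mu[None, :]
        amp2 = np.abs(slab_amplitude(con, qz, 0.0)) ** 2
        return mem + (amp2 * self.Ip) @ self.w


class _GaussianEvaluator:
    """Per-dataset Gaussian-membrane intensity with J0 kernels cached.

    The radial grid is fixed from an upper bound on l_xy so the (q, mu, r)
    Bessel kernel can be reused across optimizer iterations.
    """

    def __init__(self, q: np.ndarray, table: dict, protein: ProteinSpec | None,
                 order: int = MU_ORDER, n_r: int = 2048,
                 l_xy_max: float = 150.0):
        self.q = q
        self.table = table
        self.protein = protein
        self.mu, self.w = _mu_nodes(order)
        self.r = np.linspace(0.0, 8.0 * l_xy_max, n_r)
        wr = np.gradient(self.r) * self.r
        qxy = q[:, None] * np.sqrt(1.0 - self.mu[None, :] ** 2)
        self.kern = (j0(qxy[..., None] * self.r[None, None, :])
                     * wr[None, None, :]).astype(np.float32)
        self.cp = (None if protein is None
                   else inplane.boolean_correlation(self.r, protein, 0.0))

    def _bilayer(self, l_C, l_H):
        t = self.table
        return SymmetricBilayer(l_C, l_H, 0.0, t["rho_C"], t["rho_H"],
                                t["rho_W"], t["rho_W"])

    def __call__(self, l_C, l_H, l_alpha=0.0, l_xy=rbc.DEFAULT_L_XY, **_):
        g = GaussianMembraneParams(l_alpha, l_xy, 0.0)
        stack = self._bilayer(l_C, l_H).to_stack()
        if self.protein is not None:
            avg = protein_corrected_slds(stack, self.protein, "average")
            con = protein_corrected_slds(stack, self.protein, "contrast")
        else:
            avg, con = stack, None
        out = average_term(avg, g, self.q)
        gv = gw_covariance(self.r, 0.0, g)
        qz = self.q[:, None] * self.mu[None, :]
        la2 = g.l_alpha**2
        amp2_a = np.abs(slab_amplitude(avg, qz, avg.solvent_sld)) ** 2
        amp2_c = (None if con is None
                  else np.abs(slab_amplitude(con, qz, 0.0)) ** 2)
        extra = np.zeros(self.q.size)
        for sl in _chunks(self.q.size, 16):
            e_full = np.exp(-(qz[sl] ** 2 * la2)[..., None]
                            * (1.0 - gv[None, None, :]))
            if la2 > 0:
                f = amp2_a[sl][..., None] * (
                    e_full - np.exp(-(qz[sl] ** 2 * la2))[..., None])
            else:
                f = np.zeros_like(e_full)
            if amp2_c is not None:
                f += amp2_c[sl][..., None] * self.cp[None, None, :] * e_full
            H = 2.0 * math.pi * np.einsum(
                "qmr,qmr->qm", f, self.kern[sl].astype(f.dtype))
            extra[sl] = H @ self.w
        return out + extra


_GEOM_DEFAULTS = {"l_C": rbc.DEFAULT_L_C, "l_H": rbc.DEFAULT_L_H,
                  "l_alpha": rbc.DEFAULT_L_ALPHA, "l_xy": rbc.DEFAULT_L_XY}
_GEOM_BOUNDS = {"l_C": (5.0, 40.0), "l_H": (0.5, 20.0),
                "l_alpha": (0.0, 80.0), "l_xy": (20.0, 150.0)}


@dataclass
class ElasticResults:
    """Elastic fit results: estimates, uncertainties and diagnostics."""

    params: dict
    stderr: dict
    chisqr: float
    dof: int
    fixed: dict
    datasets: list
    model_curves: list
    start_chisqr: float
    success: bool

    @property
    def redchi(self) -> float:
        return self.chisqr / max(self.dof, 1)

    @property
    def total_thickness(self) -> float:
        """Derived total membrane thickness 2 (l_C + l_H), A."""
        return 2.0 * (self.params["l_C"] + self.params["l_H"])

    def summary(self) -> str:
        lines = ["Elastic membrane fit", "=" * 54,
                 f"{'parameter':<14}{'value':>14}{'std err':>14}"]
        for k, v in self.params.items():
            se = self.stderr.get(k)
            lines.append(f"{k:<14}{v:>14.5g}{'' if se is None else format(se, '>14.3g')}")
        lines.append("-" * 54)
        lines.append(f"chi^2 / dof = {self.chisqr:.4g} / {self.dof} "
                     f"(reduced {self.redchi:.4g})")
        lines.append(f"total thickness 2(l_C+l_H) = {self.total_thickness:.2f} A")
        for k, v in self.fixed.items():
            lines.append(f"fixed: {k} = {v}")
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({"params": self.params, "stderr": self.stderr,
                           "chisqr": self.chisqr, "dof": self.dof,
                           "redchi": self.redchi,
                           "total_thickness_A": self.total_thickness,
                           "fixed": {k: str(v) for k, v in self.fixed.items()},
                           "success": self.success}, indent=2)


class ElasticModel:
    """Joint weighted least-squares model for elastic scattering curves.

    Parameters
    ----------
    datasets : list of ScatteringCurve
        One or more curves; each carries its radiation ("xray"/"neutron"),
        which selects the SLD table.  Geometry is shared across datasets.
    membrane : "slab" or "gaussian"
    protein_model : "boolean", "harddisc" or None
        None removes the protein entirely (bare membrane).
    phi_p : float
        Fixed transmembrane area fraction.
    q_range : (qmin, qmax)
        Fitting window applied to every dataset.
    background : bool
        Include a free flat background per dataset.
    """

    def __init__(self, datasets, membrane: str = "slab",
                 protein_model: str | None = "boolean",
                 phi_p: float = rbc.TRANSMEMBRANE_FRACTION,
                 dimer: bool = False,
                 q_range=DEFAULT_Q_RANGE,
                 background: bool = True,
                 sld_tables: dict | None = None,
                 order: int = MU_ORDER):
        if not datasets:
            raise ValidationError("need at least one dataset")
        if membrane not in ("slab", "gaussian"):
            raise ValidationError(f"unknown membrane model {membrane!r}")
        self.membrane = membrane
        self.background = background
        tables = sld_tables or rbc.SLD_TABLES
        self.data = [c.mask(*q_range) for c in datasets]
        self.fixed = {"membrane": membrane, "protein_model": protein_model,
                      "phi_p": phi_p, "dimer": dimer, "q_range": q_range}
        self._evals = []
        for c in self.data:
            table = tables[c.radiation]
            prot = (None if protein_model is None
                    else _protein_for(c.radiation, protein_model, phi_p,
                                      dimer, table))
            cls = _SlabEvaluator if membrane == "slab" else _GaussianEvaluator
            self._evals.append(cls(c.q, table, prot, order=order))

    @property
    def geometry_names(self):
        base = ["l_C", "l_H"]
        return base + (["l_alpha", "l_xy"] if self.membrane == "gaussian" else [])

    def eval_dataset(self, i: int, scaled: bool = True, **geom) -> np.ndarray:
        shape = self._evals[i](**geom)
        if not scaled:
            return shape
        s, b = self._scale_bg(i, shape)
        return s * shape + b

    def _scale_bg(self, i: int, shape: np.ndarray) -> tuple[float, float]:
        """Profile out scale (and background) analytically per dataset."""
        c = self.data[i]
        w2 = _weights(c) ** 2
        if self.background:
            A = np.array([[np.sum(w2 * shape**2), np.sum(w2 * shape)],
                          [np.sum(w2 * shape), np.sum(w2)]])
            b = np.array([np.sum(w2 * shape * c.I), np.sum(w2 * c.I)])
            try:
                s, bg = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                s, bg = b[0] / max(A[0, 0], 1e-300), 0.0
            if s <= 0:
                s = max(b[0] / max(A[0, 0], 1e-300), 1e-300)
                bg = 0.0
            return float(s), float(bg)
        s = np.sum(w2 * shape * c.I) / max(np.sum(w2 * shape**2), 1e-300)
        return float(max(s, 1e-300)), 0.0

    def _residuals(self, params: lmfit.Parameters) -> np.ndarray:
        geom = {k: params[k].value for k in self.geometry_names}
        res = []
        for i, c in enumerate(self.data):
            shape = self._evals[i](**geom)
            if not np.all(np.isfinite(shape)):
                raise ValidationError("model evaluated to non-finite intensity")
            s, b = self._scale_bg(i, shape)
            res.append((s * shape + b - c.I) * _weights(c))
        return np.concatenate(res)

    def fit(self, free=("l_C", "l_H"), start: dict | None = None,
            bounds: dict | None = None, multistart: int = 5,
            seed: int = 0) -> ElasticResults:
        """Bounded least squares over the free geometry parameters.

        Per-dataset scale and background are profiled out analytically at
        every iteration (they are always effectively free).  ``multistart``
        seeded restarts perturb the starting geometry to guard against local
        minima; the best optimum is kept.
        """
        free = list(free)
        for name in free:
            if name not in self.geometry_names:
                raise ValidationError(f"unknown free parameter {name!r}")
        start = {**_GEOM_DEFAULTS, **(start or {})}
        bnds = {**_GEOM_BOUNDS, **(bounds or {})}
        rng = np.random.default_rng(seed)
        best = None
        for trial in range(max(multistart, 1)):
            params = lmfit.Parameters()
            for name in self.geometry_names:
                v = start[name]
                if trial > 0 and name in free:
                    lo, hi = bnds[name]
                    v = np.clip(v * rng.uniform(0.7, 1.3), lo + 1e-6, hi - 1e-6)
                params.add(name, value=v, min=bnds[name][0], max=bnds[name][1],
                           vary=name in free)
            out = lmfit.minimize(self._residuals, params, method="least_squares")
            if best is None or out.chisqr < best.chisqr:
                best = out
        start_params = lmfit.Parameters()
        for name in self.geometry_names:
            start_params.add(name, value=start[name], vary=False)
        start_chisqr = float(np.sum(self._residuals(start_params) ** 2))
        geom = {k: float(best.params[k].value) for k in self.geometry_names}
        stderr = {k: (float(best.params[k].stderr)
                      if best.params[k].stderr is not None else None)
                  for k in self.geometry_names if k in free}
        curves, pars = [], dict(geom)
        for i, c in enumerate(self.data):
            shape = self._evals[i](**geom)
            s, b = self._scale_bg(i, shape)
            pars[f"scale_{i}"] = s
            pars[f"background_{i}"] = b
            curves.append(ScatteringCurve(c.q, s * shape + b,
                                          radiation=c.radiation))
        npts = sum(c.q.size for c in self.data)
        nfree = len(free) + (2 if self.background else 1) * len(self.data)
        return ElasticResults(pars, stderr, float(best.chisqr),
                              npts - nfree, dict(self.fixed), self.data,
                              curves, start_chisqr, bool(best.success))


@dataclass
class NSEResults:
    """One-parameter NSE fit: diffusion coefficient and correlation time."""

    D: float
    D_stderr: float | None
    chisqr: float
    dof: int
    l_alpha: float
    l_xy: float
    start_chisqr: float
    model: ISFSurface

    @property
    def redchi(self) -> float:
        return self.chisqr / max(self.dof, 1)

    @property
    def correlation_time(self) -> float:
        """tau_c = l_xy^2 / (4 D) (ns): lateral diffusion over a packet size."""
        return math.inf if self.D == 0 else self.l_xy**2 / (4.0 * self.D)

    def summary(self) -> str:
        se = "" if self.D_stderr is None else f" +/- {self.D_stderr:.3g}"
        return "\n".join([
            "NSE one-parameter fit", "=" * 54,
            f"D = {self.D:.4g}{se} A^2/ns",
            f"correlation time tau_c = l_xy^2/(4 D) = {self.correlation_time:.4g} ns",
            f"chi^2 / dof = {self.chisqr:.4g} / {self.dof} (reduced {self.redchi:.4g})",
            f"fixed: l_alpha = {self.l_alpha} A, l_xy = {self.l_xy} A",
        ])


class NSEModel:
    """Weighted least squares for the normalized ISF surface, D free.

    All structural parameters (bilayer geometry, SLDs, protein fraction,
    l_alpha, l_xy) are fixed — typically from an elastic fit — and only the
    wave-packet diffusion coefficient D is adjusted against every (q, tau)
    cell of the surface.
    """

    def __init__(self, surface: ISFSurface, bilayer: SymmetricBilayer,
                 g: GaussianMembraneParams, protein: ProteinSpec | None = None,
                 order: int = MU_ORDER, n_r: int = 2048, D_max: float = 50.0):
        if not surface.has_dynamics:
            raise ValidationError("NSE surface has no tau > 0 points")
        self.surface = surface
        stack = bilayer.to_stack()
        if protein is not None:
            stack = protein_corrected_slds(stack, protein, "average")
        self.stack = stack
        self.g0 = g
        self.q = np.asarray(surface.q, dtype=float)
        self.tau = np.asarray(surface.tau, dtype=float)
        self.mu, self.w = _mu_nodes(order)
        tau_max = float(self.tau.max())
        r_max = 8.0 * g.l_xy * math.sqrt(1.0 + D_max * tau_max / g.l_xy**2)
        self.r = np.linspace(0.0, r_max, n_r)
        wr = np.gradient(self.r) * self.r
        qxy = self.q[:, None] * np.sqrt(1.0 - self.mu[None, :] ** 2)
        self.kern = j0(qxy[..., None] * self.r[None, None, :]) * wr
        qz = self.q[:, None] * self.mu[None, :]
        self.amp2 = np.abs(slab_amplitude(stack, qz, stack.solvent_sld)) ** 2
        self.avg = average_term(stack, g, self.q)
        self.qz2la2 = (qz * g.l_alpha) ** 2

    def isf(self, D: float) -> np.ndarray:
        """Model I(q,tau)/I(q,0) on the surface grid for a trial D."""
        g = GaussianMembraneParams(self.g0.l_alpha, self.g0.l_xy, D)
        taus = np.concatenate([[0.0], self.tau])
        I = np.empty((self.q.size, taus.size))
        for j, t in enumerate(taus):
            gv = gw_covariance(self.r, t, g)
            expo = (np.exp(-self.qz2la2[..., None] * (1.0 - gv[None, None, :]))
                    - np.exp(-self.qz2la2)[..., None])
            H = 2.0 * math.pi * np.einsum("qmr,qmr->qm", self.amp2[..., None] * expo,
                                          self.kern)
            I[:, j] = self.avg + H @ self.w
        return I[:, 1:] / I[:, :1]

    def _residuals(self, D: float) -> np.ndarray:
        model = self.isf(D)
        obs = self.surface.values
        ok = np.isfinite(obs)
        if self.surface.sigma is not None:
            wgt = 1.0 / self.surface.sigma
        else:
            wgt = 1.0 / np.abs(obs)
        return ((model - obs) * wgt)[ok]

    def fit(self, start: float = 1.0, multistart: int = 3,
            seed: int = 0) -> NSEResults:
        rng = np.random.default_rng(seed)
        best = None
        for trial in range(max(multistart, 1)):
            params = lmfit.Parameters()
            v = start if trial == 0 else float(start * rng.uniform(0.3, 3.0))
            params.add("D", value=max(v, 1e-3), min=0.0, max=50.0)
            out = lmfit.minimize(lambda p: self._residuals(p["D"].value),
                                 params, method="least_squares")
            if best is None or out.chisqr < best.chisqr:
                best = out
        D = float(best.params["D"].value)
        se = best.params["D"].stderr
        start_chisqr = float(np.sum(self._residuals(start) ** 2))
        model = ISFSurface(self.q, self.tau, self.isf(D))
        npts = int(np.isfinite(self.surface.values).sum())
        return NSEResults(D, None if se is None else float(se),
                          float(best.chisqr), npts - 1, self.g0.l_alpha,
                          self.g0.l_xy, start_chisqr, model)


def fit_elastic(datasets, membrane: str = "slab", free=("l_C", "l_H"),
                q_range=DEFAULT_Q_RANGE, **kwargs) -> ElasticResults:
    """Functional wrapper over :class:`ElasticModel`."""
    fit_kw = {k: kwargs.pop(k) for k in ("start", "bounds", "multistart", "seed")
              if k in kwargs}
    return ElasticModel(datasets, membrane=membrane, q_range=q_range,
                        **kwargs).fit(free=free, **fit_kw)


def fit_nse(surface: ISFSurface, bilayer: SymmetricBilayer,
            g: GaussianMembraneParams, protein: ProteinSpec | None = None,
            **kwargs) -> NSEResults:
    """Functional wrapper over :class:`NSEModel`."""
    fit_kw = {k: kwargs.pop(k) for k in ("start", "multistart", "seed")
              if k in kwargs}
    return NSEModel(surface, bilayer, g, protein, **kwargs).fit(**fit_kw)
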