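"""Synthetic fixture generator.

Produces reduced-data files with the statistical structure of real
measurements: model curves evaluated at instrument-like q (and tau) grids
with multiplicative Gaussian noise, plus a JSON "truth" sidecar recording
the generating parameters.  Default truths are the reference RBC values
(l_C = 16.3 A, l_H = 5.0 A, l_alpha = 23 A, l_xy = 63 A, D = 1.85 A^2/ns,
phi_p = 0.23, band 3 equivalent radius 21.4 A) with the radiation-specific
SLD tables.  Everything derives from a single integer seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import rbc
from .curves import (ISFSurface, ScatteringCurve, _atomic_write,
                     write_nse_table, write_sas_ascii)
from .gaussian import nse_curve
from .profiles import ValidationError
from .slab import slab_intensity_with_proteins
from .compose import intensity_with_proteins

__all__ = ["make_fixtures", "SCENARIOS", "synthetic_elastic", "synthetic_nse"]

SCENARIOS = ("slab_sans", "slab_saxs", "gaussian_joint", "nse")

_DEFAULT_TRUTH = {
    "l_C": rbc.DEFAULT_L_C, "l_H": rbc.DEFAULT_L_H,
    "l_alpha": rbc.DEFAULT_L_ALPHA, "l_xy": rbc.DEFAULT_L_XY,
    "D": rbc.DEFAULT_D, "phi_p": rbc.TRANSMEMBRANE_FRACTION,
    "lateral_model": "boolean",
}

#: Instrument-like grids: elastic curves span the standard fitting window,
#: NSE uses the three reported q values and spin-echo times to 500 ns.
ELASTIC_Q = np.geomspace(8e-3, 0.5, 100)
NSE_Q = np.array([0.036, 0.071, 0.109])
NSE_TAU = np.concatenate([[0.0], np.geomspace(1.0, 500.0, 19)])


def synthetic_elastic(radiation: str, membrane: str, truth: dict,
                      q=None) -> ScatteringCurve:
    """Noiseless model curve for one radiation at the truth parameters."""
    q = ELASTIC_Q if q is None else np.asarray(q, dtype=float)
    b = rbc.default_bilayer(radiation, truth["l_C"], truth["l_H"])
    p = rbc.default_protein(radiation, truth["lateral_model"], truth["phi_p"])
    if membrane == "slab":
        dec = slab_intensity_with_proteins(b, p, q, radiation=radiation)
    else:
        g = rbc.default_gaussian(truth["l_alpha"], truth["l_xy"])
        dec = intensity_with_proteins("gaussian", b, g, p, q,
                                      radiation=radiation)
    return dec.curve()


def synthetic_nse(truth: dict, q=None, tau=None) -> ISFSurface:
    """Noiseless normalized ISF surface at the truth parameters."""
    q = NSE_Q if q is None else np.asarray(q, dtype=float)
    tau = NSE_TAU if tau is None else np.asarray(tau, dtype=float)
    b = rbc.default_bilayer("neutron", truth["l_C"], truth["l_H"])
    p = rbc.default_protein("neutron", truth["lateral_model"], truth["phi_p"])
    g = rbc.default_gaussian(truth["l_alpha"], truth["l_xy"], truth["D"])
    return nse_curve(b, g, p, q, tau)


def _noisy_curve(curve: ScatteringCurve, noise: float,
                 rng: np.random.Generator) -> ScatteringCurve:
    sigma = np.maximum(noise * np.abs(curve.I), 1e-300)
    I = curve.I * (1.0 + noise * rng.standard_normal(curve.I.shape)) \
        if noise > 0 else curve.I.copy()
    return ScatteringCurve(curve.q, I, sigma if noise > 0 else None,
                           curve.radiation)


def make_fixtures(scenario: str, out_dir, noise: float = 0.02, seed: int = 0,
                  truth: dict | None = None) -> dict:
    """Write synthetic data files for a scenario; returns {name: path}.

    scenario: "slab_sans" | "slab_saxs" | "gaussian_joint" | "nse".
    Multiplicative Gaussian noise at the given fractional level; sigma
    columns carry the true (noiseless-referenced) uncertainties.  Fully
    reproducible from the seed.  A ``truth.json`` sidecar stores the
    generating parameters.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; "
                              f"choose from {SCENARIOS}")
    truth = {**_DEFAULT_TRUTH, **(truth or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: dict[str, str] = {}
    meta = {f"truth_{k}": v for k, v in truth.items()}
    meta.update({"scenario": scenario, "noise": noise, "seed": seed})
    if scenario in ("slab_sans", "slab_saxs"):
        radiation = "neutron" if scenario == "slab_sans" else "xray"
        curve = _noisy_curve(synthetic_elastic(radiation, "slab", truth),
                             noise, rng)
        path = out / f"{scenario}.dat"
        write_sas_ascii(path, curve, meta)
        written[scenario] = str(path)
    elif scenario == "gaussian_joint":
        for radiation in ("neutron", "xray"):
            curve = _noisy_curve(synthetic_elastic(radiation, "gaussian", truth),
                                 noise, rng)
            path = out / f"gaussian_{radiation}.dat"
            write_sas_ascii(path, curve, meta)
            written[radiation] = str(path)
    else:  # nse
        surf = synthetic_nse(truth)
        sigma = np.maximum(noise * np.abs(surf.values), 1e-300)
        vals = surf.values.copy()
        if noise > 0:
            mask = surf.tau > 0  # tau = 0 stays exactly normalized
            vals[:, mask] *= 1.0 + noise * rng.standard_normal(
                vals[:, mask].shape)
        noisy = ISFSurface(surf.q, surf.tau, vals,
                           sigma if noise > 0 else None)
        path = out / "nse.dat"
        write_nse_table(path, noisy, meta)
        written["nse"] = str(path)
    sidecar = out / f"{scenario}_truth.json"
    _atomic_write(sidecar, json.dumps({"scenario": scenario, "noise": noise,
                                       "seed": seed, "truth": truth}, indent=2) + "\n")
    written["truth"] = str(sidecar)
    return written
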