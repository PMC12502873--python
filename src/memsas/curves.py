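"""Data containers and plain-text I/O.

Reduced elastic curves are 3-column ASCII (q [1/A], I, sigma) and NSE tables
are 4-column ASCII (q [1/A], tau [ns], I(q,tau)/I(q,0), sigma), both with
'#' comment/header lines.  Writers are atomic (temp file + rename) and record
the generating parameter set in the header.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "ScatteringCurve",
    "ISFSurface",
    "read_sas_ascii",
    "write_sas_ascii",
    "read_nse_table",
    "write_nse_table",
]


class ParseError(ValueError):
    """Raised for malformed data files."""


@dataclass
class ScatteringCurve:
    """1D reduced small-angle scattering curve.

    q is strictly increasing and positive (1/A); I is the per-unit-area
    intensity on an arbitrary scale; sigma are optional 1-sigma uncertainties.
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    radiation: str = "neutron"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.size == 0:
            raise ParseError("empty curve")
        if self.q.size != self.I.size:
            raise ParseError("q and I must have the same length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ParseError("q must be positive and strictly increasing")
        if not np.all(np.isfinite(self.I)):
            raise ParseError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.size != self.q.size or np.any(self.sigma <= 0):
                raise ParseError("sigma must be positive and match q")

    def mask(self, qmin: float | None = None, qmax: float | None = None) -> "ScatteringCurve":
        sel = np.ones(self.q.size, dtype=bool)
        if qmin is not None:
            sel &= self.q >= qmin
        if qmax is not None:
            sel &= self.q <= qmax
        if not sel.any():
            raise ParseError("q-range mask removed every point")
        return ScatteringCurve(self.q[sel], self.I[sel],
                               None if self.sigma is None else self.sigma[sel],
                               self.radiation, dict(self.meta))


@dataclass
class ISFSurface:
    """Normalized intermediate scattering function on a (q, tau) grid.

    ``values[i, j] = I(q[i], tau[j]) / I(q[i], 0)``; NaN marks missing cells.
    """

    q: np.ndarray
    tau: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.q.size, self.tau.size):
            raise ParseError("values must have shape (len(q), len(tau))")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.values.shape:
                raise ParseError("sigma must match values")
        if np.any(self.tau == 0):
            col = self.values[:, self.tau == 0]
            if np.any(np.abs(col[np.isfinite(col)] - 1.0) > 1e-6):
                log.warning("ISF at tau=0 deviates from 1")

    @property
    def has_dynamics(self) -> bool:
        return bool(np.any(self.tau > 0))


def _load_rows(path) -> tuple[np.ndarray, list[str]]:
    header: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                header.append(s.lstrip("# "))
                continue
            rows.append([float(tok) for tok in s.replace(",", " ").split()])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    width = max(len(r) for r in rows)
    arr = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        arr[i, : len(r)] = r
    return arr, header


def read_sas_ascii(path, radiation: str = "neutron") -> ScatteringCurve:
    """Read a 2- or 3-column (q, I[, sigma]) ASCII curve.

    Rows containing non-finite values are dropped with a logged count.
    """
    arr, header = _load_rows(path)
    if arr.shape[1] < 2:
        raise ParseError(f"{path}: need at least 2 columns (q, I)")
    ncol = min(arr.shape[1], 3)
    keep = np.isfinite(arr[:, :ncol]).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.warning("%s: dropped %d non-finite rows", path, dropped)
    arr = arr[keep]
    if arr.size == 0:
        raise ParseError(f"{path}: no finite data rows")
    sigma = arr[:, 2] if ncol >= 3 else None
    if sigma is not None and not np.all(sigma > 0):
        # a zero-filled third column means "no uncertainties"
        sigma = None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma, radiation,
                           {"header": header, "path": str(path)})


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _header_lines(meta: Mapping | None) -> str:
    out = []
    for k, v in (meta or {}).items():
        if k in ("header", "path"):
            continue
        out.append(f"# {k} = {v}")
    return "\n".join(out)


def write_sas_ascii(path, curve: ScatteringCurve, meta: Mapping | None = None) -> None:
    """Write a curve as 3-column ASCII with '#' parameter headers."""
    hdr = _header_lines({**curve.meta, **(meta or {})})
    sig = curve.sigma if curve.sigma is not None else np.zeros_like(curve.q)
    body = "\n".join(f"{q:.9e} {i:.9e} {s:.9e}"
                     for q, i, s in zip(curve.q, curve.I, sig))
    cols = "# q_invA I sigma"
    _atomic_write(path, "\n".join(x for x in (hdr, cols, body) if x) + "\n")


def read_nse_table(path) -> ISFSurface:
    """Read a 3/4-column (q, tau, isf[, sigma]) table onto the union grid.

    Duplicate (q, tau) rows are an error; missing cells are NaN-flagged.
    """
    arr, header = _load_rows(path)
    if arr.shape[1] < 3:
        raise ParseError(f"{path}: need at least 3 columns (q, tau, isf)")
    q_vals = np.unique(arr[:, 0])
    tau_vals = np.unique(arr[:, 1])
    values = np.full((q_vals.size, tau_vals.size), np.nan)
    sigma = np.full_like(values, np.nan)
    seen = set()
    for row in arr:
        i = int(np.searchsorted(q_vals, row[0]))
        j = int(np.searchsorted(tau_vals, row[1]))
        if (i, j) in seen:
            raise ParseError(f"{path}: duplicate (q, tau) row ({row[0]}, {row[1]})")
        seen.add((i, j))
        values[i, j] = row[2]
        if arr.shape[1] >= 4:
            sigma[i, j] = row[3]
    if np.isnan(values).any():
        log.warning("%s: %d missing (q, tau) cells", path, int(np.isnan(values).sum()))
    sig = None if (np.isnan(sigma).all() or not np.nansum(sigma) > 0) else sigma
    return ISFSurface(q_vals, tau_vals, values, sig, {"header": header, "path": str(path)})


def write_nse_table(path, surface: ISFSurface, meta: Mapping | None = None) -> None:
    """Write an ISF surface as 4-column ASCII with '#' parameter headers."""
    hdr = _header_lines({**surface.meta, **(meta or {})})
    lines = []
    for i, qv in enumerate(surface.q):
        for j, tv in enumerate(surface.tau):
            v = surface.values[i, j]
            if not np.isfinite(v):
                continue
            s = surface.sigma[i, j] if surface.sigma is not None else 0.0
            lines.append(f"{qv:.9e} {tv:.9e} {v:.9e} {s:.9e}")
    cols = "# q_invA tau_ns isf sigma"
    _atomic_write(path, "\n".join(x for x in (hdr, cols, "\n".join(lines)) if x) + "\n")
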