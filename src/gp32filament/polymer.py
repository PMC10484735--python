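"""Freely jointed chain (FJC) and worm-like chain (WLC) elasticity.

Bare ssDNA and ssDNA saturated with a noncooperative SSB behave as freely
jointed chains (rigid links of Kuhn length b = 2p); the cooperatively bound
wild-type filament is stiffer and is described by the Marko–Siggia worm-like
chain.  This module evaluates both models, fits them to force–extension
curves over a low-force window where enthalpic stretching is negligible, and
builds 1-pN-binned extension-change curves relative to bare ssDNA.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from .constants import Constants, DEFAULT_CONSTANTS
from .errors import DomainError, FitFailureError, InsufficientDataError

__all__ = [
    "PolymerParams",
    "ForceExtensionCurve",
    "PolymerFitResult",
    "fjc_extension",
    "wlc_force",
    "wlc_extension",
    "fit_fjc",
    "fit_wlc",
    "bin_fec",
    "extension_change",
]


@dataclass(frozen=True)
class PolymerParams:
    """Elastic parameters of a (protein-bound) nucleic-acid polymer.

    contour_per_nt : contour length per nucleotide, nm/nt.
    n_nt : number of nucleotides in the substrate.
    persistence : persistence length p, nm.  The FJC Kuhn length is b = 2p.
    stretch_modulus : elastic stretch modulus S in pN; ``None`` means the
        inextensible model (the default — fits are restricted to low force).
    """

    contour_per_nt: float
    n_nt: int
    persistence: float
    stretch_modulus: Optional[float] = None

    def __post_init__(self) -> None:
        if self.contour_per_nt <= 0:
            raise ValueError("contour_per_nt must be > 0")
        if self.n_nt < 1:
            raise ValueError("n_nt must be >= 1")
        if self.persistence <= 0:
            raise ValueError("persistence must be > 0")
        if self.stretch_modulus is not None and self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0 when finite")

    @property
    def total_contour(self) -> float:
        """Full contour length n_nt * contour_per_nt, nm."""
        return self.contour_per_nt * self.n_nt


@dataclass
class ForceExtensionCurve:
    """Paired force (pN) / end-to-end extension (nm) samples.

    ``direction`` records whether the curve was acquired while stretching or
    releasing the tether; ``meta`` carries substrate id, protein,
    concentration and generator ground truth for synthetic curves.
    """

    force: np.ndarray
    extension: np.ndarray
    direction: str = "stretch"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.force.shape != self.extension.shape or self.force.ndim != 1:
            raise ValueError("force and extension must be equal-length 1-D sequences")
        if not (np.all(np.isfinite(self.force)) and np.all(np.isfinite(self.extension))):
            raise ValueError("force and extension must be finite")
        if np.any(self.force < 0):
            raise ValueError("forces must be >= 0")
        if self.direction not in ("stretch", "release"):
            raise ValueError("direction must be 'stretch' or 'release'")

    def __len__(self) -> int:
        return self.force.size


@dataclass
class PolymerFitResult:
    """Outcome of an FJC or WLC least-squares fit."""

    model: str  # "FJC" | "WLC"
    params: PolymerParams
    param_uncertainties: dict
    force_window: tuple
    residual_rms: float
    n_points: int = 0


def _langevin(u: np.ndarray) -> np.ndarray:
    """coth(u) - 1/u, series-expanded near 0 to avoid cancellation."""
    out = np.empty_like(u)
    small = u < 1e-4
    us = u[small]
    out[small] = us / 3.0 - us**3 / 45.0
    ul = u[~small]
    out[~small] = 1.0 / np.tanh(ul) - 1.0 / ul
    return out


def fjc_extension(force, params: PolymerParams, constants: Constants = DEFAULT_CONSTANTS):
    """Extension (nm) of a freely jointed chain at the given force (pN).

    x(F) = L_tot * [coth(Fb/kBT) - kBT/(Fb)] * (1 + F/S), Kuhn length b = 2p.
    The enthalpic (1 + F/S) factor applies only when ``stretch_modulus`` is
    set.  F = 0 returns the exact limit 0; negative force raises
    :class:`DomainError`.
    """
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise DomainError("FJC requires finite force >= 0 (limit at F=0 is x=0)")
    b = 2.0 * params.persistence
    u = f * b / constants.kBT
    x = params.total_contour * _langevin(u)
    if params.stretch_modulus is not None:
        x = x * (1.0 + f / params.stretch_modulus)
    return float(x[0]) if scalar else x


def wlc_force(relative_extension, params: PolymerParams,
              constants: Constants = DEFAULT_CONSTANTS):
    """Marko–Siggia WLC force (pN) at fractional extension z = x/L_tot.

    F(z) = (kBT/p) * [1/(4(1-z)^2) - 1/4 + z], valid for 0 <= z < 1.
    """
    z = np.asarray(relative_extension, dtype=float)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    if not np.all(np.isfinite(z)) or np.any(z < 0) or np.any(z >= 1):
        raise DomainError("WLC requires 0 <= z < 1 (force diverges at z = 1)")
    f = (constants.kBT / params.persistence) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return float(f[0]) if scalar else f


_Z_MAX = 1.0 - 1e-12


def wlc_extension(force, params: PolymerParams,
                  constants: Constants = DEFAULT_CONSTANTS):
    """Fractional extension z solving the Marko–Siggia relation for F (pN).

    Inverted by bracketed root finding on [0, 1 - 1e-12]; relative tolerance
    better than 1e-10.  Inverse of :func:`wlc_force`.
    """
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    f = np.atleast_1d(f)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise DomainError("force must be finite and >= 0")
    scale = constants.kBT / params.persistence

    def solve(fi: float) -> float:
        if fi == 0.0:
            return 0.0
        g = lambda z: scale * (0.25 / (1.0 - z) ** 2 - 0.25 + z) - fi
        return brentq(g, 0.0, _Z_MAX, xtol=1e-14, rtol=1e-14)

    z = np.array([solve(fi) for fi in f])
    return float(z[0]) if scalar else z


def _window(fec: ForceExtensionCurve, f_max: float):
    mask = (fec.force <= f_max) & (fec.force > 0)
    if int(mask.sum()) < 5:
        raise InsufficientDataError(
            f"need >= 5 samples with 0 < force <= {f_max} pN, got {int(mask.sum())}"
        )
    return fec.force[mask], fec.extension[mask]


def _resolve_n_nt(fec: ForceExtensionCurve, n_nt) -> int:
    if n_nt is not None:
        return int(n_nt)
    if "n_nt" in fec.meta:
        return int(fec.meta["n_nt"])
    return 8100  # length of the standard ssDNA tether used throughout


def fit_fjc(fec: ForceExtensionCurve, f_max: float = 10.0, n_nt=None,
            extensible: bool = False,
            constants: Constants = DEFAULT_CONSTANTS) -> PolymerFitResult:
    """Least-squares FJC fit of contour-per-nt and persistence below f_max.

    Inextensible by default; ``extensible=True`` additionally fits the
    stretch modulus S.  Uncertainties come from the fit covariance.
    """
    n = _resolve_n_nt(fec, n_nt)
    f, x = _window(fec, f_max)
    p0 = [max(x.max() / (0.8 * n), 1e-3), 1.0]
    if extensible:
        def model(ff, c_nt, p, s):
            return fjc_extension(ff, PolymerParams(c_nt, n, p, s), constants)
        p0 = p0 + [1000.0]
        bounds = ([1e-6, 1e-6, 1.0], [100.0, 1e4, 1e7])
    else:
        def model(ff, c_nt, p):
            return fjc_extension(ff, PolymerParams(c_nt, n, p), constants)
        bounds = ([1e-6, 1e-6], [100.0, 1e4])
    try:
        popt, pcov = curve_fit(model, f, x, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FitFailureError(f"FJC fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    params = PolymerParams(popt[0], n, popt[1],
                           popt[2] if extensible else None)
    resid = x - model(f, *popt)
    unc = {"contour_per_nt": perr[0], "persistence": perr[1]}
    if extensible:
        unc["stretch_modulus"] = perr[2]
    return PolymerFitResult("FJC", params, unc, (float(f.min()), f_max),
                            float(np.sqrt(np.mean(resid**2))), len(f))


def fit_wlc(fec: ForceExtensionCurve, f_max: float = 5.0, n_nt=None,
            constants: Constants = DEFAULT_CONSTANTS) -> PolymerFitResult:
    """Least-squares Marko–Siggia WLC fit below f_max (inextensible)."""
    n = _resolve_n_nt(fec, n_nt)
    f, x = _window(fec, f_max)

    def model(ff, c_nt, p):
        z = wlc_extension(ff, PolymerParams(1.0, 1, p), constants)
        return np.asarray(z) * c_nt * n

    p0 = [max(x.max() / (0.8 * n), 1e-3), 10.0]
    try:
        popt, pcov = curve_fit(model, f, x, p0=p0,
                               bounds=([1e-6, 1e-3], [100.0, 1e4]), maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitFailureError(f"WLC fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    params = PolymerParams(popt[0], n, popt[1])
    resid = x - model(f, *popt)
    return PolymerFitResult("WLC", params,
                            {"contour_per_nt": perr[0], "persistence": perr[1]},
                            (float(f.min()), f_max),
                            float(np.sqrt(np.mean(resid**2))), len(f))


def bin_fec(fec: ForceExtensionCurve, bin_width: float = 1.0) -> pd.DataFrame:
    """Bin a force–extension curve into [n, n+1)-pN force bins.

    Returns a DataFrame indexed by the bin's left edge with per-bin mean
    force, mean extension, SEM of extension and sample count; empty bins are
    omitted.  A single-sample bin reports SEM 0.
    """
    if len(fec) == 0:
        raise InsufficientDataError("cannot bin an empty curve")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    key = np.floor(fec.force / bin_width).astype(int)
    df = pd.DataFrame({"key": key, "force": fec.force, "extension": fec.extension})
    g = df.groupby("key")
    out = pd.DataFrame({
        "force_mean": g["force"].mean(),
        "extension_mean": g["extension"].mean(),
        "extension_sem": g["extension"].sem().fillna(0.0),
        "n": g["extension"].count(),
    })
    out.index = out.index * bin_width
    out.index.name = "bin_left"
    return out


def extension_change(fec_complex: ForceExtensionCurve,
                     fec_bare: ForceExtensionCurve,
                     bin_width: float = 1.0) -> pd.DataFrame:
    """Binned extension change Δx(F) of a protein–DNA complex vs bare ssDNA.

    Both curves are binned with :func:`bin_fec`; per overlapping bin,
    Δx = mean(complex) - mean(bare) with SEMs propagated in quadrature.
    Only overlapping bins are returned.
    """
    bc = bin_fec(fec_complex, bin_width)
    bb = bin_fec(fec_bare, bin_width)
    common = bc.index.intersection(bb.index)
    if len(common) == 0:
        raise InsufficientDataError("curves share no force bin")
    bc, bb = bc.loc[common], bb.loc[common]
    return pd.DataFrame({
        "force_mean": 0.5 * (bc["force_mean"] + bb["force_mean"]),
        "delta_x": bc["extension_mean"] - bb["extension_mean"],
        "delta_x_sem": np.hypot(bc["extension_sem"], bb["extension_sem"]),
        "n_complex": bc["n"],
        "n_bare": bb["n"],
    }, index=common)
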