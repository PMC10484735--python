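"""Seeded generators for every input class, with embedded ground truth.

The experimental recordings behind the analysis (optical-tweezers
force–extension curves and constant-force traces, AFM backbone traces and
height images, rate tables) are emulated here from the functional forms the
analysis assumes: FJC/WLC mechanics with additive Gaussian extension noise,
sums of saturating exponential binding phases, linear-plus-exponential
dissociation, discrete 2-D worm-like backbones, and tip-convolved height
rasters.  Every generator is deterministic given its seed and records the
generating parameters in the output object's ``meta`` so recovery tests can
close the loop.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .afm import AFMImage, BackboneTrace, resample_trace
from .constants import Constants, DEFAULT_CONSTANTS
from .errors import DomainError
from .kinetics import RateSeries, TimeExtensionTrace
from .polymer import ForceExtensionCurve, PolymerParams, fjc_extension, wlc_extension

__all__ = [
    "GeneratorSpec",
    "gen_fec",
    "gen_binding_trace",
    "gen_dissociation_trace",
    "gen_chain_2d",
    "gen_afm_image",
    "gen_rate_series",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Common knobs of the synthetic generators.

    seed : required RNG seed (generators are deterministic given it).
    noise_sd : additive Gaussian noise SD in nm.  Defaults to 5 nm for
        time traces, the visual scatter of a constant-force recording;
        force–extension and AFM callers typically pass ~1 nm and ~0.01 nm.
    dt : trace sampling interval, s.
    arc_step : discretization step of generated 2-D chains, nm.
    """

    seed: int
    noise_sd: float = 5.0
    dt: float = 0.1
    arc_step: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dt <= 0 or self.arc_step <= 0:
            raise ValueError("dt and arc_step must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_fec(params: PolymerParams, model: str, force_grid,
            spec: GeneratorSpec,
            constants: Constants = DEFAULT_CONSTANTS) -> ForceExtensionCurve:
    """Force–extension curve from a forward FJC or WLC evaluation + noise."""
    model = model.upper()
    f = np.asarray(force_grid, dtype=float)
    if model == "FJC":
        x = fjc_extension(f, params, constants)
    elif model == "WLC":
        x = np.asarray(wlc_extension(f, params, constants)) * params.total_contour
    else:
        raise ValueError("model must be 'FJC' or 'WLC'")
    x = x + spec.rng().normal(0.0, spec.noise_sd, size=f.shape)
    meta = {
        "model": model, "contour_per_nt": params.contour_per_nt,
        "n_nt": params.n_nt, "persistence": params.persistence,
        "stretch_modulus": params.stretch_modulus,
        "seed": spec.seed, "noise_sd": spec.noise_sd,
    }
    return ForceExtensionCurve(f, x, meta=meta)


def gen_binding_trace(x0: float, amplitudes: Sequence[float],
                      rates: Sequence[float], duration: float,
                      spec: GeneratorSpec, force: float = 0.0,
                      concentration: float = 0.0) -> TimeExtensionTrace:
    """Three-phase binding trace x(t) = x0 + sum a_i (1 - e^{-k_i t}) + noise.

    ``amplitudes`` are the signed phase amplitudes (dx1, dx2, dx3) with the
    initial compaction negative; ``rates`` (k1, k2, k3) must be descending
    wherever the matching amplitude is nonzero.  Rates of absent phases are
    ignored.  Noiselessly, x(inf) - x0 = dx1 + dx2 + dx3.
    """
    a = np.asarray(amplitudes, dtype=float)
    k = np.asarray(rates, dtype=float)
    if a.shape != (3,) or k.shape != (3,):
        raise ValueError("amplitudes and rates must be length-3 sequences")
    live = np.nonzero(a)[0]
    klive = k[live]
    if np.any(klive <= 0):
        raise ValueError("rates of present phases must be > 0")
    if np.any(np.diff(klive) > 0):
        raise ValueError("rates must be descending where amplitudes are nonzero")
    t = np.arange(0.0, duration, spec.dt)
    x = np.full_like(t, x0)
    for ai, ki in zip(a[live], klive):
        x = x + ai * (1.0 - np.exp(-ki * t))
    x = x + spec.rng().normal(0.0, spec.noise_sd, size=t.shape)
    meta = {
        "x0": x0, "amplitudes": tuple(float(v) for v in a),
        "rates": tuple(float(v) for v in k),
        "seed": spec.seed, "noise_sd": spec.noise_sd,
    }
    return TimeExtensionTrace(t, x, force, concentration, "binding", meta)


def gen_dissociation_trace(slope: float, exp_amp: float, exp_rate: float,
                           duration: float, spec: GeneratorSpec,
                           x0: float = 0.0, force: float = 0.0,
                           concentration: float = 0.0) -> TimeExtensionTrace:
    """Dissociation trace x(t) = x0 + slope*t - exp_amp*e^{-exp_rate t} + noise.

    Either component may be zeroed: ``exp_amp = 0`` gives the pure linear
    recompaction of cluster-end dissociation, ``slope = 0`` the single
    exponential relaxation of a noncooperative binder.
    """
    if exp_amp != 0.0 and exp_rate <= 0:
        raise ValueError("exp_rate must be > 0 when the exponential is present")
    t = np.arange(0.0, duration, spec.dt)
    x = x0 + slope * t
    if exp_amp != 0.0:
        x = x - exp_amp * np.exp(-exp_rate * t)
    x = x + spec.rng().normal(0.0, spec.noise_sd, size=t.shape)
    meta = {
        "x0": x0, "slope": slope, "exp_amp": exp_amp, "exp_rate": exp_rate,
        "seed": spec.seed, "noise_sd": spec.noise_sd,
    }
    return TimeExtensionTrace(t, x, force, concentration, "dissociation", meta)


def gen_chain_2d(persistence: float, total_length: float,
                 spec: GeneratorSpec,
                 molecule_id: str = "") -> BackboneTrace:
    """Discrete 2-D worm-like chain of the given persistence length.

    Successive turning angles are i.i.d. Gaussian with mean 0 and variance
    arc_step/persistence, which yields <cos theta(L)> = exp(-L/2p) exactly
    at the discrete separations.  ``persistence=inf`` produces a straight
    line.  The arc step should be well below the persistence length for a
    faithful continuum limit.
    """
    step = spec.arc_step
    if persistence <= 0:
        raise ValueError("persistence must be > 0")
    n = int(round(total_length / step))
    if n < 2:
        raise ValueError("total_length must cover >= 2 arc steps")
    rng = spec.rng()
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    sd = math.sqrt(step / persistence) if math.isfinite(persistence) else 0.0
    dtheta = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta[:-1])])
    steps = step * np.column_stack([np.cos(theta), np.sin(theta)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    tr = BackboneTrace(pts, molecule_id or f"chain-{spec.seed}")
    return tr


def gen_afm_image(trace: BackboneTrace, spec: GeneratorSpec,
                  molecule_height: float = 2.0, tip_sigma: float = 3.0,
                  pixel_size: float = 2.0) -> AFMImage:
    """Rasterize a backbone into a tip-convolved height image.

    The backbone is painted at ``molecule_height`` (nm) on a grid with a
    margin of 3 tip sigmas, blurred with a Gaussian of SD ``tip_sigma``
    (a proxy for tip convolution that conserves integrated volume), and
    overlaid with Gaussian background noise of ``spec.noise_sd``.  The
    injected (pre-noise) integrated volume is recorded in ``meta``.
    """
    if molecule_height <= 0 or tip_sigma <= 0 or pixel_size <= 0:
        raise ValueError("molecule_height, tip_sigma and pixel_size must be > 0")
    margin = 3.0 * tip_sigma + 2.0 * pixel_size
    pts = resample_trace(trace, pixel_size / 2.0).points
    lo = pts.min(axis=0) - margin
    hi = pts.max(axis=0) + margin
    nx = int(math.ceil((hi[0] - lo[0]) / pixel_size)) + 1
    ny = int(math.ceil((hi[1] - lo[1]) / pixel_size)) + 1
    heights = np.zeros((ny, nx))
    ij = np.floor((pts - lo) / pixel_size).astype(int)
    heights[ij[:, 1], ij[:, 0]] = molecule_height
    injected = float(heights.sum() * pixel_size**2)
    heights = gaussian_filter(heights, sigma=tip_sigma / pixel_size,
                              mode="constant")
    if spec.noise_sd > 0:
        heights = heights + spec.rng().normal(0.0, spec.noise_sd, heights.shape)
    meta = {
        "injected_volume": injected, "molecule_height": molecule_height,
        "tip_sigma": tip_sigma, "origin": (float(lo[0]), float(lo[1])),
        "molecule_id": trace.molecule_id,
        "seed": spec.seed, "noise_sd": spec.noise_sd,
    }
    return AFMImage(heights, pixel_size, background=0.0, meta=meta)


def gen_rate_series(model: str, true_params: dict, abscissa_grid,
                    spec: GeneratorSpec, rel_noise: float = 0.0,
                    constants: Constants = DEFAULT_CONSTANTS) -> RateSeries:
    """Rate series from a forward rate model + multiplicative log-normal noise.

    ``model`` selects the forward law and the abscissa meaning:
      - "bell":        k(F) = k0 exp(F dx / kBT); params k0, delta_x.
      - "bimolecular": k(c) = c k_on + k_off;    params k_on, k_off.
      - "two_step":    k(c) = c k_b k_c/(c k_b + k_c); params k_b, k_c.
    ``rel_noise`` is the SD of the log-normal factor (rates stay positive).
    """
    x = np.asarray(abscissa_grid, dtype=float)
    if np.any(x < 0):
        raise DomainError("abscissa must be >= 0")
    if model == "bell":
        k = true_params["k0"] * np.exp(x * true_params["delta_x"] / constants.kBT)
        kind = "force"
    elif model == "bimolecular":
        k = x * true_params["k_on"] + true_params["k_off"]
        kind = "concentration"
    elif model == "two_step":
        kb, kc = true_params["k_b"], true_params["k_c"]
        k = x * kb * kc / (x * kb + kc)
        kind = "concentration"
    else:
        raise ValueError("model must be 'bell', 'bimolecular' or 'two_step'")
    if np.any(k <= 0):
        raise DomainError("forward model produced non-positive rates")
    if rel_noise > 0:
        k = k * np.exp(spec.rng().normal(0.0, rel_noise, size=k.shape))
    meta = {"model": model, "true_params": dict(true_params),
            "seed": spec.seed, "rel_noise": rel_noise}
    return RateSeries(x, k, None, kind, meta)
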