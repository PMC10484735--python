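"""Multiphase kinetics of SSB binding and dissociation on tethered ssDNA.

Constant-force time–extension traces show up to three sequential binding
phases — a fast compaction (amplitude dx1 < 0, rate k1) followed by two
partial elongations (dx2, k2 and dx3, k3, rates descending) — and, on
protein removal, either a linear recompaction (cluster-end dissociation), a
linear-plus-exponential recompaction (overcrowded filaments), or a single
exponential relaxation (noncooperative binder).  This module decomposes
traces into those phases and fits the force dependence (Bell model) and
concentration dependence (bimolecular and sequential two-step models) of
the extracted rates.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .constants import Constants, DEFAULT_CONSTANTS
from .errors import FitFailureError, InsufficientDataError

__all__ = [
    "TimeExtensionTrace",
    "ExponentialFit",
    "BindingDecomposition",
    "DissociationDecomposition",
    "RateSeries",
    "BellFit",
    "BimolecularFit",
    "TwoStepFit",
    "fit_exponential",
    "decompose_binding_trace",
    "decompose_dissociation_trace",
    "fit_bell",
    "fit_bimolecular",
    "fit_two_step",
    "compute_kd",
    "noise_sd",
]


@dataclass
class TimeExtensionTrace:
    """Extension (nm) vs time (s) at fixed force (pN) and concentration (nM)."""

    time: np.ndarray
    extension: np.ndarray
    force: float = 0.0
    concentration: float = 0.0
    phase_label: str = "binding"  # "binding" | "dissociation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        if self.time.shape != self.extension.shape or self.time.ndim != 1:
            raise ValueError("time and extension must be equal-length 1-D sequences")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.extension))):
            raise ValueError("time and extension must be finite")
        if self.time.size >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.force < 0 or self.concentration < 0:
            raise ValueError("force and concentration must be >= 0")
        if self.phase_label not in ("binding", "dissociation"):
            raise ValueError("phase_label must be 'binding' or 'dissociation'")

    def __len__(self) -> int:
        return self.time.size

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time))) if len(self) > 1 else math.nan


def noise_sd(x: np.ndarray) -> float:
    """Robust noise SD from the MAD of first differences.

    For white noise, successive differences have SD sqrt(2) times the point
    noise; slow kinetic drift contributes negligibly to the differences.
    """
    d = np.diff(np.asarray(x, dtype=float))
    if d.size == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / math.sqrt(2.0))


@dataclass
class ExponentialFit:
    """Sum-of-decaying-exponentials fit x(t) = x_eq - sum_i A_i e^{-k_i t}."""

    x_eq: float
    amplitudes: np.ndarray  # ordered by descending rate; signed
    rates: np.ndarray       # descending
    rss: float
    n: int
    fallback: bool = False  # True when a 2-rate fit collapsed to 1 rate
    constant: bool = False  # True when the trace had no resolvable kinetics

    @property
    def n_rates(self) -> int:
        return len(self.rates)


def _multiexp_model(n_rates: int):
    if n_rates == 1:
        return lambda t, xeq, a1, k1: xeq - a1 * np.exp(-k1 * t)
    return lambda t, xeq, a1, k1, a2, k2: (
        xeq - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t))


def _rate_guess(ts: np.ndarray, x: np.ndarray, xeq: float) -> float:
    """Crude 1/e-time rate guess from the first crossing of 63% amplitude."""
    a = xeq - x[0]
    if a == 0:
        return 3.0 / max(ts[-1], 1e-9)
    frac = (x - x[0]) / a
    idx = np.nonzero(frac >= 0.632)[0]
    t63 = ts[idx[0]] if idx.size and ts[idx[0]] > 0 else ts[-1] / 3.0
    return 1.0 / max(t63, ts[1] if ts.size > 1 else 1e-6)


def _fit_multiexp(t: np.ndarray, x: np.ndarray, n_rates: int) -> ExponentialFit:
    ts = t - t[0]
    n = len(x)
    ntail = max(1, n // 10)
    xeq0 = float(x[-ntail:].mean())
    atot = xeq0 - float(x[0])
    kg = _rate_guess(ts, x, xeq0)
    model = _multiexp_model(n_rates)
    if n_rates == 1:
        starts = [[xeq0, atot, kg * s] for s in (1.0, 5.0, 0.2, 25.0, 0.04)]
        lo = [-np.inf, -np.inf, 1e-9]
        hi = [np.inf, np.inf, 1e6]
    else:
        starts = [[xeq0, 0.6 * atot, kg * sf, 0.4 * atot, kg * ss]
                  for sf, ss in ((5.0, 0.5), (10.0, 0.1), (2.0, 0.05),
                                 (30.0, 1.0), (1.0, 0.02))]
        lo = [-np.inf, -np.inf, 1e-9, -np.inf, 1e-9]
        hi = [np.inf, np.inf, 1e6, np.inf, 1e6]
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(model, ts, x, p0=p0, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((x - model(ts, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise FitFailureError(
            f"{n_rates}-rate exponential fit failed from {len(starts)} starts")
    popt, rss = best
    xeq = float(popt[0])
    amps = np.array(popt[1::2], dtype=float)
    rates = np.array(popt[2::2], dtype=float)
    order = np.argsort(rates)[::-1]
    return ExponentialFit(xeq, amps[order], rates[order], rss, n)


def fit_exponential(trace: TimeExtensionTrace, n_rates: int = 1,
                    min_separation: float = 1.5) -> ExponentialFit:
    """Fit x(t) = x_eq - sum A_i e^{-k_i t} with 1 or 2 rates.

    Rates are returned in descending order.  For ``n_rates=2`` the two rates
    must be separated by at least ``min_separation``×; otherwise the fit
    falls back to a single rate and sets ``fallback``.  A trace with no
    resolvable signal (range below 5× the noise SD) returns zero amplitudes
    with the mean as offset and ``constant`` set.
    """
    if n_rates not in (1, 2):
        raise ValueError("n_rates must be 1 or 2")
    t, x = trace.time, trace.extension
    if len(x) < 4 * n_rates + 2:
        raise InsufficientDataError(
            f"need >= {4 * n_rates + 2} samples for a {n_rates}-rate fit")
    sd = noise_sd(x)
    if np.ptp(x) <= max(5.0 * sd, 1e-12):
        return ExponentialFit(float(x.mean()), np.zeros(n_rates),
                              np.full(n_rates, np.nan),
                              float(np.sum((x - x.mean()) ** 2)), len(x),
                              constant=True)
    fit = _fit_multiexp(t, x, n_rates)
    if n_rates == 2:
        span = t[-1] - t[0]
        close = fit.rates[1] > 0 and fit.rates[0] / fit.rates[1] < min_separation
        # a rate whose decay is not resolved within the record is
        # unidentifiable and only mimics a baseline/drift term
        unresolved = fit.rates[1] * span < 1.0
        if close or unresolved:
            fit1 = _fit_multiexp(t, x, 1)
            fit1.fallback = True
            return fit1
    return fit


@dataclass
class BindingDecomposition:
    """Signed amplitudes and rates of the sequential binding phases.

    dx1 < 0 is the initial compaction; dx2, dx3 > 0 the fast and slow
    elongations.  Absent phases carry zero amplitude and NaN rate.  The
    noiseless identity x_eq - x_init = dx1 + dx2 + dx3 holds by construction.
    """

    dx1: float
    dx2: float
    dx3: float
    k1: float
    k2: float
    k3: float
    x_init: float
    x_eq: float
    present_phases: tuple
    eq_warning: bool = False
    fallback: bool = False
    rss: float = math.nan

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([self.dx1, self.dx2, self.dx3])

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3])


def _phase_model(t, x0, a1, k1, a2, k2, a3, k3):
    return (x0 + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))
            + a3 * (1.0 - np.exp(-k3 * t)))


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    window = max(1, int(window))
    if window % 2 == 0:
        window += 1
    if window == 1:
        return x.copy()
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(xp, kernel, mode="valid")


def decompose_binding_trace(trace: TimeExtensionTrace,
                            smooth_window_s: float = 1.0,
                            depth_sd: float = 3.0,
                            alpha: float = 0.05) -> BindingDecomposition:
    """Decompose a constant-force binding trace into its kinetic phases.

    Procedure: (i) smooth with a centered moving average spanning
    ``smooth_window_s`` seconds; (ii) locate the global extension minimum —
    if it lies below both endpoints by more than ``depth_sd`` noise SDs the
    trace is non-monotone (compaction followed by elongation): a single
    exponential on the pre-minimum segment and a two-rate exponential on the
    post-minimum segment seed a full three-phase least-squares refinement
    over the whole trace; (iii) otherwise one- and two-rate exponential fits
    are compared by a residual F-test at ``alpha`` (with rate-separation and
    3-SD amplitude-significance guards) to decide the phase count.
    """
    t, x = trace.time, trace.extension
    if len(x) < 20:
        raise InsufficientDataError("binding decomposition needs >= 20 samples")
    sd = noise_sd(x)
    dt = trace.dt
    win = max(1, int(round(smooth_window_s / dt))) if dt > 0 else 1
    xs = _smooth(x, win)
    ts = t - t[0]
    imin = int(np.argmin(xs))
    # endpoint plateau levels from short medians: a single smoothed sample is
    # noise-limited and would let plateau noise dips mimic a real minimum
    head = max(win, len(x) // 50)
    depth0 = float(np.median(xs[:head])) - xs[imin]
    depth1 = float(np.median(xs[-head:])) - xs[imin]
    interior = win < imin < len(x) - win
    thresh = depth_sd * max(sd, 1e-12)

    ntail = max(1, len(x) // 10)

    if interior and depth0 > thresh and depth1 > thresh:
        # compaction + two elongations, split at the smoothed minimum
        pre = TimeExtensionTrace(t[: imin + 1], x[: imin + 1],
                                 trace.force, trace.concentration, "binding")
        fit1 = fit_exponential(pre, 1)
        a1_0 = float(fit1.amplitudes[0]) if not fit1.constant else xs[imin] - xs[0]
        k1_0 = float(fit1.rates[0]) if not fit1.constant else 1.0 / max(ts[imin], dt)
        post = TimeExtensionTrace(t[imin:], x[imin:],
                                  trace.force, trace.concentration, "binding")
        try:
            fit2 = fit_exponential(post, 2)
        except (FitFailureError, InsufficientDataError):
            fit2 = fit_exponential(post, 1)
        if fit2.n_rates == 2 and not fit2.constant:
            a2_0, a3_0 = float(fit2.amplitudes[0]), float(fit2.amplitudes[1])
            k2_0, k3_0 = float(fit2.rates[0]), float(fit2.rates[1])
        else:
            a2_0 = a3_0 = 0.5 * (xs[-1] - xs[imin])
            k2_0, k3_0 = 10.0 / ts[-1], 1.0 / ts[-1]
        p0 = [float(xs[0]), a1_0, k1_0, a2_0, k2_0, a3_0, k3_0]
        lo = [-np.inf, -np.inf, 1e-9, -np.inf, 1e-9, -np.inf, 1e-9]
        hi = [np.inf] * 2 + [1e6] + [np.inf, 1e6, np.inf, 1e6]
        try:
            popt, _ = curve_fit(_phase_model, ts, x, p0=p0, bounds=(lo, hi),
                                maxfev=50000)
        except (RuntimeError, ValueError) as exc:
            raise FitFailureError(f"three-phase refinement failed: {exc}") from exc
        x0 = float(popt[0])
        amps = np.array(popt[1::2])
        rates = np.array(popt[2::2])
        order = np.argsort(rates)[::-1]
        amps, rates = amps[order], rates[order]
        resid = x - _phase_model(ts, *popt)
        x_eq = x0 + amps.sum()
        eq_warn = abs(float(x[-ntail:].mean()) - x_eq) > 3.0 * max(sd, 1e-12)
        return BindingDecomposition(
            float(amps[0]), float(amps[1]), float(amps[2]),
            float(rates[0]), float(rates[1]), float(rates[2]),
            x0, float(x_eq), (1, 2, 3), eq_warn, False,
            float(np.sum(resid**2)))

    # monotone trace: one vs two exponential phases, F-test selection
    fit1 = fit_exponential(trace, 1)
    if fit1.constant:
        x0 = fit1.x_eq
        return BindingDecomposition(0.0, 0.0, 0.0, math.nan, math.nan, math.nan,
                                    x0, x0, (), False, False, fit1.rss)
    try:
        fit2 = fit_exponential(trace, 2)
    except FitFailureError:
        fit2 = None
    use_two = False
    if fit2 is not None and fit2.n_rates == 2 and not fit2.fallback:
        n = len(x)
        df2 = n - 5
        if df2 > 0 and fit2.rss > 0:
            F = ((fit1.rss - fit2.rss) / 2.0) / (fit2.rss / df2)
            pval = stats.f.sf(F, 2, df2) if F > 0 else 1.0
            # each phase must contribute a detectable extension change
            # within the record, not merely a large extrapolated amplitude
            observed = np.abs(fit2.amplitudes
                              * (1.0 - np.exp(-fit2.rates * ts[-1])))
            amp_ok = np.all(observed > depth_sd * max(sd, 1e-12))
            use_two = (pval < alpha) and bool(amp_ok)
        if use_two:
            # the sequential scheme admits one compaction phase at most,
            # and compaction precedes (is faster than) any elongation
            neg = fit2.amplitudes < 0  # descending-rate order
            if neg.sum() == 2 or (neg.sum() == 1 and not neg[0]):
                use_two = False
    chosen = fit2 if use_two else fit1
    x_eq = chosen.x_eq
    x0 = x_eq - chosen.amplitudes.sum()
    eq_warn = abs(float(x[-ntail:].mean()) - x_eq) > 3.0 * max(sd, 1e-12)

    dx = {1: 0.0, 2: 0.0, 3: 0.0}
    kk = {1: math.nan, 2: math.nan, 3: math.nan}
    present = []
    if use_two:
        elong_slot = 2
        for a, k in zip(chosen.amplitudes, chosen.rates):  # descending rate
            if a < 0 and 1 not in present:
                dx[1], kk[1] = float(a), float(k)
                present.append(1)
            else:
                dx[elong_slot], kk[elong_slot] = float(a), float(k)
                present.append(elong_slot)
                elong_slot = 3
    else:
        a, k = float(chosen.amplitudes[0]), float(chosen.rates[0])
        slot = 1 if a < 0 else 3  # lone elongation equilibrates to x_eq
        dx[slot], kk[slot] = a, k
        present.append(slot)
    return BindingDecomposition(dx[1], dx[2], dx[3], kk[1], kk[2], kk[3],
                                float(x0), float(x_eq), tuple(sorted(present)),
                                eq_warn, bool(getattr(chosen, "fallback", False)),
                                chosen.rss)


@dataclass
class DissociationDecomposition:
    """Phases of a dissociation trace after removal of free protein.

    ``mode`` is one of "linear" (cluster-end dissociation, recompaction
    slope < 0 in nm/s), "linear_plus_exponential" (overcrowding regime) or
    "exponential".  ``normalized_slope`` is the linear slope divided by the
    magnitude of the total extension change, in s^-1 (reported alongside the
    raw slope because the natural units of the initial dissociation rate are
    ambiguous).
    """

    mode: str
    linear_slope: float = 0.0
    exp_amplitude: float = 0.0
    exp_rate: float = math.nan
    intercept: float = math.nan
    ambiguous: bool = False
    normalized_slope: float = math.nan
    aicc: dict = field(default_factory=dict)


def _aicc(rss: float, n: int, n_params: int) -> float:
    k = n_params + 1  # +1 for the residual variance
    if n - k - 1 <= 0 or rss <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def decompose_dissociation_trace(trace: TimeExtensionTrace) -> DissociationDecomposition:
    """Classify and fit a dissociation trace starting at buffer exchange.

    Candidate models — pure linear, linear + single decaying exponential,
    pure exponential — are fit by least squares and compared by corrected
    AIC.  Models within 2 AICc of the minimum are statistically
    indistinguishable; the simplest of those is returned, flagged
    ``ambiguous`` when more than one qualifies.
    """
    t, x = trace.time, trace.extension
    n = len(x)
    if n < 8:
        raise InsufficientDataError("dissociation decomposition needs >= 8 samples")
    ts = t - t[0]

    fits = {}
    # pure linear
    slope, intercept = np.polyfit(ts, x, 1)
    rss_lin = float(np.sum((x - (intercept + slope * ts)) ** 2))
    fits["linear"] = {"params": (float(intercept), float(slope)),
                      "rss": rss_lin, "k": 2}
    # pure exponential
    try:
        fe = _fit_multiexp(t, x, 1)
        fits["exponential"] = {"params": (fe.x_eq, float(fe.amplitudes[0]),
                                          float(fe.rates[0])),
                               "rss": fe.rss, "k": 3}
    except FitFailureError:
        pass
    # linear + exponential
    half = n // 2
    m0, b0 = np.polyfit(ts[half:], x[half:], 1)
    r = x - (b0 + m0 * ts)

    def linexp(tt, c, m, a, k):
        return c + m * tt - a * np.exp(-k * tt)

    a0 = -(r[0] - r[-1])
    kg = _rate_guess(ts, r, float(r[-1:].mean())) if np.ptp(r) > 0 else 1.0 / ts[-1]
    best = None
    for s in (1.0, 5.0, 0.2, 25.0):
        try:
            popt, _ = curve_fit(linexp, ts, x, p0=[b0, m0, -a0, kg * s],
                                bounds=([-np.inf, -np.inf, -np.inf, 1e-9],
                                        [np.inf, np.inf, np.inf, 1e6]),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((x - linexp(ts, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is not None:
        popt, rss = best
        fits["linear_plus_exponential"] = {
            "params": tuple(float(v) for v in popt), "rss": rss, "k": 4}

    # identifiability guards: an exponential component is only a real,
    # distinct phase when its decay is resolved within the record
    # (rate * span >= 1) and its amplitude exceeds 3x the noise SD;
    # otherwise it duplicates the linear model with extra parameters.
    sd = noise_sd(x)
    span = ts[-1]
    for name in ("exponential", "linear_plus_exponential"):
        if name in fits:
            amp, rate = fits[name]["params"][-2:]
            if abs(rate) * span < 1.0 or abs(amp) <= 3.0 * max(sd, 1e-12):
                del fits[name]

    aicc = {name: _aicc(f["rss"], n, f["k"]) for name, f in fits.items()}
    amin = min(aicc.values())
    candidates = [name for name, a in aicc.items() if a - amin < 2.0]
    mode = min(candidates, key=lambda name: fits[name]["k"])
    ambiguous = len(candidates) > 1

    total = abs(float(x[-1] - x[0]))
    out = DissociationDecomposition(mode, ambiguous=ambiguous, aicc=aicc)
    if mode == "linear":
        out.intercept, out.linear_slope = fits["linear"]["params"]
        if total > 0:
            out.normalized_slope = out.linear_slope / total
    elif mode == "exponential":
        out.intercept, out.exp_amplitude, out.exp_rate = fits["exponential"]["params"]
    else:
        c, m, a, k = fits["linear_plus_exponential"]["params"]
        out.intercept, out.linear_slope = c, m
        out.exp_amplitude, out.exp_rate = a, k
        if total > 0:
            out.normalized_slope = m / total
    return out


@dataclass
class RateSeries:
    """Rates (s^-1) vs force (pN) or free-protein concentration (nM)."""

    abscissa: np.ndarray
    rates: np.ndarray
    rate_uncertainties: Optional[np.ndarray] = None
    kind: str = "force"  # "force" | "concentration"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.abscissa.shape != self.rates.shape:
            raise ValueError("abscissa and rates must have equal length")
        if np.any(self.rates <= 0):
            raise ValueError("rates must be > 0")
        if self.rate_uncertainties is not None:
            self.rate_uncertainties = np.asarray(self.rate_uncertainties, dtype=float)
            if self.rate_uncertainties.shape != self.rates.shape:
                raise ValueError("rate_uncertainties must match rates")

    def __len__(self) -> int:
        return self.rates.size


@dataclass
class BellFit:
    """Bell-model fit k(F) = k0 exp(F dx / kBT); dx (nm) is signed."""

    k0: float
    delta_x: float
    k0_err: float = math.nan
    delta_x_err: float = math.nan

    def predict(self, force, constants: Constants = DEFAULT_CONSTANTS):
        return self.k0 * np.exp(np.asarray(force, dtype=float)
                                * self.delta_x / constants.kBT)


def fit_bell(series: RateSeries,
             constants: Constants = DEFAULT_CONSTANTS) -> BellFit:
    """Weighted linear regression of ln k on force.

    slope = dx/kBT so delta_x = slope*kBT (signed transition length);
    k0 = exp(intercept).  Weights follow from propagated log-uncertainties
    when the series carries per-point errors.
    """
    if len(series) < 3:
        raise InsufficientDataError("Bell fit needs >= 3 force points")
    F = series.abscissa
    y = np.log(series.rates)
    w = None
    if series.rate_uncertainties is not None:
        sigma_ln = series.rate_uncertainties / series.rates
        w = 1.0 / np.clip(sigma_ln, 1e-12, None)
    try:
        coef, cov = np.polyfit(F, y, 1, w=w, cov=True)
        errs = np.sqrt(np.diag(cov))
    except (np.linalg.LinAlgError, ValueError):
        coef = np.polyfit(F, y, 1, w=w)
        errs = np.array([math.nan, math.nan])
    slope, intercept = coef
    return BellFit(float(np.exp(intercept)), float(slope * constants.kBT),
                   float(np.exp(intercept) * errs[1]),
                   float(errs[0] * constants.kBT))


@dataclass
class BimolecularFit:
    """kobs = c*k_on + k_off; K_D = k_off/k_on (nM)."""

    k_on: float
    k_off: float
    K_D: float
    unreliable: bool = False  # non-positive fitted rate: extrapolation suspect


def fit_bimolecular(series: RateSeries) -> BimolecularFit:
    """Weighted linear regression of observed rate on concentration."""
    if len(series) < 2:
        raise InsufficientDataError("bimolecular fit needs >= 2 concentrations")
    w = None
    if series.rate_uncertainties is not None:
        w = 1.0 / np.clip(series.rate_uncertainties, 1e-12, None)
    k_on, k_off = np.polyfit(series.abscissa, series.rates, 1, w=w)
    unreliable = bool(k_on <= 0 or k_off < 0)
    kd = compute_kd(float(k_off), float(k_on)) if k_on > 0 else math.nan
    return BimolecularFit(float(k_on), float(k_off), kd, unreliable)


@dataclass
class TwoStepFit:
    """Sequential two-step binding: k(c) = c k_b k_c / (c k_b + k_c).

    Linear at low concentration (slope k_b, the diffusion-limited on-rate in
    nM^-1 s^-1) and saturating at the compaction/oligomerization rate k_c
    (s^-1) at high concentration.
    """

    k_b: float
    k_c: float
    k_b_err: float = math.nan
    k_c_err: float = math.nan
    k_c_unbounded: bool = False

    def predict(self, c):
        c = np.asarray(c, dtype=float)
        return c * self.k_b * self.k_c / (c * self.k_b + self.k_c)


def fit_two_step(series: RateSeries) -> TwoStepFit:
    """Fit the saturating two-step rate law to a concentration series."""
    if len(series) < 3:
        raise InsufficientDataError("two-step fit needs >= 3 concentrations")
    c, k = series.abscissa, series.rates
    sigma = series.rate_uncertainties

    def model(cc, kb, kc):
        return cc * kb * kc / (cc * kb + kc)

    p0 = [max(k[0] / max(c[0], 1e-9), 1e-9), 1.2 * float(k.max())]
    try:
        popt, pcov = curve_fit(model, c, k, p0=p0, sigma=sigma,
                               bounds=([1e-12, 1e-12], [1e6, 1e9]), maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"two-step fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    kb, kc = float(popt[0]), float(popt[1])
    unbounded = bool(kc > 10.0 * float(k.max()))
    if unbounded:
        warnings.warn("two-step fit: data lie in the linear regime, "
                      "k_c is effectively unbounded", stacklevel=2)
    return TwoStepFit(kb, kc, float(perr[0]), float(perr[1]), unbounded)


def compute_kd(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (nM)."""
    if k_on <= 0 or k_off < 0:
        raise ValueError("require k_on > 0 and k_off >= 0")
    return k_off / k_on
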