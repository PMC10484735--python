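"""AFM backbone-trace statistics and height-image volume analysis.

Surface-deposited filaments behave as two-dimensional worm-like chains:
the mean cosine of the tangent-angle difference between two points
separated by arc length L decays as exp(-L/2p), so the persistence length
p follows from a single-parameter fit to the tangent-correlation profile.
Because deposited strands preserve solution loops (self-crossings that
anticorrelate tangents), persistence is measured on the longest loop-free
segment of each molecule, while contour length uses the whole trace.
Integrated height-above-background volume serves as a proxy for the total
protein bound.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .errors import FitFailureError, InsufficientDataError

__all__ = [
    "BackboneTrace",
    "TangentCorrelationProfile",
    "AFMImage",
    "PersistenceFit",
    "trace_contour_length",
    "resample_trace",
    "tangent_correlation",
    "fit_persistence_2d",
    "longest_loopfree_segment",
    "integrated_volume",
    "trace_image",
]


@dataclass
class BackboneTrace:
    """Ordered 2-D coordinates (nm) of one traced molecule."""

    points: np.ndarray
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (N, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a trace needs >= 3 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive points must be distinct")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class TangentCorrelationProfile:
    """<cos theta> vs arc-length separation, pooled over molecules."""

    separations: np.ndarray
    mean_cos: np.ndarray
    n_pairs: np.ndarray
    sem: Optional[np.ndarray] = None  # across-molecule SEM where defined


@dataclass
class AFMImage:
    """Height grid (nm) with square pixels of side pixel_size (nm)."""

    heights: np.ndarray
    pixel_size: float
    background: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D grid")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


def trace_contour_length(trace: BackboneTrace) -> float:
    """Total contour length: sum of consecutive segment lengths, nm."""
    return float(trace.arc_lengths[-1])


def resample_trace(trace: BackboneTrace, step: float) -> BackboneTrace:
    """Resample a trace at uniform arc-length spacing ``step`` (nm).

    Linear interpolation along the polyline; the final point is kept so the
    resampled contour spans the full original arc length.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    s = trace.arc_lengths
    total = s[-1]
    if total < 2 * step:
        raise InsufficientDataError("trace shorter than two resample steps")
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-9:
        targets = np.append(targets, total)
    x = np.interp(targets, s, trace.points[:, 0])
    y = np.interp(targets, s, trace.points[:, 1])
    return BackboneTrace(np.column_stack([x, y]), trace.molecule_id)


def _unit_tangents(points: np.ndarray) -> np.ndarray:
    d = np.diff(points, axis=0)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def tangent_correlation(traces: Sequence[BackboneTrace], resample_step: float = 5.0,
                        max_separation: Optional[float] = None,
                        weighting: str = "molecule") -> TangentCorrelationProfile:
    """Tangent-correlation profile <cos theta>(L) of a trace ensemble.

    Each trace is resampled to uniform arc step; tangents come from the
    local segment direction.  For each separation L = k*step the cosine of
    the tangent-angle difference is averaged within each molecule, then —
    with the default equal-molecule ``weighting`` — averaged across
    molecules; ``weighting="pooled"`` instead pools all pairs.  Traces
    shorter than two resample steps are skipped with a warning.
    """
    if weighting not in ("molecule", "pooled"):
        raise ValueError("weighting must be 'molecule' or 'pooled'")
    per_mol = []
    counts = []
    max_k = 0
    for tr in traces:
        try:
            rs = resample_trace(tr, resample_step)
        except InsufficientDataError:
            warnings.warn(f"trace {tr.molecule_id!r} shorter than two resample "
                          "steps; skipped", stacklevel=2)
            continue
        t = _unit_tangents(rs.points)
        m = t.shape[0]
        kmax = m - 1
        if max_separation is not None:
            kmax = min(kmax, int(max_separation / resample_step))
        if kmax < 1:
            continue
        mc = np.empty(kmax + 1)
        npair = np.empty(kmax + 1, dtype=int)
        mc[0], npair[0] = 1.0, m
        for k in range(1, kmax + 1):
            dots = np.sum(t[:-k] * t[k:], axis=1)
            mc[k] = dots.mean()
            npair[k] = dots.size
        per_mol.append(mc)
        counts.append(npair)
        max_k = max(max_k, kmax)
    if not per_mol:
        raise InsufficientDataError("no trace long enough for the resample step")

    seps = np.arange(max_k + 1) * resample_step
    mean_cos = np.full(max_k + 1, np.nan)
    n_pairs = np.zeros(max_k + 1, dtype=int)
    sem = np.full(max_k + 1, np.nan)
    for k in range(max_k + 1):
        vals = np.array([m[k] for m in per_mol if len(m) > k])
        cnts = np.array([c[k] for c, m in zip(counts, per_mol) if len(m) > k])
        n_pairs[k] = cnts.sum()
        if weighting == "molecule":
            mean_cos[k] = vals.mean()
        else:
            mean_cos[k] = np.sum(vals * cnts) / cnts.sum()
        if len(vals) > 1:
            sem[k] = vals.std(ddof=1) / math.sqrt(len(vals))
    return TangentCorrelationProfile(seps, mean_cos, n_pairs, sem)


@dataclass
class PersistenceFit:
    """Single-parameter fit of exp(-L/2p) to a tangent-correlation profile."""

    persistence: float
    persistence_err: float = math.nan
    unbounded: bool = False  # profile consistent with a straight line
    n_points: int = 0


def fit_persistence_2d(profile: TangentCorrelationProfile,
                       L_max: float) -> PersistenceFit:
    """Fit the 2-D worm-like-chain decay <cos theta> = exp(-L/2p) on [0, L_max]."""
    mask = ((profile.separations <= L_max) & np.isfinite(profile.mean_cos)
            & (profile.mean_cos > 0))
    L = profile.separations[mask]
    y = profile.mean_cos[mask]
    if len(L) < 3:
        raise FitFailureError(
            "need >= 3 separations below L_max with positive mean cos "
            "(over-flexible or loop-dominated input)")

    def model(LL, p):
        return np.exp(-LL / (2.0 * p))

    try:
        popt, pcov = curve_fit(model, L, y, p0=[L_max / 2.0],
                               bounds=(1e-9, np.inf), maxfev=20000)
    except RuntimeError as exc:
        raise FitFailureError(f"persistence fit did not converge: {exc}") from exc
    p = float(popt[0])
    perr = float(np.sqrt(pcov[0, 0]))
    unbounded = p > 100.0 * L_max  # decay not resolved within the window
    return PersistenceFit(p, perr, unbounded, int(len(L)))


def longest_loopfree_segment(trace: BackboneTrace,
                             contact_radius: float = 4.0) -> BackboneTrace:
    """Longest contiguous stretch of a trace free of self-contacts.

    A self-contact is a pair of points closer than ``contact_radius`` in
    the plane but separated by more than 4x that radius along the arc
    (excluding trivially adjacent points).  Both members of every contact
    split the trace; the longest arc-length run between splits is returned.
    The whole trace is returned when no contact exists.
    """
    if contact_radius <= 0:
        raise ValueError("contact_radius must be > 0")
    pts = trace.points
    s = trace.arc_lengths
    tree = cKDTree(pts)
    pairs = tree.query_pairs(contact_radius, output_type="ndarray")
    cut = set()
    for i, j in pairs:
        if abs(s[j] - s[i]) > 4.0 * contact_radius:
            cut.add(int(i))
            cut.add(int(j))
    if not cut:
        return trace
    # contiguous index runs avoiding every contact point, best by arc length
    boundaries = sorted(cut)
    runs = []
    prev = -1
    for b in boundaries + [len(pts)]:
        if b - prev > 1:
            runs.append((prev + 1, b - 1))
        prev = b
    best = None
    for lo, hi in runs:
        if hi - lo + 1 < 3:
            continue
        length = s[hi] - s[lo]
        if best is None or length > best[0]:
            best = (length, lo, hi)
    if best is None:
        raise InsufficientDataError("no loop-free run of >= 3 points")
    _, lo, hi = best
    return BackboneTrace(pts[lo:hi + 1], trace.molecule_id)


def integrated_volume(image: AFMImage, background: Optional[float] = None) -> float:
    """Integrated volume sum(max(h - background, 0)) * pixel_size^2, nm^3.

    The background defaults to the image's ``background`` attribute or,
    failing that, the image median (molecules cover a small area fraction).
    """
    if background is None:
        background = image.background
    if background is None:
        background = float(np.median(image.heights))
    excess = np.clip(image.heights - background, 0.0, None)
    return float(excess.sum() * image.pixel_size**2)


def trace_image(image: AFMImage, threshold: Optional[float] = None) -> BackboneTrace:
    """Ridge-follow the skeleton of a (synthetic) molecule image.

    Intended for images produced by the synthetic generator: the height
    field is thresholded halfway between background and peak, skeletonized,
    and the skeleton pixels ordered by nearest-neighbour walking from an
    endpoint.  Not a general-purpose tracer for experimental scans.
    """
    from skimage.morphology import skeletonize

    h = image.heights
    bg = image.background if image.background is not None else float(np.median(h))
    if threshold is None:
        threshold = bg + 0.5 * (float(h.max()) - bg)
    mask = h > threshold
    if not mask.any():
        raise InsufficientDataError("no pixels above threshold")
    skel = skeletonize(mask)
    rows, cols = np.nonzero(skel)
    coords = np.column_stack([cols, rows]).astype(float)  # (x, y) in pixels
    if coords.shape[0] < 3:
        raise InsufficientDataError("skeleton too short to trace")
    # order by nearest-neighbour walk from an extremal endpoint
    remaining = list(range(coords.shape[0]))
    start = int(np.argmin(coords[:, 0] + coords[:, 1]))
    order = [start]
    remaining.remove(start)
    while remaining:
        last = coords[order[-1]]
        d = np.linalg.norm(coords[remaining] - last, axis=1)
        nxt = int(np.argmin(d))
        if d[nxt] > 3.0:  # disconnected fragment; stop at the main branch
            break
        order.append(remaining.pop(nxt))
    # pixel-center convention: cell (i, j) sits at (j + 0.5, i + 0.5) px
    pts = (coords[order] + 0.5) * image.pixel_size
    return BackboneTrace(pts, image.meta.get("molecule_id", "skeleton"))
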