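"""Quantification of two-channel confocal stacks.

Implements the measurement chain used on timelapse stacks of expanding
biofilms: per-timepoint robust background thresholds (substrate-ROI median
plus a multiple of the MAD), threshold-gated z-projections, slice-averaged
cross-sections, radial ratio profiles (sporulation over constitutive for
dual-positive voxels), leading-edge and sporulation-front extraction,
parsimonious two-phase linear fits of position-time curves, and
per-position velocity-ratio comparison of the two fronts.

All functions are deterministic: identical stack and configuration yield
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .imaging import ImageStack
from .observables import (
    FrontTrajectory,
    VelocityRatioCurve,
    _front_position,
    velocity_ratio_curve,
)

__all__ = [
    "ThresholdSpec",
    "RadialProfile",
    "TwoPhaseFit",
    "compute_threshold",
    "z_project",
    "cross_section",
    "ratio_profile",
    "intensity_profile",
    "leading_edge_from_image",
    "vegetative_front",
    "sporulation_front_from_profile",
    "two_phase_fit",
    "compare_front_velocities",
    "quantify_stack",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdSpec:
    """Placement and strength of the per-timepoint background threshold.

    The ROI sits on the substrate ``roi_offset`` um beyond the current
    leading-edge estimate, measures ``roi_size`` (radial x transverse) um,
    and the threshold is ``median + n_mad[channel] * MAD`` of the
    maximum-intensity z-projection inside the ROI.
    """

    roi_offset: float = 20.0
    roi_size: tuple[float, float] = (40.0, 40.0)
    n_mad: Dict[str, float] = field(
        default_factory=lambda: {"constitutive": 4.0, "sporulation": 4.0}
    )

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.n_mad.values()):
            raise ValueError("n_mad multipliers must be >= 0")
        if min(self.roi_size) <= 0:
            raise ValueError("roi_size must be positive")

    @classmethod
    def wide_field(cls) -> "ThresholdSpec":
        """Preset for 10x-class data: 70x100 um ROI, n=2 (constitutive) / 1."""
        return cls(
            roi_size=(70.0, 100.0),
            n_mad={"constitutive": 2.0, "sporulation": 1.0},
        )


@dataclass
class RadialProfile:
    """A 1D quantity versus radial position at one timepoint."""

    t: float
    positions: np.ndarray  # um from the biofilm center, increasing
    values: np.ndarray  # NaN where undefined
    slice_width: float = 0.0  # um averaged transversely (0: full strip)
    smoothing_sigma: float = 0.0  # um

    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def compute_threshold(
    stack: ImageStack,
    frame: int,
    channel: str,
    spec: ThresholdSpec,
    edge_radius: float,
) -> float:
    """Background threshold from a substrate ROI beyond the leading edge.

    ``edge_radius`` (um) is the current leading-edge estimate used to place
    the ROI (for the first frame, bootstrap with the inoculum radius).
    """
    voxels = stack.channels[channel][frame]
    proj = voxels.max(axis=0)  # maximum-intensity z-projection
    ps = stack.pixel_size
    oy, ox = stack.origin
    x0 = int(round(ox + (edge_radius + spec.roi_offset) / ps))
    w = max(1, int(round(spec.roi_size[0] / ps)))
    hh = max(1, int(round(spec.roi_size[1] / ps)))
    y0 = int(round(oy - hh / 2))
    ny, nx = proj.shape
    if x0 < 0 or x0 + w > nx or y0 < 0 or y0 + hh > ny:
        raise ValueError(
            f"threshold ROI [{y0}:{y0 + hh}, {x0}:{x0 + w}] falls outside the "
            f"{ny}x{nx} frame"
        )
    roi = proj[y0 : y0 + hh, x0 : x0 + w].astype(float)
    return float(np.median(roi) + spec.n_mad[channel] * _mad(roi))


def z_project(
    stack: ImageStack,
    frame: int,
    channel: str,
    mode: str = "mean",
    threshold: float = 0.0,
) -> np.ndarray:
    """Z-projection over threshold-passing voxels.

    ``mean``/``sum`` aggregate only voxels at or above the threshold
    (pixels where none pass are 0); ``max`` is a plain maximum projection
    (used for the threshold ROI itself).
    """
    voxels = stack.channels[channel][frame].astype(float)
    if mode == "max":
        return voxels.max(axis=0)
    passing = voxels >= threshold
    total = np.where(passing, voxels, 0.0).sum(axis=0)
    if mode == "sum":
        return total
    if mode == "mean":
        count = passing.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(count > 0, total / np.maximum(count, 1), 0.0)
        return out
    raise ValueError(f"unknown projection mode: {mode!r}")


def cross_section(
    stack: ImageStack, frame: int, channel: str, slice_width: float = 40.0
) -> np.ndarray:
    """(Z, X) radius-depth image averaged over a radial slice.

    The slice runs along the +x axis through the biofilm center and is
    averaged over ``ceil(slice_width / pixel_size)`` transverse pixels
    (28 px at 1.43 um/px, 12 px at 3.58 um/px).
    """
    voxels = stack.channels[channel][frame].astype(float)
    oy, _ = stack.origin
    w = max(1, int(np.ceil(slice_width / stack.pixel_size)))
    y0 = int(round(oy - w / 2))
    y0 = max(0, min(y0, voxels.shape[1] - w))
    return voxels[:, y0 : y0 + w, :].mean(axis=1)


def _smooth_nan(values: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing that ignores NaNs and preserves their positions."""
    if sigma_px <= 0:
        return values
    mask = np.isfinite(values)
    filled = np.where(mask, values, 0.0)
    num = gaussian_filter1d(filled, sigma_px, mode="nearest")
    den = gaussian_filter1d(mask.astype(float), sigma_px, mode="nearest")
    with np.errstate(invalid="ignore"):
        out = np.where(mask & (den > 0), num / den, np.nan)
    return out


def _radial_bin(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel radial bin index (1-pixel-wide bins) and bin centers (um)."""
    rad_px = stack.radius_map() / stack.pixel_size
    idx = np.rint(rad_px).astype(int)
    n_bins = idx.max() + 1
    centers = np.arange(n_bins) * stack.pixel_size
    return idx, centers


def ratio_profile(
    stack: ImageStack,
    frame: int,
    thresholds: Dict[str, float],
    smoothing_sigma: float = 10.0,
    max_radius: Optional[float] = None,
) -> RadialProfile:
    """Radial profile of the sporulation/constitutive intensity ratio.

    Voxel ratios are averaged over z and the transverse direction for
    dual-positive voxels (both channels at or above their thresholds);
    positions without any dual-positive voxel are NaN.  The profile is
    smoothed with a 1D Gaussian (``smoothing_sigma`` um).  Invariant under
    multiplying both channels by the same positive constant.
    """
    spor = stack.channels["sporulation"][frame].astype(float)
    const = stack.channels["constitutive"][frame].astype(float)
    dual = (spor >= thresholds["sporulation"]) & (const >= thresholds["constitutive"])
    dual &= const > 0
    idx, centers = _radial_bin(stack)
    idx3 = np.broadcast_to(idx, spor.shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(dual, spor / np.maximum(const, 1e-30), 0.0)
    sums = np.bincount(idx3[dual], weights=ratios[dual], minlength=len(centers))
    counts = np.bincount(idx3[dual], minlength=len(centers))
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if max_radius is not None:
        values[centers > max_radius] = np.nan  # noise-passing substrate voxels
    values = _smooth_nan(values, smoothing_sigma / stack.pixel_size)
    return RadialProfile(
        t=float(stack.times[frame]),
        positions=centers,
        values=values,
        smoothing_sigma=smoothing_sigma,
    )


def intensity_profile(
    stack: ImageStack,
    frame: int,
    channel: str,
    threshold: float,
    smoothing_sigma: float = 10.0,
    max_radius: Optional[float] = None,
) -> RadialProfile:
    """Radial profile of mean threshold-passing intensity for one channel."""
    voxels = stack.channels[channel][frame].astype(float)
    passing = voxels >= threshold
    idx, centers = _radial_bin(stack)
    idx3 = np.broadcast_to(idx, voxels.shape)
    sums = np.bincount(idx3[passing], weights=voxels[passing], minlength=len(centers))
    counts = np.bincount(idx3[passing], minlength=len(centers))
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if max_radius is not None:
        values[centers > max_radius] = np.nan
    values = _smooth_nan(values, smoothing_sigma / stack.pixel_size)
    return RadialProfile(
        t=float(stack.times[frame]),
        positions=centers,
        values=values,
        smoothing_sigma=smoothing_sigma,
    )


def leading_edge_from_image(
    projection: np.ndarray,
    threshold: float,
    origin: tuple[float, float],
    pixel_size: float,
    smoothing_sigma: float = 2.0,
) -> float:
    """Outermost radius (um) with above-threshold biomass signal.

    Works on a threshold-gated projection of the constitutive channel: the
    radially binned mean is lightly smoothed (``smoothing_sigma`` um,
    deliberately narrow to avoid blurring the edge outward) and the most
    distal position above the threshold is returned.  Raises ValueError
    when no position qualifies.
    """
    oy, ox = origin
    yy, xx = np.mgrid[0 : projection.shape[0], 0 : projection.shape[1]]
    idx = np.rint(np.hypot(yy - oy, xx - ox)).astype(int)
    sums = np.bincount(idx.ravel(), weights=projection.ravel().astype(float))
    counts = np.bincount(idx.ravel())
    profile = sums / np.maximum(counts, 1)
    profile = gaussian_filter1d(profile, max(smoothing_sigma / pixel_size, 1e-6))
    above = np.flatnonzero(profile > threshold)
    if len(above) == 0:
        raise ValueError("no above-threshold biomass signal in projection")
    return float(above[-1] * pixel_size)


def vegetative_front(
    profile: RadialProfile, prominence_frac: float = 0.1
) -> tuple[float, float]:
    """[inner, edge] extent of the vegetative cell front.

    Finds the most peripheral local maximum of the (smoothed) constitutive
    profile with prominence at least ``prominence_frac`` of the profile
    range; the inner boundary is that peak's left base (where the profile
    last descended to the prominence baseline on the center-facing side).
    Falls back to the whole profile when no such peak exists.
    """
    ok = profile.valid()
    vals = profile.values[ok]
    pos = profile.positions[ok]
    if len(vals) < 3:
        raise ValueError("profile too short for front detection")
    prominence = prominence_frac * (vals.max() - vals.min())
    peaks, props = find_peaks(vals, prominence=max(prominence, 1e-12))
    edge = float(pos[-1])
    if len(peaks) == 0:
        logger.info("no local maximum in profile at t=%.3g; using whole biofilm", profile.t)
        return float(pos[0]), edge
    last = len(peaks) - 1  # most peripheral peak
    inner = float(pos[props["left_bases"][last]])
    return inner, edge


def sporulation_front_from_profile(profile: RadialProfile) -> float:
    """Most distal position where the profile reaches 75% of its maximum."""
    ok = profile.valid()
    if not np.any(ok):
        raise ValueError("empty profile: sporulation front undefined")
    return _front_position(profile.positions[ok], profile.values[ok])


@dataclass
class TwoPhaseFit:
    """Continuous two-segment linear description of a position-time curve."""

    breakpoint_time: float
    breakpoint_position: float
    slope1: float
    slope2: float
    intercept: float
    two_phase: bool  # False when a single line is more parsimonious
    sse: float
    sse_single: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        if not self.two_phase:
            return self.intercept + self.slope1 * t
        return (
            self.intercept
            + self.slope1 * t
            + (self.slope2 - self.slope1) * np.maximum(t - self.breakpoint_time, 0.0)
        )


def two_phase_fit(times: Sequence[float], positions: Sequence[float]) -> TwoPhaseFit:
    """Most parsimonious two-phase linear fit of position vs time.

    Exhaustively evaluates continuous two-segment least-squares fits with
    the breakpoint at each interior sample time (at least two samples per
    segment), picks the SSE-minimizing breakpoint, and prefers a single
    line when the Bayesian information criterion does not favour the extra
    two parameters (second slope and breakpoint).
    """
    t = np.asarray(times, float)
    y = np.asarray(positions, float)
    m = len(t)
    if m < 6:
        raise ValueError(f"need at least 6 samples for a two-phase fit, got {m}")
    order = np.argsort(t)
    t, y = t[order], y[order]

    X1 = np.column_stack([np.ones(m), t])
    coef1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse1 = float(res1[0]) if len(res1) else float(np.sum((y - X1 @ coef1) ** 2))

    best = None
    for i in range(2, m - 2):
        tb = t[i]
        X = np.column_stack([np.ones(m), t, np.maximum(t - tb, 0.0)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((y - X @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tb, coef)
    sse2, tb, coef = best

    eps = 1e-12 * m * max(float(np.var(y)), 1.0)
    bic1 = m * np.log(max(sse1, eps) / m) + 2 * np.log(m)
    bic2 = m * np.log(max(sse2, eps) / m) + 4 * np.log(m)
    two_phase = bic2 < bic1

    slope1 = float(coef[1])
    slope2 = float(coef[1] + coef[2])
    intercept = float(coef[0])
    if not two_phase:
        slope1 = slope2 = float(coef1[1])
        intercept = float(coef1[0])
    bp_pos = float(intercept + float(coef[1]) * tb) if two_phase else float(np.interp(tb, t, y))
    return TwoPhaseFit(
        breakpoint_time=float(tb),
        breakpoint_position=bp_pos,
        slope1=slope1,
        slope2=slope2,
        intercept=intercept,
        two_phase=two_phase,
        sse=sse2,
        sse_single=sse1,
    )


def _refine(times: np.ndarray, positions: np.ndarray, factor: int) -> tuple[np.ndarray, np.ndarray]:
    fine = np.linspace(times[0], times[-1], (len(times) - 1) * factor + 1)
    return fine, np.interp(fine, times, positions)


def _retrograde_boundary(positions: np.ndarray, tol: float = 1e-9) -> Optional[float]:
    """Last position before the front transiently regresses toward the center.

    Only regressions during the outward sweep count (after the series
    minimum); the initial interior collapse of a freshly ignited wave is
    not a tracking artefact.
    """
    start = int(np.argmin(positions))
    p = positions[start:]
    drops = np.flatnonzero(np.diff(p) < -tol)
    if len(drops) == 0:
        return None
    return float(p[drops[0]])


def compare_front_velocities(
    edge_times: np.ndarray,
    edge_positions: np.ndarray,
    front_times: np.ndarray,
    front_positions: np.ndarray,
    bin_width: float = 25.0,
    interp_factor: int = 4,
    apply_two_phase_boundary: bool = True,
) -> VelocityRatioCurve:
    """Per-position velocity ratio of the sporulation front to the edge.

    Both position series are refined 4-fold by linear interpolation before
    finite-difference velocities are taken.  Positions beyond the distal
    analysis boundary are excluded: the boundary is the two-phase-fit
    inflection of the leading-edge curve (separating fast and slow
    expansion) and, if the measured front transiently regresses, the last
    position before retrograde movement, whichever is more proximal.
    """
    edge_times = np.asarray(edge_times, float)
    edge_positions = np.asarray(edge_positions, float)
    front_times = np.asarray(front_times, float)
    front_positions = np.asarray(front_positions, float)

    boundary = np.inf
    if apply_two_phase_boundary and len(edge_times) >= 6:
        fit = two_phase_fit(edge_times, edge_positions)
        if fit.two_phase:
            boundary = fit.breakpoint_position
    retro = _retrograde_boundary(front_positions)
    if retro is not None:
        boundary = min(boundary, retro)

    te, pe = _refine(edge_times, edge_positions, interp_factor)
    tf, pf = _refine(front_times, front_positions, interp_factor)
    ve = np.gradient(pe, te)
    vf = np.gradient(pf, tf)
    ve[0] = vf[0] = 0.0
    keep_e = pe <= boundary
    keep_f = pf <= boundary
    if keep_e.sum() < 2 or keep_f.sum() < 2:
        raise ValueError("distal boundary excludes (almost) all samples")
    edge_traj = FrontTrajectory(
        kind="leading_edge",
        times=te[keep_e],
        positions=pe[keep_e],
        velocities=ve[keep_e],
        smoothing_window=0.0,
    )
    front_traj = FrontTrajectory(
        kind="sporulation_front",
        times=tf[keep_f],
        positions=pf[keep_f],
        velocities=vf[keep_f],
        smoothing_window=0.0,
    )
    return velocity_ratio_curve(edge_traj, front_traj, bin_width)


# ---------------------------------------------------------------------------
# per-stack driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantConfig:
    """End-to-end quantification settings for one stack."""

    threshold: ThresholdSpec = ThresholdSpec()
    inoculum_radius: float = 1140.0  # um; ROI bootstrap for the first frame
    profile_sigma: float = 10.0  # um, ratio/intensity profile smoothing
    edge_sigma: float = 2.0  # um, edge-detection smoothing
    bin_width: float = 25.0  # um, velocity-ratio bins


@dataclass
class QuantResult:
    """Tables produced by :func:`quantify_stack`."""

    thresholds: pd.DataFrame  # frame, t, channel, threshold
    edge: pd.DataFrame  # frame, t, radius_um
    front: pd.DataFrame  # frame, t, radius_um (NaN where undefined)
    profiles: pd.DataFrame  # long format: frame, t, position_um, ratio


def _coarse_edge(stack: ImageStack, frame: int) -> float:
    """Rough biomass extent for ROI placement, no threshold needed.

    The half-maximum of the radially binned max-intensity constitutive
    projection separates biomass (bright) from substrate background even
    before the background statistics are known.
    """
    proj = stack.channels["constitutive"][frame].max(axis=0).astype(float)
    oy, ox = stack.origin
    yy, xx = np.mgrid[0 : proj.shape[0], 0 : proj.shape[1]]
    idx = np.rint(np.hypot(yy - oy, xx - ox)).astype(int)
    sums = np.bincount(idx.ravel(), weights=proj.ravel())
    counts = np.bincount(idx.ravel())
    profile = gaussian_filter1d(sums / np.maximum(counts, 1), 2.0)
    above = np.flatnonzero(profile >= 0.5 * profile.max())
    return float(above[-1] * stack.pixel_size)


def quantify_stack(stack: ImageStack, config: QuantConfig = QuantConfig()) -> QuantResult:
    """Run the full measurement chain on every frame of a stack.

    The threshold ROI is placed per frame from a coarse (half-maximum)
    edge estimate of that frame's own constitutive projection — the edge
    can advance by more than the ROI offset within one frame interval, so
    chaining the previous frame's measurement would park the ROI on
    biomass.  The configured inoculum radius serves as a floor for the
    first frame.
    """
    thr_rows, edge_rows, front_rows, prof_rows = [], [], [], []
    edge_estimate = config.inoculum_radius
    for i, t in enumerate(stack.times):
        edge_estimate = max(_coarse_edge(stack, i), edge_estimate if i == 0 else 0.0)
        thresholds = {
            ch: compute_threshold(stack, i, ch, config.threshold, edge_estimate)
            for ch in stack.channels
        }
        for ch, thr in thresholds.items():
            thr_rows.append((i, t, ch, thr))
        proj = z_project(stack, i, "constitutive", "mean", thresholds["constitutive"])
        edge = leading_edge_from_image(
            proj,
            thresholds["constitutive"],
            stack.origin,
            stack.pixel_size,
            config.edge_sigma,
        )
        edge_rows.append((i, t, edge))
        prof = ratio_profile(
            stack, i, thresholds, config.profile_sigma, max_radius=edge
        )
        for p, v in zip(prof.positions, prof.values):
            if np.isfinite(v):
                prof_rows.append((i, t, p, v))
        try:
            front = sporulation_front_from_profile(prof)
        except ValueError:
            logger.info("frame %d (t=%.3g hr): sporulation front undefined", i, t)
            front = np.nan
        front_rows.append((i, t, front))
    return QuantResult(
        thresholds=pd.DataFrame(thr_rows, columns=["frame", "t", "channel", "threshold"]),
        edge=pd.DataFrame(edge_rows, columns=["frame", "t", "radius_um"]),
        front=pd.DataFrame(front_rows, columns=["frame", "t", "radius_um"]),
        profiles=pd.DataFrame(prof_rows, columns=["frame", "t", "position_um", "ratio"]),
    )
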