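"""Quantitative readouts of a simulation run.

Turns snapshot sequences into the study's observables: bulk spore
percentage, front trajectories (leading edge, sporulation-flux front, cell
region) with 1-hour-smoothed instantaneous velocities, and per-position
velocity-ratio curves comparing how fast the sporulation wave moves through
biomass relative to how fast the leading edge moved through the same
positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import ModelParams, SimulationState, hill_sporulation_rate
from .simulate import SimulationRun

__all__ = [
    "FrontTrajectory",
    "VelocityRatioCurve",
    "instantaneous_velocities",
    "bulk_spore_percentage",
    "spore_percentage_curve",
    "leading_edge",
    "sporulation_front",
    "cell_region",
    "velocity_ratio_curve",
    "trajectory_overlay_rms",
]

logger = logging.getLogger(__name__)

#: fraction of the maximum flux/ratio profile defining the sporulation front
FRONT_LEVEL = 0.75


@dataclass
class FrontTrajectory:
    """Time-indexed positions of a tracked front with smoothed velocities."""

    kind: str  # leading_edge | sporulation_front | cell_region_boundary
    times: np.ndarray  # hr, strictly increasing
    positions: np.ndarray  # um
    velocities: np.ndarray  # um/hr; first entry 0 by convention
    smoothing_window: float = 1.0  # hr

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if len(self.velocities) != len(self.times):
            raise ValueError("velocities must align with times")

    def mean_velocity(self) -> tuple[float, float]:
        """Mean and standard deviation of the instantaneous velocity."""
        return float(np.mean(self.velocities)), float(np.std(self.velocities))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "t": self.times,
                "position": self.positions,
                "velocity": self.velocities,
            }
        )


@dataclass
class VelocityRatioCurve:
    """Per-radial-bin pairing of front and expansion velocities.

    For each radial bin both fronts crossed, ``expansion_velocity`` is the
    instantaneous leading-edge velocity when the edge first crossed the bin
    and ``front_velocity`` the sporulation-front velocity when the wave
    first crossed the same bin; ``ratio`` is front over expansion.
    """

    positions: np.ndarray  # bin centers, um
    expansion_velocity: np.ndarray
    front_velocity: np.ndarray
    ratio: np.ndarray
    bin_width: float = 25.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.positions,
                "v_edge": self.expansion_velocity,
                "v_front": self.front_velocity,
                "ratio": self.ratio,
            }
        )


def instantaneous_velocities(
    times: np.ndarray, positions: np.ndarray, window: float = 1.0
) -> np.ndarray:
    """Centered-difference velocities smoothed with a boxcar of ``window`` hr.

    The first sample is set to 0 (no motion estimate before the first
    interval).  Translation-invariant: shifting all positions by a constant
    leaves the result unchanged.
    """
    times = np.asarray(times, float)
    positions = np.asarray(positions, float)
    if len(times) < 2:
        raise ValueError("need at least 2 samples to estimate velocities")
    vel = np.gradient(positions, times)
    dt = float(np.median(np.diff(times)))
    width = max(1, int(round(window / dt)))
    if width > 1:
        kernel = np.ones(width) / width
        # reflect-pad so the boxcar does not shrink near the ends
        padded = np.concatenate(
            [vel[width - 1 : 0 : -1], vel, vel[-2 : -width - 1 : -1]]
        )
        vel = np.convolve(padded, kernel, mode="valid")
        vel = vel[(len(vel) - len(times)) // 2 :][: len(times)]
    vel = vel.copy()
    vel[0] = 0.0
    return vel


def _biofilm_integral(state: SimulationState, values: np.ndarray) -> float:
    ins = state.inside
    return float(np.trapezoid(values[ins] * state.r[ins], state.r[ins]))


def bulk_spore_percentage(state: SimulationState) -> float:
    """Spore share of total biomass, 100 * int(rho2 r dr) / int((rho1+rho2) r dr)."""
    total = _biofilm_integral(state, state.rho1 + state.rho2)
    if not np.any(state.inside) or total <= 0:
        raise ValueError("empty biofilm: bulk spore percentage undefined")
    return 100.0 * _biofilm_integral(state, state.rho2) / total


def spore_percentage_curve(run: SimulationRun) -> pd.DataFrame:
    """Bulk spore percentage at every snapshot time."""
    rows = [(s.t, bulk_spore_percentage(s)) for s in run.snapshots]
    return pd.DataFrame(rows, columns=["t", "spore_percentage"])


def leading_edge(run: SimulationRun, window: float = 1.0) -> FrontTrajectory:
    """Leading-edge trajectory R(t) with smoothed instantaneous velocities."""
    t, R = run.boundary_trajectory()
    if len(t) < 2:
        raise ValueError("need at least 2 snapshots")
    return FrontTrajectory(
        kind="leading_edge",
        times=t,
        positions=R,
        velocities=instantaneous_velocities(t, R, window),
        smoothing_window=window,
    )


def _front_position(r: np.ndarray, profile: np.ndarray, level: float = FRONT_LEVEL) -> float:
    """Most distal position where ``profile >= level * max(profile)``.

    Sub-grid resolution via linear interpolation on the descending limb.
    """
    fmax = profile.max()
    thr = level * fmax
    above = np.flatnonzero(profile >= thr)
    i = above[-1]
    if i == len(profile) - 1:
        return float(r[i])
    # interpolate the crossing between the last point above and its neighbour
    f0, f1 = profile[i], profile[i + 1]
    frac = (f0 - thr) / (f0 - f1)
    return float(r[i] + frac * (r[i + 1] - r[i]))


def sporulation_flux(state: SimulationState, params: ModelParams) -> np.ndarray:
    """Instantaneous cell-to-spore conversion rate k(n)*rho1 on the grid."""
    return hill_sporulation_rate(state.n, params) * state.rho1


def sporulation_front(
    run: SimulationRun, window: float = 1.0, level: float = FRONT_LEVEL
) -> FrontTrajectory:
    """Trajectory of the sporulation-flux front.

    Per snapshot the flux profile ``f(r) = k(n) * rho1`` is computed inside
    the biofilm and the front is the most distal position with
    ``f >= level * max(f)``.  Snapshots with all-zero flux (e.g. k0 = 0)
    are skipped with a log message.
    """
    times, positions = [], []
    for s in run.snapshots:
        ins = s.inside
        f = sporulation_flux(s, run.params)[ins]
        if not np.any(f > 0):
            logger.info("no sporulation flux at t=%.3g hr; front undefined", s.t)
            continue
        times.append(s.t)
        positions.append(_front_position(s.r[ins], f, level))
    if len(times) < 2:
        raise ValueError("sporulation front undefined for (nearly) all snapshots")
    times = np.array(times)
    positions = np.array(positions)
    return FrontTrajectory(
        kind="sporulation_front",
        times=times,
        positions=positions,
        velocities=instantaneous_velocities(times, positions, window),
        smoothing_window=window,
    )


def cell_region(state: SimulationState, level: float = 0.5) -> Optional[tuple[float, float]]:
    """[min, max] radial extent where the cell fraction is >= ``level``.

    Returns None when no node qualifies (fully sporulated biofilm).
    """
    ins = state.inside
    mask = state.rho1[ins] >= level
    if not np.any(mask):
        return None
    r_in = state.r[ins][mask]
    return float(r_in.min()), float(r_in.max())


def _first_bin_crossings(
    traj: FrontTrajectory, lo: float, width: float, n_bins: int
) -> dict[int, float]:
    """Map bin index -> front velocity at the first sample inside the bin."""
    idx = np.floor((traj.positions - lo) / width).astype(int)
    out: dict[int, float] = {}
    for i, b in enumerate(idx):
        if 0 <= b < n_bins and b not in out:
            out[b] = float(traj.velocities[i])
    return out


def velocity_ratio_curve(
    edge: FrontTrajectory,
    front: FrontTrajectory,
    bin_width: float = 25.0,
) -> VelocityRatioCurve:
    """Pair instantaneous velocities of two fronts by radial position.

    Radial bins of ``bin_width`` um cover the range both trajectories
    visited; in each bin the velocity each front had when it first crossed
    the bin is recorded.  Ratios are reported only where the expansion
    velocity is positive.  When a front recrosses a bin (numerical jitter),
    the first crossing wins.
    """
    lo = max(edge.positions.min(), front.positions.min())
    hi = min(edge.positions.max(), front.positions.max())
    if hi <= lo:
        raise ValueError("trajectories share no radial range")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    e = _first_bin_crossings(edge, lo, bin_width, n_bins)
    f = _first_bin_crossings(front, lo, bin_width, n_bins)
    rows = []
    for b in sorted(set(e) & set(f)):
        ve, vf = e[b], f[b]
        if ve > 0:
            rows.append((lo + (b + 0.5) * bin_width, ve, vf, vf / ve))
    if not rows:
        raise ValueError("no radial bin was crossed by both fronts")
    pos, ve, vf, ratio = map(np.array, zip(*rows))
    return VelocityRatioCurve(
        positions=pos,
        expansion_velocity=ve,
        front_velocity=vf,
        ratio=ratio,
        bin_width=bin_width,
    )


def trajectory_overlay_rms(
    edge: FrontTrajectory, front: FrontTrajectory
) -> tuple[float, float]:
    """Best time shift overlaying the front onto the edge trajectory.

    Only front samples within the position range the edge traversed are
    compared (the wave first ignites in interior biomass the edge never
    occupied; the comparison concerns biomass formed by outward spreading).
    Searches lags on the snapshot grid for the shift minimizing the RMS
    position difference between the (shifted) front and the leading edge.
    Returns ``(lag_hr, rms_um)``.
    """
    dt = float(np.median(np.diff(edge.times)))
    in_range = front.positions >= edge.positions.min()
    f_times = front.times[in_range]
    f_pos = front.positions[in_range]
    lags = np.arange(0.0, edge.times[-1] - edge.times[0], dt)
    best = (0.0, np.inf)
    for lag in lags:
        shifted = f_times - lag
        ok = (shifted >= edge.times[0]) & (shifted <= edge.times[-1])
        if ok.sum() < max(3, len(f_times) // 4):
            continue
        ref = np.interp(shifted[ok], edge.times, edge.positions)
        rms = float(np.sqrt(np.mean((f_pos[ok] - ref) ** 2)))
        if rms < best[1]:
            best = (float(lag), rms)
    return best
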