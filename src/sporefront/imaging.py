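"""Synthetic two-channel confocal-like stacks with known ground truth.

Renders simulation runs into 4D (T, Z, Y, X) voxel stacks mimicking
timelapse confocal imaging of a biofilm with a constitutive reporter
(intensity tracking the cell fraction, with a residual contribution from
sporulated biomass) and a sporulation-initiation reporter (intensity
tracking the normalized sporulation flux ``k(n) rho1``, suppressed in a
thin biomass layer adjacent to the substrate).  A bright substrate-air
interface plane beyond the leading edge plus Poisson-like and Gaussian
read noise complete the phantom.

This is a rendering model for validating the quantification pipeline, not
an optics simulation: there is no point-spread function, depth attenuation,
photobleaching, or cell-scale texture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .model import ModelParams, hill_sporulation_rate
from .observables import _front_position, sporulation_flux
from .simulate import SimulationRun

__all__ = [
    "RenderParams",
    "BackgroundParams",
    "ImageStack",
    "GroundTruth",
    "render_stack",
    "add_background_and_noise",
    "write_stack",
    "read_stack",
]

CHANNELS = ("constitutive", "sporulation")


@dataclass(frozen=True)
class RenderParams:
    """Geometry and intensity constants of the rendering model.

    Defaults follow the 25x acquisition geometry (1.43 um pixels, 1.34 um
    z-interval, 90-minute frames); ``pixel_size=3.58`` reproduces the 10x
    class.  The image is a strip oriented along the biofilm radius with the
    biofilm center at pixel ``(ny/2, 0)``.
    """

    pixel_size: float = 1.43  # um per pixel
    z_interval: float = 1.34  # um between z planes
    frame_interval: float = 1.5  # hr between frames
    t_start: float = 0.0
    t_stop: Optional[float] = None  # default: end of run
    height: float = 40.0  # biofilm height, um
    ny: int = 48  # strip width, pixels
    nx: Optional[int] = None  # auto: final radius + margin
    margin: float = 150.0  # um of substrate beyond the final edge
    const_amplitude: float = 3000.0  # counts at rho1 = 1
    spor_amplitude: float = 3000.0  # counts at the run's peak flux
    residual_fraction: float = 0.15  # constitutive signal left in spores
    bottom_layer: float = 4.0  # substrate-adjacent suppressed layer, um
    bottom_factor: float = 0.1  # sporulation intensity factor in that layer


@dataclass(frozen=True)
class BackgroundParams:
    """Substrate background and noise model."""

    median_constitutive: float = 800.0  # counts
    median_sporulation: float = 300.0
    spread: float = 30.0  # Gaussian spread of the substrate plane
    read_noise: float = 5.0  # additive Gaussian noise everywhere
    poisson: bool = True  # signal-dependent shot noise

    def median(self, channel: str) -> float:
        return {
            "constitutive": self.median_constitutive,
            "sporulation": self.median_sporulation,
        }[channel]


@dataclass
class ImageStack:
    """Two-channel 4D voxel data with physical calibration."""

    channels: Dict[str, np.ndarray]  # each (T, Z, Y, X) uint16
    pixel_size: float
    z_interval: float
    frame_interval: float
    origin: tuple[float, float]  # biofilm center (y, x) in pixel coords
    times: np.ndarray  # hr, per frame

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if min(self.pixel_size, self.z_interval, self.frame_interval) <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return next(iter(self.channels.values())).shape

    def radius_map(self) -> np.ndarray:
        """Per-pixel distance from the biofilm center, in um."""
        _, _, ny, nx = self.shape
        oy, ox = self.origin
        yy, xx = np.mgrid[0:ny, 0:nx]
        return np.hypot(yy - oy, xx - ox) * self.pixel_size


@dataclass
class GroundTruth:
    """Per-frame truth for parameter-recovery tests (synthetic data only)."""

    frames: pd.DataFrame  # frame, t, edge_radius_um, spor_front_um
    background: Dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_csv(self, path: Union[str, Path]) -> None:
        df = self.frames.copy()
        for ch, (med, mad) in self.background.items():
            df[f"bg_median_{ch}"] = med
            df[f"bg_mad_{ch}"] = mad
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GroundTruth":
        df = pd.read_csv(path)
        bg = {}
        for ch in CHANNELS:
            col = f"bg_median_{ch}"
            if col in df:
                bg[ch] = (float(df[col].iloc[0]), float(df[f"bg_mad_{ch}"].iloc[0]))
        keep = [c for c in df.columns if not c.startswith("bg_")]
        return cls(frames=df[keep], background=bg)


def _frame_times(run: SimulationRun, rp: RenderParams) -> np.ndarray:
    t_stop = rp.t_stop if rp.t_stop is not None else run.times[-1]
    times = np.arange(rp.t_start, t_stop + 1e-9, rp.frame_interval)
    snap_dt = run.params.snapshot_interval
    ratio = rp.frame_interval / snap_dt
    if abs(ratio - round(ratio)) > 1e-6:
        raise ValueError(
            f"frame interval {rp.frame_interval} hr is not a multiple of the "
            f"snapshot interval {snap_dt} hr"
        )
    return times


def render_stack(
    run: SimulationRun, rp: RenderParams = RenderParams()
) -> tuple[ImageStack, GroundTruth]:
    """Render a run into a noiseless two-channel stack plus ground truth.

    Constitutive intensity is ``const_amplitude * (rho1 +
    residual_fraction * rho2)``; sporulation intensity is the flux
    ``k(n) rho1`` normalised by its maximum over the whole run, times
    ``spor_amplitude``, with the bottom ``bottom_layer`` um attenuated by
    ``bottom_factor``.  Biomass fills ``height`` um of z; everything is
    clipped to a hard disc of radius R(t).
    """
    times = _frame_times(run, rp)
    states = [run.state_at(t) for t in times]
    for t, s in zip(times, states):
        if abs(s.t - t) > 0.5 * run.params.snapshot_interval + 1e-9:
            raise ValueError(f"no snapshot near requested frame time {t} hr")

    flux_profiles = [sporulation_flux(s, run.params) for s in states]
    flux_max = max(fp.max() for fp in flux_profiles)
    flux_scale = rp.spor_amplitude / flux_max if flux_max > 0 else 0.0

    nz = int(np.ceil(rp.height / rp.z_interval))
    z_pos = (np.arange(nz) + 0.5) * rp.z_interval
    z_mask = np.where(z_pos < rp.bottom_layer, rp.bottom_factor, 1.0)

    max_R = max(s.R for s in states)
    nx = rp.nx or int(np.ceil((max_R + rp.margin) / rp.pixel_size))
    oy, ox = (rp.ny - 1) / 2.0, 0.0

    stack = ImageStack(
        channels={
            c: np.zeros((len(times), nz, rp.ny, nx), dtype=np.uint16) for c in CHANNELS
        },
        pixel_size=rp.pixel_size,
        z_interval=rp.z_interval,
        frame_interval=rp.frame_interval,
        origin=(oy, ox),
        times=times,
    )
    rad = stack.radius_map()

    rows = []
    for i, (t, s, fp) in enumerate(zip(times, states, flux_profiles)):
        disc = rad <= s.R
        rho1_im = np.where(disc, np.interp(rad, s.r, s.rho1, right=0.0), 0.0)
        rho2_im = np.where(disc, np.interp(rad, s.r, s.rho2, right=0.0), 0.0)
        flux_im = np.where(disc, np.interp(rad, s.r, fp, right=0.0), 0.0)
        const2d = rp.const_amplitude * (rho1_im + rp.residual_fraction * rho2_im)
        spor2d = flux_scale * flux_im
        stack.channels["constitutive"][i] = np.clip(
            const2d[None, :, :] * np.ones(nz)[:, None, None], 0, 65535
        ).astype(np.uint16)
        stack.channels["sporulation"][i] = np.clip(
            spor2d[None, :, :] * z_mask[:, None, None], 0, 65535
        ).astype(np.uint16)
        ins = s.inside
        front = (
            _front_position(s.r[ins], fp[ins]) if np.any(fp[ins] > 0) else np.nan
        )
        rows.append((i, t, s.R, front))

    truth = GroundTruth(
        frames=pd.DataFrame(
            rows, columns=["frame", "t", "edge_radius_um", "spor_front_um"]
        )
    )
    return stack, truth


def add_background_and_noise(
    stack: ImageStack,
    seed: int,
    bg: BackgroundParams = BackgroundParams(),
    ground_truth: Optional[GroundTruth] = None,
) -> tuple[ImageStack, Optional[GroundTruth]]:
    """Add the substrate-air background plane and acquisition noise.

    The substrate plane (bottom z) beyond the biomass edge receives a
    bright background of median ``bg.median(channel)`` and Gaussian spread
    ``bg.spread``; all voxels get Poisson shot noise (if enabled) and
    additive Gaussian read noise.  Deterministic for a fixed ``seed``.  If
    a :class:`GroundTruth` is given, it is returned updated with the
    realized background median/MAD per channel.
    """
    rng = np.random.default_rng(seed)
    rad = stack.radius_map()
    T = stack.shape[0]
    # biomass extent per frame from the noiseless constitutive channel
    const = stack.channels["constitutive"]
    edges = []
    for i in range(T):
        sig = const[i].max(axis=0) > 0
        edges.append(rad[sig].max() if np.any(sig) else 0.0)

    out: Dict[str, np.ndarray] = {}
    realized: Dict[str, tuple[float, float]] = {}
    for ch, voxels in stack.channels.items():
        data = voxels.astype(np.float64)
        bg_samples = []
        for i in range(T):
            beyond = rad > edges[i]
            plane = bg.median(ch) + bg.spread * rng.standard_normal(
                int(beyond.sum())
            )
            data[i, 0][beyond] += plane
            bg_samples.append(plane)
        if bg.poisson:
            data = rng.poisson(np.clip(data, 0, None)).astype(np.float64)
        if bg.read_noise > 0:
            data += bg.read_noise * rng.standard_normal(data.shape)
        out[ch] = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
        allbg = np.concatenate(bg_samples)
        med = float(np.median(allbg))
        mad = float(np.median(np.abs(allbg - med)))
        realized[ch] = (med, mad)

    noisy = ImageStack(
        channels=out,
        pixel_size=stack.pixel_size,
        z_interval=stack.z_interval,
        frame_interval=stack.frame_interval,
        origin=stack.origin,
        times=stack.times,
    )
    if ground_truth is not None:
        ground_truth = GroundTruth(
            frames=ground_truth.frames.copy(), background=realized
        )
    return noisy, ground_truth


# ---------------------------------------------------------------------------
# persistence: one multi-page TIFF per channel + JSON sidecar (+ truth CSV)
# ---------------------------------------------------------------------------

def write_stack(
    stack: ImageStack,
    out_dir: Union[str, Path],
    ground_truth: Optional[GroundTruth] = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ch, voxels in stack.channels.items():
        tifffile.imwrite(out / f"{ch}.tif", voxels, metadata={"axes": "TZYX"})
    sidecar = {
        "pixel_size_um": stack.pixel_size,
        "z_interval_um": stack.z_interval,
        "frame_interval_hr": stack.frame_interval,
        "origin_px": list(stack.origin),
        "times_hr": [float(t) for t in stack.times],
        "shape": list(stack.shape),
        "channels": sorted(stack.channels),
    }
    (out / "stack.json").write_text(json.dumps(sidecar, indent=2))
    if ground_truth is not None:
        ground_truth.to_csv(out / "ground_truth.csv")
    return out


def read_stack(in_dir: Union[str, Path]) -> tuple[ImageStack, Optional[GroundTruth]]:
    d = Path(in_dir)
    sidecar_path = d / "stack.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing stack sidecar: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    channels = {}
    for ch in meta["channels"]:
        voxels = tifffile.imread(d / f"{ch}.tif")
        if list(voxels.shape) != meta["shape"]:
            raise ValueError(
                f"channel {ch} shape {voxels.shape} does not match sidecar "
                f"{meta['shape']}"
            )
        channels[ch] = voxels
    stack = ImageStack(
        channels=channels,
        pixel_size=meta["pixel_size_um"],
        z_interval=meta["z_interval_um"],
        frame_interval=meta["frame_interval_hr"],
        origin=tuple(meta["origin_px"]),
        times=np.array(meta["times_hr"]),
    )
    truth_path = d / "ground_truth.csv"
    truth = GroundTruth.from_csv(truth_path) if truth_path.exists() else None
    return stack, truth
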