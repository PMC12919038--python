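"""Core model types and nutrient-response kinetics.

The biofilm is described as an expanding disc of fixed height with radial
symmetry.  At each radius the biomass is partitioned into a cell fraction
``rho1`` and a spore fraction ``rho2 = 1 - rho1``; a dimensionless nutrient
field ``n`` (initially 1 everywhere) diffuses freely across the biofilm
boundary.  Cells grow at a Monod rate ``g*n/(n + ng)`` and convert to spores
at a repressive-Hill rate ``k0*nk**h/(nk**h + n**h)``, so growth and
sporulation are mutually exclusive nutrient regimes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "SimulationState",
    "monod_growth_rate",
    "hill_sporulation_rate",
]

#: seconds per hour, for converting the diffusivity from um^2/s to um^2/hr
_S_PER_HR = 3600.0

# Parameter fields serialized to/from flat JSON/YAML mappings.
_PARAM_FIELDS = (
    "g", "ng", "k0", "nk", "h", "gamma", "phi", "D",
    "R0", "L", "dr", "dt", "t_end", "snapshot_interval",
)


@dataclass(frozen=True)
class ModelParams:
    """Model parameters and numerical controls.

    Rates are per hour, lengths in micrometres, nutrient dimensionless
    (normalised so the initial uniform concentration is 1).

    Attributes
    ----------
    g : float
        Maximum per-capita growth rate (1/hr).
    ng : float
        Monod half-saturation nutrient level (dimensionless).
    k0 : float
        Maximum per-capita sporulation rate (1/hr).
    nk : float
        Hill half-repression nutrient level (dimensionless).
    h : float
        Hill exponent (steepness of sporulation repression).
    gamma : float
        Nutrient consumed per unit of cell growth activity (1/hr scale).
    phi : float
        Fraction of new cellular biomass converted into radial expansion,
        0 <= phi <= 1.  Proxy for matrix effects (e.g. PGA) on spreading.
    D : float
        Nutrient diffusivity in um^2/s (converted internally to um^2/hr).
    R0 : float
        Initial biofilm radius (um).
    L : float
        Environment (growth chamber) radius (um).
    dr : float
        Radial grid spacing (um); the grid is cell-centered on [0, L].
    dt : float
        Time step (hr).
    t_end : float
        Simulated duration (hr).
    snapshot_interval : float
        Interval between stored state snapshots (hr).
    """

    g: float = 1.0
    ng: float = 1.0
    k0: float = 10.0
    nk: float = 0.03
    h: float = 4.0
    gamma: float = 4.0
    phi: float = 0.3
    D: float = 300.0
    R0: float = 1140.0
    L: float = 7800.0
    dr: float = 5.0
    dt: float = 2.0e-3
    t_end: float = 66.0
    snapshot_interval: float = 0.1

    def __post_init__(self) -> None:
        for name in ("g", "ng", "k0", "nk", "gamma", "D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.h < 1:
            raise ValueError(f"Hill exponent h must be >= 1, got {self.h}")
        if not 0.0 < self.R0 < self.L:
            raise ValueError(f"need 0 < R0 < L, got R0={self.R0}, L={self.L}")
        if self.dr <= 0 or self.dt <= 0:
            raise ValueError("dr and dt must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.snapshot_interval <= 0:
            raise ValueError("snapshot_interval must be positive")

    @property
    def D_um2_hr(self) -> float:
        """Nutrient diffusivity in um^2/hr."""
        return self.D * _S_PER_HR

    @property
    def n_nodes(self) -> int:
        """Number of cell-centered grid nodes on [0, L]."""
        return int(round(self.L / self.dr))

    def grid(self) -> np.ndarray:
        """Cell-centered radial grid: first node at dr/2, last below L."""
        return (np.arange(self.n_nodes) + 0.5) * self.dr

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    # -- flat-mapping serialization ------------------------------------
    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, mapping: dict) -> "ModelParams":
        unknown = set(mapping) - set(_PARAM_FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} does not hold a mapping")
        return cls.from_dict(data)


def monod_growth_rate(n, params: ModelParams):
    """Per-capita growth rate g*n/(n + ng), saturating in nutrient.

    Parameters
    ----------
    n : float or ndarray
        Nutrient level(s); must be non-negative.
    params : ModelParams

    Returns
    -------
    float or ndarray
        Growth rate in 1/hr, monotone nondecreasing in ``n``, bounded by g.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("nutrient level must be non-negative")
    out = params.g * n / (n + params.ng)
    return float(out) if out.ndim == 0 else out


def hill_sporulation_rate(n, params: ModelParams):
    """Per-capita sporulation rate k0*nk**h/(nk**h + n**h).

    Repressive Hill response: maximal (k0) at zero nutrient, half-maximal
    at ``n = nk``, and effectively off at growth-permissive nutrient levels.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("nutrient level must be non-negative")
    nk_h = params.nk ** params.h
    out = params.k0 * nk_h / (nk_h + n ** params.h)
    return float(out) if out.ndim == 0 else out


@dataclass
class SimulationState:
    """Radial fields of the model at one instant.

    ``rho1`` (cells) and ``rho2`` (spores) are fractions of biomass on the
    cell-centered grid ``r``; both are zero beyond the biofilm boundary
    ``R``, and sum to 1 (to solver round-off) inside it.  ``n`` is the
    nutrient field over the whole domain and ``v`` the radial velocity
    field (zero outside the biofilm).
    """

    t: float
    r: np.ndarray
    rho1: np.ndarray
    rho2: np.ndarray
    n: np.ndarray
    v: np.ndarray
    R: float

    @property
    def inside(self) -> np.ndarray:
        """Boolean mask of grid nodes inside the biofilm (r <= R)."""
        return self.r <= self.R

    def validate(self, atol: float = 1e-6) -> None:
        """Raise ValueError if the state violates its invariants."""
        arrays = {"rho1": self.rho1, "rho2": self.rho2, "n": self.n, "v": self.v}
        for name, a in arrays.items():
            if a.shape != self.r.shape:
                raise ValueError(f"{name} shape {a.shape} != grid {self.r.shape}")
            if np.any(~np.isfinite(a)):
                raise ValueError(f"non-finite values in {name} at t={self.t}")
        for name in ("rho1", "rho2"):
            a = arrays[name]
            if np.any(a < -atol) or np.any(a > 1 + atol):
                raise ValueError(f"{name} outside [0, 1] at t={self.t}")
        if np.any(self.n < -atol):
            raise ValueError(f"negative nutrient at t={self.t}")
        outside = ~self.inside
        if np.any(np.abs(self.rho1[outside]) > atol) or np.any(
            np.abs(self.rho2[outside]) > atol
        ):
            raise ValueError(f"biomass beyond the boundary R={self.R} at t={self.t}")

    def copy(self) -> "SimulationState":
        return SimulationState(
            t=self.t,
            r=self.r.copy(),
            rho1=self.rho1.copy(),
            rho2=self.rho2.copy(),
            n=self.n.copy(),
            v=self.v.copy(),
            R=self.R,
        )
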