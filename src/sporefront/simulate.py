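"""Moving-boundary reaction-advection-diffusion solver on a radial grid.

The dynamical system, in cylindrical symmetry on a fixed Eulerian grid
covering the dish ``[0, L]`` with an explicitly tracked biofilm boundary
``R(t)``::

    d(rho1)/dt + (1/r) d(r v rho1)/dr = phi*g(n)*rho1 - k(n)*rho1
    d(rho2)/dt + (1/r) d(r v rho2)/dr = k(n)*rho1
    dn/dt = D (1/r) d(r dn/dr)/dr - gamma*g(n)*rho1
    (1/r) d(r v)/dr = phi*g(n)*rho1,   v(0) = 0

The continuity closure for ``v`` is the unique choice under which the
biomass partition ``rho1 + rho2 = 1`` is preserved inside the biofilm.  To
keep that partition exact at the discrete level the transport step uses the
advective (non-conservative) form

    d(rho)/dt + v d(rho)/dr = source - rho * div(v),

with ``div(v) = phi*g(n)*rho1`` substituted pointwise: a uniform
``rho1 + rho2`` is then an exact fixed point of the update, so the
partition holds to round-off rather than to the splitting error.

Time stepping is operator-split per step: local reactions (sources plus
continuity dilution, explicit Euler) -> upwind advection of both biomass
fractions -> implicit (backward Euler) nutrient diffusion over the full
domain with zero-flux walls -> boundary motion ``R += dt*v(R)``.  Nutrients
diffuse freely across the biofilm boundary; biomass is confined within R.
Nodes newly engulfed by the advancing boundary inherit the composition of
their inward neighbour.  The model is deterministic: repeated runs with the
same parameters are bitwise identical.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import json
import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from .model import (
    ModelParams,
    SimulationState,
    hill_sporulation_rate,
    monod_growth_rate,
)

__all__ = [
    "SimulationRun",
    "SimulationError",
    "initialize",
    "compute_velocity_field",
    "advance_one_step",
    "run_simulation",
    "save_run",
    "load_run",
]


class SimulationError(RuntimeError):
    """Raised when the solver detects an invalid state or configuration."""


@dataclass
class SimulationRun:
    """A completed simulation: parameters plus time-ordered snapshots."""

    params: ModelParams
    snapshots: List[SimulationState]
    metadata: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    def boundary_trajectory(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, R) arrays of the leading-edge radius."""
        return self.times, np.array([s.R for s in self.snapshots])

    def state_at(self, t: float) -> SimulationState:
        """Snapshot nearest to time ``t`` (hr)."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.snapshots[idx]


def _stability_check(params: ModelParams) -> None:
    if params.dt * params.k0 > 0.5:
        raise SimulationError(
            f"dt*k0 = {params.dt * params.k0:.3g} > 0.5: the explicit "
            "sporulation reaction would be unstable; reduce dt"
        )


def initialize(
    params: ModelParams,
    coffee_stain: bool = False,
    seed: int = 0,
    ring_inner_frac: float = 0.9,
    interior_mean: float = 0.45,
) -> SimulationState:
    """Initial condition: a uniform disc of cells in fresh nutrient.

    With ``coffee_stain=True`` the cell fraction instead mimics a dried
    inoculum droplet: a continuous ring of dense cells at the perimeter
    (``r`` in ``[ring_inner_frac*R0, R0]`` at rho1=1) over a patchy interior
    whose smooth random profile averages ``interior_mean``.  The patchy
    profile is deterministic for a given ``seed``.  In that case
    ``rho1 + rho2 < 1`` in the interior (unoccupied volume); growth and its
    continuity dilution relax the sum toward 1 as the biofilm matures.
    """
    if params.R0 >= params.L:
        raise SimulationError("R0 must be smaller than the environment radius L")
    r = params.grid()
    inside = r <= params.R0
    rho1 = np.zeros_like(r)
    if coffee_stain:
        rng = np.random.default_rng(seed)
        n_in = int(inside.sum())
        # smooth patchiness: coarse random field linearly interpolated
        n_knots = max(4, n_in // 12)
        knots = np.linspace(0.0, params.R0, n_knots)
        vals = rng.uniform(0.3, 0.9, size=n_knots)
        patchy = np.interp(r[inside], knots, vals)
        patchy *= interior_mean / patchy.mean()
        rho1[inside] = np.clip(patchy, 0.0, 1.0)
        ring = inside & (r >= ring_inner_frac * params.R0)
        rho1[ring] = 1.0
    else:
        rho1[inside] = 1.0
    rho2 = np.zeros_like(r)
    n = np.ones_like(r)
    v = np.zeros_like(r)
    return SimulationState(t=0.0, r=r, rho1=rho1, rho2=rho2, n=n, v=v, R=params.R0)


def _cumtrapz_from_zero(integrand: np.ndarray, dr: float) -> np.ndarray:
    """Cumulative trapezoid of a cell-centered integrand, anchored at r=0.

    The integrand is assumed to vanish at r=0 (it always carries a factor
    of r here), so the first half-cell contributes a triangle.
    """
    out = np.empty_like(integrand)
    out[0] = 0.25 * integrand[0] * dr  # triangle from 0 to dr/2
    np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * dr, out=out[1:])
    out[1:] += out[0]
    return out


def compute_velocity_field(
    state: SimulationState, params: ModelParams, mask_outside: bool = True
) -> np.ndarray:
    """Radial velocity from the continuity closure.

    Solves ``(1/r) d(r v)/dr = phi * g(n) * rho1`` with ``v(0) = 0``:
    ``v(r) = (1/r) * int_0^r r' phi g(n(r')) rho1(r') dr'`` by cumulative
    trapezoid.  With ``mask_outside`` (the reported convention) the field
    is zeroed beyond the boundary, where no biomass exists to advect.
    """
    div = params.phi * monod_growth_rate(state.n, params) * state.rho1
    v = _cumtrapz_from_zero(state.r * div, params.dr) / state.r
    if mask_outside:
        v = np.where(state.r <= state.R, v, 0.0)
    return v


def _diffusion_matrix(params: ModelParams) -> Optional[np.ndarray]:
    """Banded matrix for backward-Euler cylindrical diffusion on [0, L].

    Finite-volume discretization with zero-flux faces at r=0 and r=L; the
    face at r=0 carries zero area so the axis needs no special casing.
    Returns None when D == 0.
    """
    if params.D_um2_hr == 0.0:
        return None
    N = params.n_nodes
    dr = params.dr
    r = params.grid()
    r_lo = r - 0.5 * dr  # inner faces (first is exactly 0)
    r_hi = r + 0.5 * dr  # outer faces (last is exactly L)
    lam = params.D_um2_hr * params.dt / dr**2
    a_lo = lam * r_lo / r
    a_hi = lam * r_hi / r
    a_hi[-1] = 0.0  # zero flux at r = L
    ab = np.zeros((3, N))
    ab[0, 1:] = -a_hi[:-1]  # superdiagonal
    ab[1, :] = 1.0 + a_lo + a_hi
    ab[2, :-1] = -a_lo[1:]  # subdiagonal
    return ab


def _step(
    rho1: np.ndarray,
    rho2: np.ndarray,
    n: np.ndarray,
    R: float,
    r: np.ndarray,
    params: ModelParams,
    diff_ab: Optional[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Advance the fields in place by one dt; returns (new R, velocity)."""
    dt, dr = params.dt, params.dr
    m = int(np.searchsorted(r, R, side="right"))  # nodes inside the biofilm

    # --- local reactions + continuity dilution (explicit, simultaneous) ---
    n_in = n[:m]
    g = params.g * n_in / (n_in + params.ng)
    nk_h = params.nk ** params.h
    k = params.k0 * nk_h / (nk_h + n_in ** params.h)
    p1 = rho1[:m]
    p2 = rho2[:m]
    div = params.phi * g * p1  # velocity divergence = continuity source
    d1 = dt * (div - k * p1 - p1 * div)
    d2 = dt * (k * p1 - p2 * div)
    n[:m] = np.maximum(n_in - dt * params.gamma * g * p1, 0.0)
    p1 += d1
    p2 += d2

    # --- velocity from the pre-reaction growth field ---
    rv = np.zeros_like(r)
    rv[:m] = r[:m] * div
    v = _cumtrapz_from_zero(rv, dr) / r

    # --- upwind advection of both fractions (advective form, v >= 0) ---
    c = dt / dr * v[1:m]
    if m > 1:
        cmax = c.max(initial=0.0)
        if cmax > 1.0:
            raise SimulationError(
                f"advective CFL violated (v*dt/dr = {cmax:.3g} > 1); reduce dt"
            )
        rho1[1:m] -= c * (rho1[1:m] - rho1[: m - 1])
        rho2[1:m] -= c * (rho2[1:m] - rho2[: m - 1])

    # --- implicit nutrient diffusion over the whole dish ---
    if diff_ab is not None:
        n[:] = solve_banded((1, 1), diff_ab, n, check_finite=False)

    # --- boundary motion; engulfed nodes inherit the edge composition ---
    vR = float(np.interp(R, r, v))
    R_new = R + dt * vR
    m_new = int(np.searchsorted(r, R_new, side="right"))
    if m_new > m:
        rho1[m:m_new] = rho1[m - 1]
        rho2[m:m_new] = rho2[m - 1]
    return R_new, v


def _check_fields(rho1, rho2, n, t: float) -> None:
    for name, a in (("rho1", rho1), ("rho2", rho2), ("n", n)):
        if not np.all(np.isfinite(a)):
            raise SimulationError(f"non-finite {name} at t={t:.4g} hr")
    if rho1.min() < -1e-9 or rho2.min() < -1e-9:
        raise SimulationError(f"negative biomass fraction at t={t:.4g} hr")
    if n.min() < -1e-12:
        raise SimulationError(f"negative nutrient at t={t:.4g} hr")


def advance_one_step(state: SimulationState, params: ModelParams) -> SimulationState:
    """One operator-split step of length ``params.dt`` (pure: returns new state)."""
    _stability_check(params)
    _check_fields(state.rho1, state.rho2, state.n, state.t)
    new = state.copy()
    diff_ab = _diffusion_matrix(params)
    R, v = _step(new.rho1, new.rho2, new.n, new.R, new.r, params, diff_ab)
    new.R = R
    new.v = np.where(new.r <= R, v, 0.0)
    new.t = state.t + params.dt
    _check_fields(new.rho1, new.rho2, new.n, new.t)
    return new


def run_simulation(
    params: ModelParams,
    coffee_stain: bool = False,
    seed: int = 0,
) -> SimulationRun:
    """Integrate from t=0 to ``params.t_end``, collecting snapshots.

    Snapshots (including the initial state) are stored every
    ``params.snapshot_interval`` hours.  The run is deterministic; with
    ``coffee_stain`` the initial patchiness is seeded by ``seed``.
    """
    _stability_check(params)
    t0 = _time.perf_counter()
    state = initialize(params, coffee_stain=coffee_stain, seed=seed)
    r = state.r
    rho1, rho2, n = state.rho1, state.rho2, state.n
    R = state.R
    diff_ab = _diffusion_matrix(params)

    n_steps = int(round(params.t_end / params.dt))
    per_snap = max(1, int(round(params.snapshot_interval / params.dt)))

    def snap(t: float, R: float, v: np.ndarray) -> SimulationState:
        return SimulationState(
            t=t,
            r=r,
            rho1=rho1.copy(),
            rho2=rho2.copy(),
            n=n.copy(),
            v=np.where(r <= R, v, 0.0),
            R=R,
        )

    snapshots = [snap(0.0, R, state.v)]
    try:
        for istep in range(1, n_steps + 1):
            R, v = _step(rho1, rho2, n, R, r, params, diff_ab)
            if istep % per_snap == 0 or istep == n_steps:
                t = istep * params.dt
                _check_fields(rho1, rho2, n, t)
                snapshots.append(snap(t, R, v))
    except SimulationError as err:
        raise SimulationError(f"step {istep} (t={istep * params.dt:.4g} hr): {err}")

    metadata = {
        "scheme": "reaction(explicit)+upwind-advection+implicit-diffusion",
        "n_nodes": params.n_nodes,
        "n_steps": n_steps,
        "coffee_stain": bool(coffee_stain),
        "wall_clock_s": round(_time.perf_counter() - t0, 3),
    }
    return SimulationRun(params=params, snapshots=snapshots, metadata=metadata)


# ---------------------------------------------------------------------------
# columnar-text persistence (CLI round-trip format)
# ---------------------------------------------------------------------------

def save_run(
    run: SimulationRun, out_dir: Union[str, Path], field_interval: Optional[float] = None
) -> Path:
    """Write a run as text: fields.csv, boundary.csv, params.yaml, metadata.json.

    ``field_interval`` thins the per-node field table (boundary trajectory is
    always written at full snapshot resolution).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run.params.to_yaml(out / "params.yaml")
    (out / "metadata.json").write_text(json.dumps(run.metadata, indent=2))
    t, R = run.boundary_trajectory()
    pd.DataFrame({"t": t, "R": R}).to_csv(out / "boundary.csv", index=False)
    keep = run.snapshots
    if field_interval is not None:
        stride = max(1, int(round(field_interval / run.params.snapshot_interval)))
        keep = run.snapshots[::stride]
        if keep[-1] is not run.snapshots[-1]:
            keep = keep + [run.snapshots[-1]]
    frames = []
    for s in keep:
        frames.append(
            pd.DataFrame(
                {"t": s.t, "r": s.r, "rho1": s.rho1, "rho2": s.rho2, "n": s.n, "v": s.v}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        out / "fields.csv", index=False, float_format="%.10g"
    )
    return out


def load_run(run_dir: Union[str, Path]) -> SimulationRun:
    """Load a run previously written by :func:`save_run`."""
    d = Path(run_dir)
    params = ModelParams.from_yaml(d / "params.yaml")
    meta_path = d / "metadata.json"
    metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    fields = pd.read_csv(d / "fields.csv")
    boundary = pd.read_csv(d / "boundary.csv")
    R_of_t = dict(zip(boundary["t"].round(9), boundary["R"]))
    snapshots = []
    for t, grp in fields.groupby("t", sort=True):
        key = round(float(t), 9)
        R = float(R_of_t.get(key, grp["r"][grp["rho1"] > 0].max()))
        snapshots.append(
            SimulationState(
                t=float(t),
                r=grp["r"].to_numpy(),
                rho1=grp["rho1"].to_numpy(),
                rho2=grp["rho2"].to_numpy(),
                n=grp["n"].to_numpy(),
                v=grp["v"].to_numpy(),
                R=R,
            )
        )
    return SimulationRun(params=params, snapshots=snapshots, metadata=metadata)
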