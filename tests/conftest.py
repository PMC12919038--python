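"""Shared fixtures: simulation runs and synthetic stacks reused across tests.

The expensive artifacts (full-length default run, seven-value phi sweep,
rendered noisy stack with its quantification) are session-scoped so each is
computed once per test session.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from sporefront import observables as obs
from sporefront import quantify as q
from sporefront.imaging import RenderParams, add_background_and_noise, render_stack
from sporefront.model import ModelParams
from sporefront.pipeline import SWEEP_PHI_VALUES
from sporefront.simulate import run_simulation


@pytest.fixture(scope="session")
def default_run():
    """The high-sporulation calibration: k0=10/hr, phi=0.3, 66 hr."""
    return run_simulation(ModelParams())


@pytest.fixture(scope="session")
def short_run():
    """A cheap 10 hr run with the default parameters."""
    return run_simulation(ModelParams(t_end=10.0))


@pytest.fixture(scope="session")
def sweep_results(default_run):
    """Front trajectories and ratio curves for the seven-phi sweep."""
    out = {}
    for phi in SWEEP_PHI_VALUES:
        run = (
            default_run
            if phi == default_run.params.phi
            else run_simulation(ModelParams(phi=phi))
        )
        edge = obs.leading_edge(run)
        front = obs.sporulation_front(run)
        out[phi] = SimpleNamespace(
            run=run,
            edge=edge,
            front=front,
            curve=obs.velocity_ratio_curve(edge, front),
        )
    return out


@pytest.fixture(scope="session")
def imaging_bundle():
    """Noisy synthetic stack from a default run, quantified end to end.

    Carries the clean (pre-noise) stack, the realized ground truth, the
    pipeline output on the noisy stack, and the ideal measurement (same
    pipeline and thresholds applied to the clean stack).
    """
    run = run_simulation(ModelParams(t_end=40.0))
    clean, truth = render_stack(run, RenderParams(t_start=3.0))
    noisy, truth = add_background_and_noise(clean, seed=7, ground_truth=truth)
    config = q.QuantConfig(inoculum_radius=float(truth.frames["edge_radius_um"][0]))
    result = q.quantify_stack(noisy, config)
    thr = result.thresholds.pivot(index="frame", columns="channel", values="threshold")
    ideal_edge, ideal_front = [], []
    for i in range(len(noisy.times)):
        t = {ch: float(thr.loc[i, ch]) for ch in ("constitutive", "sporulation")}
        proj = q.z_project(clean, i, "constitutive", "mean", t["constitutive"])
        e = q.leading_edge_from_image(
            proj, t["constitutive"], clean.origin, clean.pixel_size
        )
        ideal_edge.append(e)
        prof = q.ratio_profile(clean, i, t, max_radius=e)
        ideal_front.append(q.sporulation_front_from_profile(prof))
    return SimpleNamespace(
        run=run,
        clean=clean,
        noisy=noisy,
        truth=truth,
        config=config,
        result=result,
        ideal_edge=np.array(ideal_edge),
        ideal_front=np.array(ideal_front),
    )
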