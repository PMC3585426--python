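"""Shared fixtures: the reference synthetic bundle and a set of
well-tempered metadynamics runs on the analytic double well (expensive, so
session-scoped and reused by the convergence, reweighting and replay
tests)."""

from __future__ import annotations

import numpy as np
import pytest

from bundlecv.metad import (DoubleWell, WTMetadParams, WallSpec,
                            free_energy_from_bias, langevin_propagate,
                            run_well_tempered_metadynamics)
from bundlecv.synthetic import BundleLayout, build_bundle

DW = DoubleWell(5.0)
DW_PARAMS = dict(temperature=298.0, bias_factor=10.0, pace=2.0,
                 initial_height=0.25, widths=(0.2,))
# soft walls: stiff springs (e.g. kappa=500, rescale=0.1) give thermal
# wall hits velocity kicks beyond what dt=0.01 ps integrates stably
DW_WALLS = [WallSpec(0, 1.8, "upper", kappa=20.0, rescale=0.3),
            WallSpec(0, -1.8, "lower", kappa=20.0, rescale=0.3)]
DW_EDGES = [np.linspace(-2.6, 2.6, 261)]
DW_STEPS = 400_000
DW_DT = 0.01
DW_FRICTION = 5.0


def run_doublewell(n_steps: int, seed: int):
    return run_well_tempered_metadynamics(
        DW, WTMetadParams(**DW_PARAMS), DW_WALLS, x0=[-1.0],
        n_steps=n_steps, dt=DW_DT, friction=DW_FRICTION, seed=seed,
        grid_edges=DW_EDGES, colvar_stride=20)


def barrier_from_run(run) -> float:
    """Barrier height (kJ/mol) of the recovered double-well profile."""
    surf = free_energy_from_bias(run.state)
    c = surf.centers[0]
    f = surf.values
    well = f[np.abs(np.abs(c) - 1.0) < 0.1].min()
    return float(f[np.abs(c) < 0.05].min() - well)


@pytest.fixture(scope="session")
def bundle_ref():
    """Default synthetic bundle: (frame, bundle definition, reference)."""
    return build_bundle(BundleLayout())


@pytest.fixture(scope="session")
def doublewell_runs():
    """Five 400k-step well-tempered runs on the 5 kJ/mol double well."""
    return [run_doublewell(DW_STEPS, seed) for seed in range(5)]


@pytest.fixture(scope="session")
def unbiased_doublewell():
    """A 1e6-step unbiased Langevin reference on the same double well."""
    times, xs, _ = langevin_propagate(
        DW, None, [-1.0], DW_DT, DW_FRICTION, 298.0, 1_000_000,
        seed=123, record_stride=10)
    return xs[:, 0]
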