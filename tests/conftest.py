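"""Shared fixtures: small synthetic datasets and session-scoped phantoms.

Expensive full-geometry phantoms are generated once per session and
shared; unit tests use small grids.
"""

from __future__ import annotations

import numpy as np
import pytest

import valveflow as vf


def make_dataset(
    velocities: np.ndarray,
    spacing=(2.0, 2.0, 2.0),
    venc: float = 150.0,
    rr: float = 400.0,
    origin_centered: bool = True,
) -> vf.FlowDataset:
    """Wrap a (X, Y, Z, 3, P) array into a FlowDataset with a diagonal affine."""
    velocities = np.asarray(velocities, dtype=np.float64)
    n_phases = velocities.shape[4]
    aff = np.eye(4)
    for i, s in enumerate(spacing):
        aff[i, i] = s
        if origin_centered:
            aff[i, 3] = -s * (velocities.shape[i] - 1) / 2.0
    times = (np.arange(n_phases) + 0.5) * rr / (n_phases + 1)
    return vf.FlowDataset(
        velocities=velocities,
        spacing=spacing,
        phase_times=times,
        rr_interval=rr,
        venc=venc,
        grid_to_world=aff,
    )


def make_uniform_dataset(
    velocity=(10.0, 0.0, 0.0),
    shape=(12, 12, 10),
    spacing=(2.0, 2.0, 2.0),
    n_phases: int = 3,
) -> vf.FlowDataset:
    vel = np.zeros(shape + (3, n_phases))
    vel[:] = np.asarray(velocity)[None, None, None, :, None]
    return make_dataset(vel, spacing=spacing)


@pytest.fixture
def uniform_dataset() -> vf.FlowDataset:
    return make_uniform_dataset()


@pytest.fixture(scope="session")
def default_phantom():
    """Default single-jet phantom: (spec, dataset, ground truth)."""
    spec = vf.default_phantom_spec(seed=11)
    dataset, truth = vf.generate_phantom(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def default_report(default_phantom):
    """Full pipeline report for the default phantom."""
    spec, _, truth = default_phantom
    report = vf.run_pipeline(vf.PipelineConfig(seed=11, phantom=spec.to_dict()))
    return report, truth, spec


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = vf.default_phantom_spec(seed=12, noise_sd=0.0)
    dataset, truth = vf.generate_phantom(spec)
    return spec, dataset, truth
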