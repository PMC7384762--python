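"""Shared fixtures: small simulated acquisitions reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from qusradiomics.config import PipelineConfig
from qusradiomics.datamodel import ROIMask
from qusradiomics.simulate import (
    SimulationTruth,
    simulate_phantom,
    simulate_rf,
    simulate_scatterer_field,
)

DEPTH_M = 0.025
WIDTH_M = 0.008


@pytest.fixture(scope="session")
def phantom():
    """Reference phantom: 2.5 cm deep, alpha 0.5 dB/cm/MHz, 3 frames."""
    ph, truth = simulate_phantom(
        depth_m=DEPTH_M, width_m=WIDTH_M, alpha_ref=0.5, seed=11, n_frames=3
    )
    return ph


@pytest.fixture(scope="session")
def phantom_truth():
    ph, truth = simulate_phantom(
        depth_m=DEPTH_M, width_m=WIDTH_M, alpha_ref=0.5, seed=11, n_frames=3
    )
    return truth


def make_tumour_frame(
    seed: int,
    alpha: float = 0.7,
    a_eff: float = 25.0,
    density: float = 24.0,
    depth_m: float = DEPTH_M,
    width_m: float = WIDTH_M,
):
    rng = np.random.default_rng(seed)
    truth = SimulationTruth(alpha_true=alpha, a_eff_true=a_eff, density_true=density)
    field = simulate_scatterer_field(truth, depth_m, width_m, rng)
    return simulate_rf(field, truth, rng=rng), truth


def rect_roi(frame, z0_m=0.004, z1_m=0.021, lat_margin=2) -> ROIMask:
    mask = np.zeros(frame.samples.shape, dtype=bool)
    a0 = int(z0_m / frame.axial_pitch)
    a1 = int(z1_m / frame.axial_pitch)
    mask[a0:a1, lat_margin : frame.n_lines - lat_margin] = True
    return ROIMask(mask)


@pytest.fixture(scope="session")
def tumour_frame():
    return make_tumour_frame(seed=21)


@pytest.fixture()
def fast_cfg():
    """Coarser window grid than the clinical default, for unit-test speed."""
    return PipelineConfig(overlap=0.75)
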