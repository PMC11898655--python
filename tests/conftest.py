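"""Shared fixtures: small seeded synthetic populations and helper builders."""

import numpy as np
import pytest

from poleprof import landmarks as lmk
from poleprof import profiles as prf
from poleprof import synthgen, workflow


def make_profile(values, cell_id=1, channel="hada", length_um=7.0):
    values = np.asarray(values, dtype=float)
    return prf.IntensityProfile(
        cell_id=cell_id, channel=channel,
        positions=np.linspace(0.0, 1.0, len(values)),
        values=values, length_um=length_um, native_step_um=0.105,
    )


def gaussian_bump(center, amplitude, sigma=0.03, n=101, baseline=0.0):
    x = np.linspace(0, 1, n)
    return baseline + amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def capsule_mask(shape, p0, p1, width):
    """Binary capsule between endpoints p0, p1 (row, col) of given width."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    L = np.hypot(*d)
    u = d / L
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1) - p0
    t = np.clip(pts @ u, width / 2, L - width / 2)
    closest = np.outer(t, u)
    dist = np.linalg.norm(pts - closest, axis=1)
    return (dist <= width / 2).reshape(shape)


@pytest.fixture(scope="session")
def control_noiseless():
    """40 noiseless control cells with profiles (shared across tests)."""
    scenes, gt = synthgen.generate_population(
        "control", 40, seed=101, overrides={"noise": False})
    pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
    return scenes, gt, pop


@pytest.fixture(scope="session")
def control_snr10():
    """40 control cells at the default noise level, with calibrated prominence."""
    scenes, gt = synthgen.generate_population("control", 40, seed=202)
    pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
    flags = [gt[c].septate for c in pop.profiles]
    prom, diag = lmk.calibrate_prominence(list(pop.profiles.values()), flags)
    return scenes, gt, pop, prom


@pytest.fixture(scope="session")
def spectral_pair():
    control, _ = synthgen.generate_spectral_population("control_like", 3, seed=31)
    shifted, _ = synthgen.generate_spectral_population("shifted", 3, seed=32)
    return control, shifted
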