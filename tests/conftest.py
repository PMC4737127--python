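import numpy as np
import pytest

import midecode as md
from midecode import glm


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete study: 6 runs keep leave-one-run-out meaningful."""
    return md.StudyConfig(n_subjects=2, n_runs=6, grid_shape=(10, 10, 10),
                          searchlight_radius=2, n_permutations=200, seed=7)


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    atlas, gray = md.make_atlas(tiny_config.grid_shape,
                                voxel_size_mm=tiny_config.voxel_size_mm)
    return atlas, gray


@pytest.fixture(scope="session")
def subject_maps(tiny_config, tiny_atlas):
    """Contrast maps of one simulated subject (signal in ROIs 1 and 3)."""
    atlas, _ = tiny_atlas
    return md.subject_contrast_maps_in_memory(tiny_config, 0, atlas)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def direct_convolution(onsets, durations, n_volumes, tr, oversample=16):
    """Independent discrete-convolution oracle: explicit Riemann sum of
    boxcar(u) * hrf(t - u) du on the same fine grid, no np.convolve."""
    spec = glm.HrfSpec()
    dt = tr / oversample
    n_fine = int(np.ceil((n_volumes * tr + spec.duration_seconds) / dt)) + 1
    u = np.arange(n_fine) * dt
    box = np.zeros(n_fine)
    for onset, duration in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + duration) / dt))
        box[i0:i1] += 1.0
    h = glm.canonical_hrf(spec, np.arange(0.0, spec.duration_seconds, dt))
    out = np.zeros(n_volumes)
    for i in range(n_volumes):
        j = int(np.round((i + 0.5) * tr / dt))
        k = min(len(h), j + 1)
        out[i] = np.sum(box[j - np.arange(k)] * h[:k]) * dt
    return out
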