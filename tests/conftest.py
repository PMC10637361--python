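"""Shared fixtures: phantoms and fitted tensor fields are expensive, so the
noise-free straight/arc phantoms are built once per session."""

import numpy as np
import pytest

from tfusplan.dti import fit_tensors
from tfusplan.phantom import PhantomSpec, make_phantom, make_scheme
from tfusplan.volumes import Volume


@pytest.fixture(scope="session")
def scheme():
    return make_scheme()


@pytest.fixture(scope="session")
def straight_phantom(scheme):
    return make_phantom(PhantomSpec(noise="none"), scheme)


@pytest.fixture(scope="session")
def straight_tensors(straight_phantom, scheme):
    return fit_tensors(straight_phantom.dwi, scheme)


@pytest.fixture(scope="session")
def arc_phantom(scheme):
    return make_phantom(PhantomSpec(geometry="arc", noise="none"), scheme)


@pytest.fixture(scope="session")
def arc_tensors(arc_phantom, scheme):
    return fit_tensors(arc_phantom.dwi, scheme)


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """A full on-disk phantom dataset (default noisy study conditions)."""
    from tfusplan.phantom import write_phantom_dataset

    out = tmp_path_factory.mktemp("dataset")
    manifest = write_phantom_dataset(out)
    return out, manifest


def dense_blob_volume(shape=(40, 40, 40), seed=0, n_blobs=30, sigma=6.0,
                      transform=None):
    """Aperiodic band-limited phantom whose blob centers can be mapped
    through a rigid transform analytically (isotropic Gaussians commute
    with rotations), giving an exact moving image without resampling."""
    rng = np.random.default_rng(seed)
    extent = np.array(shape, float)
    centers = rng.uniform(0.0, 1.0, size=(n_blobs, 3)) * extent
    amps = rng.uniform(0.5, 1.5, n_blobs) * rng.choice([-1, 1], n_blobs)
    if transform is not None:
        centers = transform.apply(centers)
    idx = np.indices(shape, dtype=float)
    world = np.moveaxis(idx, 0, -1).reshape(-1, 3)
    d2 = ((world[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    data = (np.exp(-d2 / (2 * sigma**2)) @ amps).reshape(shape)
    return Volume(data, np.eye(4))
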