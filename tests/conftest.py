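import numpy as np
import pytest
from hypothesis import settings

from chromoscape.traces import DistanceEnsemble, TraceEnsemble

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_trace_ensemble(rng, n=8, m=12, resolution=30_000, scale=200.0):
    coords = rng.normal(0.0, scale, size=(n, m, 3))
    return TraceEnsemble(
        coords=coords,
        mask=np.ones((n, m), dtype=bool),
        bin_starts=np.arange(m, dtype=np.int64) * resolution,
        resolution=resolution,
    )


def random_distance_ensemble(rng, n=8, m=12, resolution=30_000, scale=200.0):
    coords = rng.normal(0.0, scale, size=(n, m, 3))
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    mats = np.sqrt((diff ** 2).sum(axis=-1))
    return DistanceEnsemble(
        matrices=mats,
        bin_starts=np.arange(m, dtype=np.int64) * resolution,
        resolution=resolution,
    )


@pytest.fixture
def trace_ensemble(rng):
    return random_trace_ensemble(rng)


@pytest.fixture
def distance_ensemble(rng):
    return random_distance_ensemble(rng)


@pytest.fixture
def toy_trace_csv(tmp_path):
    """2 copies x 3 bins, all measured."""
    path = tmp_path / "traces.csv"
    path.write_text(
        "copy,bin,x,y,z\n"
        "c1,0,0,0,0\n"
        "c1,1,100,0,0\n"
        "c1,2,100,100,0\n"
        "c2,0,10,10,10\n"
        "c2,1,110,10,10\n"
        "c2,2,110,110,10\n"
    )
    return path
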