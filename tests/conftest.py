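import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import msipca

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def make_cube(tmp_path):
    """Factory: write a synthetic cube under the test's tmp dir."""

    counter = {"n": 0}

    def _make(n_spectra=2000, n_peaks=20, rank=4, seed=0, **kw):
        spec = msipca.SyntheticSpec(
            n_spectra=n_spectra, n_peaks=n_peaks, rank=rank, seed=seed, **kw
        )
        counter["n"] += 1
        cube, truth = msipca.generate_datacube(spec, tmp_path / f"cube{counter['n']}")
        return cube, truth

    return _make


@pytest.fixture(scope="session")
def medium_cube(tmp_path_factory):
    """The 50,000 x 100 rank-15 accuracy-study cube (seed 42), built once."""
    d = tmp_path_factory.mktemp("medium")
    spec = msipca.SyntheticSpec(
        n_spectra=50_000, n_peaks=100, rank=15, decay=0.7, seed=42
    )
    cube, truth = msipca.generate_datacube(spec, d / "medium")
    return cube, truth
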