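import logging

import numpy as np
import pytest

from threadarch import (
    FilamentSpec,
    HelicalOperator,
    build_scoring,
    gen_filament,
    thread_target_sequence,
)

#: deposited helical parameters of the thread filament
THREAD_TWIST = -103.234
THREAD_RISE = 31.649


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.getLogger("threadarch").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def scheme():
    """Default uniform-background scoring scheme."""
    return build_scoring()


@pytest.fixture(scope="session")
def target_sequence():
    return thread_target_sequence()


@pytest.fixture(scope="session")
def thread_operator():
    return HelicalOperator(THREAD_TWIST, THREAD_RISE)


def make_filament(seed=0, sigma=0.0, n_subunits=6, **kwargs):
    """Convenience wrapper used across the structural tests."""
    spec = FilamentSpec(n_subunits=n_subunits, sigma=sigma, seed=seed, **kwargs)
    return gen_filament(spec)


@pytest.fixture()
def clean_filament():
    """Noise-free default filament with planted isopeptide and tail contacts."""
    model, manifest = make_filament(seed=0, sigma=0.0)
    return model, manifest


def random_protein(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    return "".join(rng.choice(letters, size=length))
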