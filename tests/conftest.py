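import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from p31vaso.basis import MetaboliteBasis, SpectralLine, default_basis

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def basis() -> MetaboliteBasis:
    return default_basis()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_mini_basis(lines, damping=10.0, window=0.4, amplitudes=None):
    """Small custom basis for oracle tests on 1-2 line signals.

    ``lines`` is a list of (label, group, shift_ppm[, rel_amp, j_hz]).
    """
    spectral = tuple(SpectralLine(*entry) for entry in lines)
    groups = {ln.group for ln in spectral}
    return MetaboliteBasis(
        lines=spectral,
        damping_hz={g: damping for g in groups},
        search_window_ppm={g: window for g in groups},
        group_amplitudes=amplitudes or {g: 1.0 for g in groups},
    )
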