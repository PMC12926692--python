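"""Shared fixtures: small synthetic runs reused across test modules."""

import warnings

import pytest
from hypothesis import settings

from fiberform.mass_model import ProteoformSpec
from fiberform.quantification import AnalysisConfig
from fiberform.synthetic_data import (
    FAMILIES,
    NoiseModel,
    ProteoformSignal,
    SyntheticRunConfig,
    generate_run,
    mock_target_table,
    fiber_fixture,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

warnings.filterwarnings(
    "ignore", message="overlapping m/z windows merged")


def single_proteoform_config(mass=10000.0, seed=0, noise=None, mode="centroid",
                             **signal_kw):
    spec = ProteoformSpec(id="X", protein_name="X", gene="GX",
                          base_neutral_mass=mass)
    return SyntheticRunConfig(
        proteoforms=[ProteoformSignal(spec=spec, abundance=1.0,
                                      rt_center=3.0, **signal_kw)],
        rt_span=(0.0, 6.0),
        seed=seed,
        mode=mode,
        noise=noise or NoiseModel(),
    )


@pytest.fixture(scope="session")
def single_run():
    """Noise-free 10 kDa single-proteoform run plus manifest."""
    return generate_run(single_proteoform_config())


@pytest.fixture(scope="session")
def hybrid_run():
    """Hybrid-fiber fixture at the default noise level, seed 1."""
    return generate_run(fiber_fixture("hybrid_fiber", seed=1))


@pytest.fixture(scope="session")
def hybrid_noise_free_run():
    """Hybrid-fiber fixture with all noise terms off."""
    return generate_run(
        fiber_fixture("hybrid_fiber", seed=1, noise=NoiseModel()))


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig(families={k: list(v) for k, v in FAMILIES.items()},
                          charge_range=(8, 50))


@pytest.fixture(scope="session")
def targets():
    return mock_target_table()
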