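import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isomix import Measurement, ModelSpec, SignatureSet, SourceSpec, load_case

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def point_1d_case():
    """Two point-mode sources (2±2, 20±4) on one signature, sample 11±0.1."""
    return load_case("1d_example1")


@pytest.fixture(scope="session")
def range_1d_case():
    """Same problem with the sources as uniform ranges."""
    return load_case("1d_example2")


@pytest.fixture(scope="session")
def mixing_2d_case():
    """Three range-mode sources on two signatures, equal true fractions."""
    return load_case("2d_mixing")


@pytest.fixture()
def two_source_2d_model():
    """Small ad-hoc model for IO and sampler plumbing tests."""
    return ModelSpec(
        signatures=SignatureSet(("d15N", "d18O")),
        sources=[
            SourceSpec(name="a", mode="point", mean=[0.0, 0.0], sigma=[1.0, 1.0]),
            SourceSpec(name="b", mode="point", mean=[10.0, 5.0], sigma=[1.0, 1.0]),
        ],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
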