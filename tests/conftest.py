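import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pseudoclin import Gazetteer, generate_gazetteer

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# surrogate passthrough warnings are expected noise in degraded-detector tests
logging.getLogger("pseudoclin.surrogate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_gazetteer() -> Gazetteer:
    """Hand-built minimal gazetteer where most rules have forced outcomes."""
    return Gazetteer(
        first_names={"Anna": "F", "Karin": "F", "Erik": "M", "Olof": "M",
                     "Kim": "N", "Alex": "N"},
        surnames=["Lund", "Berg", "Sjöqvist"],
        streets={"Stockholm": ["Storgatan", "Lillgatan"]},
        locations={"Jämtland": ["Åre", "Kluk"], "Skåne": ["Lund", "Ystad"]},
        countries={"Europa": ["Italien", "Spanien"], "Asien": ["Japan", "Indien"]},
        care_units=["Akutmottagningen", "Kirurgkliniken"],
        postal_codes={"111 22": 1.0, "222 33": 0.5},
        phone_area_codes=["08", "070"],
    )


@pytest.fixture(scope="session")
def gen_gazetteer() -> Gazetteer:
    """A seeded synthetic gazetteer of default size."""
    return generate_gazetteer(7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


class ForcedRng:
    """Stub generator: integers() returns queued values, random() fixed.

    random() >= 0.5 makes signed magnitudes negative, < 0.5 positive
    (mirrors the sign convention of the surrogate rules).
    """

    def __init__(self, integer_values, random_value=0.0):
        self._ints = list(integer_values)
        self._rand = random_value

    def integers(self, lo, hi=None, size=None):
        assert size is None
        return self._ints.pop(0) if self._ints else lo

    def random(self, size=None):
        return self._rand


@pytest.fixture()
def forced_rng_factory():
    return ForcedRng
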