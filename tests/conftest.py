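import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from promoterlearn import PromoterRecord, PromoterSet, uniform_scale

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list(BASES), size=length, p=p))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_set():
    """Three short promoters with activities."""
    return PromoterSet(
        [
            PromoterRecord("p1", "ACGT" * 30, activity=1.5),
            PromoterRecord("p2", "GGCC" * 30, activity=0.2),
            PromoterRecord("p3", "ATAT" * 30, activity=0.9),
        ]
    )


@pytest.fixture
def ones_dinuc_scale():
    return uniform_scale("ones2", word_length=2, value=1.0)


@pytest.fixture
def ones_trinuc_scale():
    return uniform_scale("ones3", word_length=3, value=1.0)
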