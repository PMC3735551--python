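import numpy as np
import pytest

from pwmrefine.formats_io import PromoterSet, SiteSet
from pwmrefine.pwm_model import Background
from pwmrefine.synthetic import generate_promoters


@pytest.fixture
def uniform_background() -> Background:
    return Background.uniform()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def small_promoters() -> PromoterSet:
    """20 random 600-nt TSS-aligned promoters."""
    return generate_promoters(20, 600, seed=11)


@pytest.fixture
def consensus_sites() -> SiteSet:
    return SiteSet(["ACGT"] * 5)


def random_sites(rng: np.random.Generator, n: int, L: int) -> SiteSet:
    alphabet = np.array(list("ATGC"))
    return SiteSet(["".join(alphabet[rng.integers(0, 4, L)]) for _ in range(n)])
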