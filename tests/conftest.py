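import pytest

from oat_episodes.core import Dispensation, EpisodeConfig, default_config


@pytest.fixture
def cfg() -> EpisodeConfig:
    return default_config()


@pytest.fixture
def disp():
    """Factory for minimal dispensation records (100 units at strength 1)."""

    def make(
        person="p1",
        drug="methadone",
        day=0,
        ds=7,
        quantity=None,
        strength=1.0,
        din="",
    ) -> Dispensation:
        q = float(ds * 10) if quantity is None else quantity
        return Dispensation(person, drug, day, ds, q, strength, din=din)

    return make
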