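import pytest

from oncosnv.dataset import LabelledDataset
from oncosnv.features import make_track_builder
from oncosnv.synthetic import SyntheticConfig, simulate
from oncosnv.train import TrainerConfig


@pytest.fixture(scope="session")
def world():
    """Small planted-signal fixture shared across tests."""
    return simulate(SyntheticConfig(seed=11, n_drivers=150, n_neutrals=150,
                                    effect_size=1.5))


@pytest.fixture(scope="session")
def labelled_ds(world):
    records = ([m.with_fields(label="driver") for m in world.drivers]
               + [m.with_fields(label="neutral") for m in world.neutrals])
    return LabelledDataset(records)


@pytest.fixture(scope="session")
def track_builders(world):
    return {name: make_track_builder(t) for name, t in world.tracks.items()}


@pytest.fixture(scope="session")
def fast_cfg():
    """Trainer settings scaled to the fixture: single repeat, light
    boosting."""
    return TrainerConfig(n_repeats_model=1, n_repeats_tune=1,
                         n_pos=100, n_neg=100, gb_n_estimators=100, seed=3)


def make_labelled(seed, delta, n=300, **kw):
    cfg = SyntheticConfig(seed=seed, n_drivers=n, n_neutrals=n, effect_size=delta, **kw)
    w = simulate(cfg)
    records = ([m.with_fields(label="driver") for m in w.drivers]
               + [m.with_fields(label="neutral") for m in w.neutrals])
    builders = {name: make_track_builder(t) for name, t in w.tracks.items()}
    return LabelledDataset(records), builders, w
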