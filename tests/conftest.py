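import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fccat.bank import Item, ItemBank, synthesize_bank
from fccat.information import PriorSpec, default_trait_prior

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank2() -> ItemBank:
    """Two-scale toy bank; the first pair reproduces the hand-computed z example."""
    return ItemBank(
        [
            Item("a1", "S1", mu=4.0, loading=0.8, uniqueness=0.5),
            Item("a2", "S1", mu=3.2, loading=-0.5, uniqueness=0.8),
            Item("a3", "S1", mu=2.5, loading=0.6, uniqueness=0.7),
            Item("b1", "S2", mu=3.0, loading=0.6, uniqueness=0.5),
            Item("b2", "S2", mu=3.4, loading=0.7, uniqueness=0.6),
            Item("b3", "S2", mu=4.1, loading=-0.4, uniqueness=0.9),
        ],
        scales=("S1", "S2"),
    )


@pytest.fixture(scope="session")
def prior2() -> PriorSpec:
    return PriorSpec(np.zeros(2), np.array([[1.0, 0.3], [0.3, 1.0]]))


@pytest.fixture(scope="session")
def prior6() -> PriorSpec:
    return default_trait_prior()


@pytest.fixture(scope="session")
def default_bank() -> ItemBank:
    """The default synthetic 279-item HEXACO-style bank."""
    return synthesize_bank(seed=1)


def make_random_bank(rng: np.random.Generator, n_scales: int = 3, per_scale: int = 4) -> ItemBank:
    """Small random but valid bank for property tests."""
    items = []
    for s in range(n_scales):
        for j in range(per_scale):
            lam = rng.uniform(0.3, 0.9) * rng.choice([-1.0, 1.0])
            items.append(
                Item(
                    f"s{s}i{j}",
                    f"sc{s}",
                    mu=float(rng.uniform(1.5, 5.5)),
                    loading=float(lam),
                    uniqueness=float(rng.uniform(0.3, 1.2)),
                )
            )
    return ItemBank(items, scales=tuple(f"sc{s}" for s in range(n_scales)))


@pytest.fixture(scope="session")
def toy_bank12() -> ItemBank:
    """12-item, 3-scale bank used for fast end-to-end and CLI smoke tests."""
    return make_random_bank(np.random.default_rng(42), n_scales=3, per_scale=4)
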