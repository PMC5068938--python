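import numpy as np
import pytest

from minicrkit import Backbone, HandleSpec, NamedSpacer, PasConfig, RunConfig


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


def random_rna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def toy_handle() -> HandleSpec:
    """Toy handle with a hand-enumerable pairing table (-8..-5 = C, -4..-1 = U)."""
    return HandleSpec("CCCCUUUU")


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig.example(seed=7)


@pytest.fixture(scope="session")
def handle(config) -> HandleSpec:
    return config.handle()


@pytest.fixture(scope="session")
def backbone(config) -> Backbone:
    return config.backbone()


@pytest.fixture()
def five_spacers() -> list[NamedSpacer]:
    return [NamedSpacer(f"AA{i+1}", random_dna(37, seed=100 + i)) for i in range(5)]
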