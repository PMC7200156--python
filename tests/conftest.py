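import numpy as np
import pytest

from smexchange.synthetic import AlexSimConfig, SpeciesSpec

# Population centers of the dT70 / SSB-dT70 / RecO-dT70 system used
# throughout the suite as generator ground truth.
E_FREE, E_SSB, E_RECO = 0.09, 0.58, 0.78


@pytest.fixture
def three_species() -> list[SpeciesSpec]:
    return [
        SpeciesSpec("free", E_FREE, 0.07, 0.5, 0.05, 0.2),
        SpeciesSpec("ssb_bound", E_SSB, 0.07, 0.5, 0.05, 0.5),
        SpeciesSpec("reco_bound", E_RECO, 0.07, 0.5, 0.05, 0.3),
    ]


@pytest.fixture
def mixture_config(three_species) -> AlexSimConfig:
    return AlexSimConfig(species=three_species, n_bursts=10_000, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
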