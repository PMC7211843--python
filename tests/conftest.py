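import numpy as np
import pytest

from yieldtail import ExceedanceSet, GPDParams, SyntheticConfig, gpd_sample


def make_exceedances(gamma, sigma, k, seed_or_rng, threshold=10.0, n=None):
    """Simulated exceedance set with excesses drawn from a known GPD."""
    rng = np.random.default_rng(seed_or_rng)
    y = gpd_sample(GPDParams(gamma, sigma), k, rng)
    return ExceedanceSet(
        threshold=threshold,
        excesses=np.sort(y),
        k=k,
        n=n if n is not None else 6 * k,
        t0=threshold + float(y.max()),
    )


@pytest.fixture
def gpd_excesses():
    return make_exceedances


@pytest.fixture
def effects_free_config():
    """Generator configuration with all covariate effects switched off, so
    the true endpoint is the same for every farm."""
    return SyntheticConfig(
        n_farms=400,
        region_effects={"east": 0.0, "north": 0.0, "west": 0.0},
        region_weights=None,
        input_effect=0.0,
        within_farm_sd=0.0,
        seed=20260901,
    )


@pytest.fixture
def small_panel():
    """A small default-condition panel for prep/pipeline tests."""
    from yieldtail import generate_panel

    cfg = SyntheticConfig(n_farms=300, seed=77)
    return generate_panel(cfg)
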