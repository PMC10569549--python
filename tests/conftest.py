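import numpy as np
import pytest

from beemorph import PhantomParams, render_cohort, sample_cohort


@pytest.fixture(scope="session")
def phantoms32():
    """14 honey-bee-like phantoms at 32 cubed: 8 train / 2 val / 4 test."""
    params = PhantomParams(grid_shape=(32, 32, 32), seed=11, p_merge_mb=0.4)
    cohort = sample_cohort(params, 14, {"H1": 7, "H2": 7})
    phantoms, cohort = render_cohort(cohort, params)
    return {"params": params, "cohort": cohort, "phantoms": phantoms}


@pytest.fixture(scope="session")
def phantoms24():
    """13 phantoms at 24 cubed for the learning-curve experiment."""
    params = PhantomParams(grid_shape=(24, 24, 24), seed=11, p_merge_mb=0.4)
    cohort = sample_cohort(params, 13, {"H1": 7, "H2": 6})
    phantoms, cohort = render_cohort(cohort, params)
    return {"params": params, "cohort": cohort, "phantoms": phantoms}


@pytest.fixture(scope="session")
def trained_mini(phantoms32):
    """Mini-profile model trained on 8 phantoms, validated on 2."""
    from beemorph import NetConfig, train_unet

    ph = phantoms32["phantoms"]
    return train_unet(ph[:8], ph[8:10], NetConfig.mini(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
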