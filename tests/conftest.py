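import warnings

import numpy as np
import pytest

from alcmeta.model import Model, ModelConfig
from alcmeta.synth import make_bundle

warnings.filterwarnings("ignore", category=FutureWarning)

#: model basis dimensions for the scaled fixture (5 years, 3 age groups)
SMALL_MODEL_CONFIG = ModelConfig(dc1=3, dc2=2, dp1=3, dp2=2)

#: seeds of the parameter-recovery study
RECOVERY_SEEDS = tuple(range(1, 7))


@pytest.fixture(scope="session")
def small_bundle():
    """Default synthetic study: 5 years x 2 sexes x 3 ages, 3 surveys."""
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def small_model(small_bundle):
    return Model(small_bundle.model_inputs(), SMALL_MODEL_CONFIG)


@pytest.fixture(scope="session")
def recovery_fits():
    """Fitted posteriors on freshly simulated bundles across several seeds.

    Shared by the recovery, APC-consistency and diagnostics tests so the
    expensive sampling runs once per session.
    """
    from alcmeta.inference import SamplerConfig, diagnose, fit

    out = []
    for seed in RECOVERY_SEEDS:
        bundle = make_bundle(seed=seed)
        draws = fit(bundle.model_inputs(),
                    SamplerConfig.preset("test", seed=seed),
                    SMALL_MODEL_CONFIG)
        out.append((bundle, draws, diagnose(draws)))
    return out


@pytest.fixture(scope="session")
def first_fit(recovery_fits):
    """One representative fitted posterior (bundle, draws, diagnostics)."""
    return recovery_fits[0]
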