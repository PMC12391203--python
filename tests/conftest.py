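import numpy as np
import pytest

import fullbody as fb


@pytest.fixture(scope="session")
def geometry():
    return fb.default_geometry()


@pytest.fixture(scope="session")
def augmented(geometry):
    return fb.build_model(fb.ModelVariantSpec.augmented(), geometry)


@pytest.fixture(scope="session")
def baseline(geometry):
    return fb.build_model(fb.ModelVariantSpec.baseline(), geometry)


@pytest.fixture(scope="session")
def all_variants(geometry):
    """Every neck x shoulder x torso combination, built once."""
    return {spec.label(): fb.build_model(spec, geometry)
            for spec in fb.all_variant_specs()}


@pytest.fixture(scope="session")
def vcut_trial(augmented):
    """Short noiseless vcut-like trial generated with the augmented model."""
    cfg = fb.SyntheticTrialConfig(archetype="vcut", duration=1.0, rate=120.0,
                                  marker_noise_sd=0.0, seed=11)
    return fb.make_trial(cfg, augmented)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
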