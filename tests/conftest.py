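import pytest
from hypothesis import settings

from mmpcliff.labeling import EXCLUDED, ThresholdPolicy, compute_class_threshold, label_mmps

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from mmpcliff.mmp import build_mmps
from mmpcliff.synthetic import SyntheticClassConfig, fixture_class, generate_class


@pytest.fixture(scope="session")
def fix():
    """The hand-built noise-free 12-compound class with ground truth."""
    return fixture_class()


@pytest.fixture(scope="session")
def fix_mmps(fix):
    cls, _ = fix
    return build_mmps(cls)


@pytest.fixture(scope="session")
def small_class():
    """A compact noisy class for generic downstream tests."""
    cfg = SyntheticClassConfig(
        n_scaffolds=6, substituents_per_scaffold=10, seed=11, class_id="SMALL"
    )
    return generate_class(cfg)


@pytest.fixture(scope="session")
def small_labeled(small_class):
    cls, _ = small_class
    mmps = build_mmps(cls)
    threshold = compute_class_threshold(cls, mmps, ThresholdPolicy())
    labeled = label_mmps(mmps, threshold)
    kept = [lm for lm in labeled if lm.label != EXCLUDED]
    return cls, mmps, threshold, labeled, kept


@pytest.fixture(scope="session")
def clean_class():
    """Noise-free, fully penetrant class with a strong separable signal."""
    cfg = SyntheticClassConfig(
        n_scaffolds=5,
        substituents_per_scaffold=10,
        noise_sd=0.0,
        cliff_penetrance=1.0,
        cliff_fraction=0.2,
        seed=3,
        class_id="CLEAN",
    )
    return generate_class(cfg)
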