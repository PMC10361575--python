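import pytest

from ecochg.forward_model import (
    ANNParams,
    CMParams,
    CohortSpec,
    simulate_cohort,
    synthesize_average_cycle,
)
from ecochg.signal_core import StimulusSpec


@pytest.fixture
def stim_500() -> StimulusSpec:
    return StimulusSpec(frequency=500, level=70)


@pytest.fixture
def cm_ann_cycle(stim_500):
    """Noiseless CM+ANN cycle with known proportion 0.3."""
    return synthesize_average_cycle(
        CMParams(7.0, 1.0, 0.5, 3.0), ANNParams(3.0, 0.6), stim_500
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small NH cohort for fast classifier tests (not the acceptance cohort)."""
    return simulate_cohort(
        CohortSpec(
            preset="NH",
            n_subjects=6,
            frequencies=(250.0, 500.0, 2000.0, 4000.0),
            levels=(40.0, 60.0, 80.0),
            snr_db=25.0,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """Detector trained briefly on the small cohort; adequate for behavioral
    tests (scale invariance, serialization, gating), not for the performance
    surrogates."""
    from ecochg import classifier as clf

    labeled = clf.build_dataset(small_cohort.records)
    config = clf.TrainConfig(epochs=30, seed=3, batch_size=32)
    model = clf.train(labeled, config)
    return model, labeled
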