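import numpy as np
import pytest

from wescnv.model import ArchitectureSpec
from wescnv.simulate import SimulationConfig, flatten_cohort, simulate_cohort
from wescnv.train import TrainConfig, fit_and_train
from wescnv.windows import SEQ_LEN, ExonWindow

#: the pinned study conditions for the parameter-recovery experiments:
#: default cohort (50 samples x 400 loci, mean depth 80, ratios 0.5/1.5)
STUDY_CONFIG = SimulationConfig(seed=7)
STUDY_TRAIN = TrainConfig(max_epochs=6, split_seed=0)


def make_window(depths=None, start=100, end=250, chrom="chr1", label=None,
                sample_id="S0", fill=50.0):
    if depths is None:
        depths = np.full(SEQ_LEN, fill, dtype=np.float32)
    return ExonWindow(np.asarray(depths, dtype=np.float32), start, end, chrom,
                      label, sample_id)


@pytest.fixture
def toy_windows():
    """Three labeled windows on distinct chromosomes with distinct coordinates."""
    return [
        make_window(fill=10.0, start=100, end=250, chrom="chr1", label=0),
        make_window(fill=50.0, start=5_000, end=6_200, chrom="chr2", label=1),
        make_window(fill=90.0, start=70_000, end=71_500, chrom="chrX", label=2),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small but realistic simulated cohort shared by read-only tests."""
    config = SimulationConfig(n_samples=6, loci_per_sample=40, mean_depth=60.0,
                              seed=11)
    cohort, truth = simulate_cohort(config)
    return config, cohort, truth


@pytest.fixture(scope="session")
def small_cohort_windows(small_cohort):
    _, cohort, _ = small_cohort
    return flatten_cohort(cohort)


@pytest.fixture(scope="session")
def study_cohort_windows():
    cohort, _ = simulate_cohort(STUDY_CONFIG)
    return flatten_cohort(cohort)


@pytest.fixture(scope="session")
def holdout_cohort_windows():
    """Unseen cohort from the same capture grid and generative parameters."""
    cohort, _ = simulate_cohort(STUDY_CONFIG.with_seed(1007))
    return flatten_cohort(cohort)


@pytest.fixture(scope="session")
def trained_study_model(study_cohort_windows):
    """The full training protocol on the default synthetic cohort.

    Trained once per session and shared by the parameter-recovery,
    transfer-learning and robustness tests.
    """
    model, scaler, history = fit_and_train(
        study_cohort_windows, ArchitectureSpec(init_seed=0), STUDY_TRAIN)
    return model, scaler, history
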