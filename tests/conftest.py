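import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirogtt.cohort import group_labels
from mirogtt.qc import filtered_ct_table, run_qc
from mirogtt.simulate import SimulationConfig, simulate_dataset


def zero_noise_config(**overrides) -> SimulationConfig:
    """Config with every stochastic nuisance switched off.

    Plate offsets may still be enabled by the caller: interplate
    calibration removes them exactly when the UniSp3 records are
    noise-free.
    """
    base = dict(
        ct_noise_sd=0.0,
        plate_offsets_sd=0.0,
        haemolysis_fraction=0.0,
        inhibition_fraction=0.0,
        baseline_log2fc={},
        response_log2fc={},
        analyte_coupling={},
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest full dataset: 4/3/3/4 participants, default effects."""
    cfg = SimulationConfig(
        seed=11,
        n_per_group={"NGT": 4, "INDET": 3, "IGT": 3, "CFRD": 4},
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_filtered(small_dataset):
    """(calibrated+filtered Ct table, participant->group) for the small set."""
    report = run_qc(small_dataset.ct_records)
    filt = filtered_ct_table(small_dataset.ct_records, report)
    return filt, group_labels(small_dataset.participants)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
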