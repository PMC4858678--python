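import pandas as pd
import pytest

from tfinduce.synthetic_data import (
    SimConfig,
    simulate_experiment,
    make_transcript_models,
    simulate_atlas,
    simulate_peaks,
)
from tfinduce.induction_profiles import compute_induction_profile


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(n_genes=800, n_tfs=2, n_tissues=3, frac_bound=0.6,
                     promoter_frac=0.4, seed=11)


@pytest.fixture(scope="session")
def experiment(sim_config):
    """(matrix, samples, truth) of a small planted experiment."""
    return simulate_experiment(sim_config)


@pytest.fixture(scope="session")
def profiles(experiment) -> dict[str, pd.DataFrame]:
    matrix, samples, _ = experiment
    return {tf: compute_induction_profile(matrix, samples, tf)
            for tf in sorted(samples["tf"].unique())}


@pytest.fixture(scope="session")
def models(sim_config):
    return make_transcript_models(sim_config.n_genes, seed=sim_config.seed)


@pytest.fixture(scope="session")
def atlas_raw(sim_config, experiment):
    _, _, truth = experiment
    return simulate_atlas(sim_config, truth)


@pytest.fixture(scope="session")
def peak_files(sim_config, experiment, models):
    _, _, truth = experiment
    return simulate_peaks(sim_config, truth, models)


@pytest.fixture(scope="session")
def truth(experiment):
    return experiment[2]
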