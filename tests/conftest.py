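import pytest

from grfest import SessionConfig, TrainConfig, prepare_features, run_single

BENCH_SEED = 1


@pytest.fixture(scope="session")
def pcm_config():
    return SessionConfig(motion_type="pcm", duration_s=120.0, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def sm_config():
    return SessionConfig(motion_type="sm", duration_s=120.0, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def pcm_data(pcm_config):
    """(features, targets, ground-truth bundle) of the seeded PCM session."""
    return prepare_features(pcm_config)


@pytest.fixture(scope="session")
def sm_data(sm_config):
    return prepare_features(sm_config)


@pytest.fixture(scope="session")
def pcm_run(pcm_config, pcm_data):
    """Pattern-6 LSTM trained and evaluated on the seeded PCM session."""
    features, targets, _ = pcm_data
    return run_single(features, targets, pcm_config, pattern_id=6,
                      train_config=TrainConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def sm_run(sm_config, sm_data):
    features, targets, _ = sm_data
    return run_single(features, targets, sm_config, pattern_id=6,
                      train_config=TrainConfig(seed=BENCH_SEED))
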