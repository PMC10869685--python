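import numpy as np
import pytest

from dvscreen import (SynthParams, TrainConfig, generate_cohort,
                      generate_exams_in_memory, train, train_test_split_by_study)


@pytest.fixture(scope="session")
def small_cohort():
    """60-study in-memory cohort at the generator's default signal strength."""
    return generate_exams_in_memory(SynthParams(seed=5), 60)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    exams = [e for e, _ in small_cohort]
    return train_test_split_by_study(exams, 0.3, seed=1)


@pytest.fixture(scope="session")
def trained_model(small_split):
    tr, te = small_split
    model, history = train(tr, te, TrainConfig(seed=1))
    return model, history


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """10-study cohort written to disk with manifest and YOLO annotations."""
    out = tmp_path_factory.mktemp("cohort")
    manifest = generate_cohort(SynthParams(seed=9), 10, out)
    return out, manifest
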