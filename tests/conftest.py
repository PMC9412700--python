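import numpy as np
import pytest

import gripdec as gd


def make_trial(values, rate=100.0, subject="S01", run=1, block=1,
               task="fingertip_touching", stage="raw"):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return gd.Trial(values=values, sample_rate=rate, subject_id=subject,
                    run=run, block=block, task=task, stage=stage)


@pytest.fixture(scope="session")
def velocity_dataset():
    """4 subjects x 60 trials of preprocessed velocity, low noise."""
    cfg = gd.SyntheticConfig(n_subjects_per_group=2, runs=1,
                             noise_sd=0.02, seed=1)
    return gd.preprocess_dataset(gd.generate_dataset(cfg))


@pytest.fixture(scope="session")
def chance_dataset():
    """6 subjects x 60 trials: large enough that the finite-sample bias of
    the permutation estimator stays well under the Monte-Carlo tolerance."""
    cfg = gd.SyntheticConfig(n_subjects_per_group=3, runs=1,
                             noise_sd=0.02, seed=1)
    return gd.preprocess_dataset(gd.generate_dataset(cfg))


@pytest.fixture(scope="session")
def within_subject_dataset():
    """2 subjects x 3 runs for leave-one-run-out evaluation."""
    cfg = gd.SyntheticConfig(n_subjects_per_group=1, runs=3,
                             noise_sd=0.02, seed=2)
    return gd.preprocess_dataset(gd.generate_dataset(cfg))


@pytest.fixture(scope="session")
def raw_dataset_small():
    cfg = gd.SyntheticConfig(n_subjects_per_group=1, runs=1,
                             trials_per_block=2, noise_sd=0.02, seed=4)
    return gd.generate_dataset(cfg)
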