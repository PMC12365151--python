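"""Shared fixtures: seeded RNGs and small prepared phantom cohorts."""

import numpy as np
import pytest

import cmmfnet as cm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def _prepare_cohort(n_cases: int, seed: int, noise_sd: float,
                    crop_small=(16, 16, 16), crop_large=(32, 32, 16)):
    """Generate and preprocess a stratified phantom cohort in memory."""
    spec = cm.PhantomSpec(noise_sd=noise_sd, seed=seed)
    gen = np.random.default_rng(seed)
    counts = cm.apportion_counts(spec.class_probs, n_cases)
    labels = np.repeat(np.arange(spec.n_classes), counts)
    labels = labels[gen.permutation(n_cases)]
    cases = []
    for i, label in enumerate(labels):
        raw = cm.sample_case(spec, int(label), gen)
        cases.append(cm.prepare_case(raw.volume, raw.bbox, raw.ehr, raw.label,
                                     case_id=f"case_{i:03d}", resample=False,
                                     crop_small=crop_small,
                                     crop_large=crop_large))
    return cases


@pytest.fixture(scope="session")
def separable_cohort_120():
    """120 noise-free phantoms: the three classes are separable by lesion
    size alone, so a working learner must reach high accuracy."""
    return _prepare_cohort(120, seed=42, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort_30():
    """30 noisy phantoms for quick structural tests of the CV machinery."""
    return _prepare_cohort(30, seed=7, noise_sd=0.05)


@pytest.fixture(scope="session")
def fitted_ehr_state(small_cohort_30):
    import pandas as pd

    from cmmfnet.preprocess import fit_ehr_encoder

    records = pd.DataFrame([c.ehr_record for c in small_cohort_30])
    return fit_ehr_encoder(records)
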