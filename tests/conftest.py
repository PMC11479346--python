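import numpy as np
import pytest

from vimsdetect.synthdata import ScenarioConfig, simulate_session


@pytest.fixture(scope="session")
def default_session():
    """One noisy severe session with the default scenario."""
    return simulate_session(ScenarioConfig(duration_s=360, seed=11))


@pytest.fixture(scope="session")
def noise_free_session():
    """Deterministic session: no noise, no RR modulation, effects kept."""
    cfg = ScenarioConfig(duration_s=360, seed=3).noise_free()
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def features_default(default_session):
    from vimsdetect.features import extract_features
    rec, _ = default_session
    return extract_features(rec)


@pytest.fixture(scope="session")
def small_dataset():
    """Preprocessed 5-participant dataset for model-level tests."""
    from vimsdetect import preprocess
    from vimsdetect.features import extract_features
    from vimsdetect.synthdata import simulate_cohort

    cohort = simulate_cohort(5, ScenarioConfig(duration_s=240), seed=21,
                             severe_fraction=0.8)
    sessions = []
    for rec, _ in cohort:
        fs = extract_features(rec)
        ls = preprocess.build_label_series(rec.reports, fs.timestamps)
        sessions.append((preprocess.standardize(fs), ls))
    thr = preprocess.fit_clip_thresholds([s for s, _ in sessions])
    repaired = [(preprocess.repair_outliers(s, thr), ls) for s, ls in sessions]
    dataset, counts = preprocess.assemble_dataset(repaired)
    return dataset, counts
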