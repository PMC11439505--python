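import numpy as np
import pytest

import adherence_da as ad


@pytest.fixture(scope="session")
def schedule_series_30():
    """30 days under the prescribed 5-on/2-off weekly schedule, 45 min."""
    return np.array([45.0 if i % 7 < 5 else 0.0 for i in range(30)])


@pytest.fixture(scope="session")
def small_cohort():
    """Six mixed-archetype participants, 60 days each."""
    spec = ad.CohortSpec(n_participants=6, n_days=60, seed=42)
    return ad.generate_cohort(spec)


@pytest.fixture(scope="session")
def lapse_cohort():
    """Homogeneous consistent-with-lapses cohort with moderate shift."""
    spec = ad.CohortSpec(
        n_participants=8, n_days=60, seed=3,
        archetype_mix={"consistent_with_lapses": 1.0}, shift=0.5)
    return ad.generate_cohort(spec)


@pytest.fixture(scope="session")
def target_and_sources(lapse_cohort):
    """Windowed target train/test plus pooled source windows (N=7)."""
    tr, te, _ = ad.participant_windows(lapse_cohort[0], 7)
    src = ad.WindowedDataset.concatenate(
        [ad.participant_windows(lg, 7)[0].with_domain(1)
         for lg in lapse_cohort[1:]])
    return tr, te, src


@pytest.fixture(scope="session")
def fast_cnn_cfg():
    return ad.CNNConfig(epochs=40, early_stop_patience=10, seed=7)
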