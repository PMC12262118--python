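import numpy as np
import pytest

import erplearn as el


def make_pairs(deviants, standards, deviant_types=None, times_ms=None,
               channel_names=("F3", "Fz", "F4", "A2"), day=1,
               participant="sub-01", start_id=1):
    """Construct a PairedEpochSet directly from arrays (test plumbing)."""
    deviants = np.asarray(deviants, dtype=float)
    standards = np.asarray(standards, dtype=float)
    n = deviants.shape[0]
    if deviant_types is None:
        deviant_types = np.array(["dev_large"] * n, dtype=object)
    if times_ms is None:
        times_ms = el.epoch_grid(250.0)
    dev_ids = start_id + 3 * np.arange(n)
    return el.PairedEpochSet(
        deviants=deviants, standards=standards,
        deviant_types=np.asarray(deviant_types, dtype=object),
        deviant_trial_ids=dev_ids, standard_trial_ids=dev_ids - 1,
        times_ms=np.asarray(times_ms, dtype=float),
        channel_names=channel_names, participant=participant, day=day,
    )


@pytest.fixture(scope="session")
def noiseless_config():
    return el.StudyConfig(
        n_participants=1, n_days=2, participant_sd_uv=0.0,
        sequence=el.SequenceSpec(n_total=300, seed=11),
        noise=el.NoiseSpec(sigma_uv=0.0, artifact_rate=0.0),
    )


@pytest.fixture(scope="session")
def noiseless_pairs(noiseless_config):
    """Day-1 balanced pairs from a noise-free session: signal is exactly the
    generator templates."""
    sess = next(iter(el.simulate_study(noiseless_config)))
    return el.preprocess_session(sess.recording, sess.events,
                                 participant=sess.participant, day=sess.day)


@pytest.fixture(scope="session")
def small_study_pairs():
    """2 participants x 2 days at study noise levels, 300 stimuli/session."""
    cfg = el.StudyConfig(
        n_participants=2, n_days=2,
        sequence=el.SequenceSpec(n_total=300, seed=5),
        noise=el.NoiseSpec(sigma_uv=10.0, artifact_rate=0.0),
        seed=42,
    )
    out = {}
    for sess in el.simulate_study(cfg):
        out[(sess.participant, sess.day)] = el.preprocess_session(
            sess.recording, sess.events,
            participant=sess.participant, day=sess.day)
    return out
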