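import pytest

import vitalcast as vc
from vitalcast.synthetic import PRESSOR_NAMES

STATIC_NAMES = [f"static_{k}" for k in range(4)]


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject cohort shared by preparation/model tests."""
    return vc.simulate_cohort(vc.SimulationParams(n_subjects=40, seed=7))


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    """Prepared windows + subject split for the 40-subject cohort."""
    schema = vc.default_schema(vc.CHANNELS, STATIC_NAMES)
    ids = sorted(small_cohort.static_table.subject_id)
    train_ids, test_ids = vc.split_subjects(ids, 0.8, seed=7)
    ws, report = vc.prepare_windows(
        small_cohort.long_table,
        small_cohort.static_table,
        schema,
        train_ids,
        pressor_names=list(PRESSOR_NAMES),
    )
    return ws, train_ids, test_ids, report


@pytest.fixture(scope="session")
def tiny_model(small_windows):
    """An untrained fixture-size model matched to the small window set."""
    ws, *_ = small_windows
    cfg = vc.ModelConfig.from_windowset(ws, state_size=16, dropout=0.1)
    return vc.TFTMulti(cfg, seed=7)


def rand_loss_instance(rng, B=8, H=25, T=5, Q=3):
    truth = rng.normal(size=(B, H, T))
    forecasts = rng.normal(size=(B, H, T, Q))
    masks = (rng.random((B, H, T)) < 0.6).astype(float)
    return truth, forecasts, masks
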