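import numpy as np
import pytest

from dualtask import synthetic as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_config():
    """One cycle of 4-trial blocks: the smallest valid blocked design."""
    return syn.ExperimentConfig(n_participants=1, trials_per_block=4,
                                trials_per_combination=4)


@pytest.fixture(scope="session")
def default_design_one_participant():
    cfg = syn.ExperimentConfig(n_participants=1)
    return cfg, syn.generate_design(cfg, seed=7)


@pytest.fixture(scope="session")
def none_trial(default_design_one_participant):
    """An auditory-WM trial without an Intervening task."""
    _, design = default_design_one_participant
    trials = [t for b in design[0] for t in b]
    return next(t for t in trials if t.cell.intervening == "none"
                and t.cell.wm_modality == "auditory")


@pytest.fixture(scope="session")
def intervening_trial(default_design_one_participant):
    _, design = default_design_one_participant
    trials = [t for b in design[0] for t in b]
    return next(t for t in trials if t.cell.intervening == "AT")
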