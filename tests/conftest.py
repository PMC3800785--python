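"""Shared fixtures: short synthetic calls reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

from cicadasong.config import AnalysisConfig
from cicadasong.synth import default_call_spec, synth_call

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def short_chiricahua():
    """A short chiricahua-template call (phrases 0.6/2.5/0.6 s) + ground truth."""
    spec = default_call_spec("chiricahua", seed=11, phrase_durations=(0.6, 2.5, 0.6))
    return synth_call(spec)


@pytest.fixture(scope="session")
def short_neomexicensis():
    """A short neomexicensis-template call + ground truth."""
    spec = default_call_spec("neomexicensis", seed=12, phrase_durations=(0.6, 2.5, 0.6))
    return synth_call(spec)


@pytest.fixture(scope="session")
def full_calls():
    """One full call per species at the measured species-mean parameters."""
    out = {}
    for sp in ("chiricahua", "neomexicensis"):
        out[sp] = synth_call(default_call_spec(sp, seed=1))
    return out


@pytest.fixture()
def config_chiricahua():
    return AnalysisConfig(species="chiricahua")


@pytest.fixture()
def config_neomexicensis():
    return AnalysisConfig(species="neomexicensis")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
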