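import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from turntaking.synthetic_data import SyntheticConfig, generate_corpus
from turntaking.types import ExGaussParams, Utterance


@pytest.fixture(scope="session")
def small_corpus():
    """A few children per group with all structural effects switched on."""
    cfg = SyntheticConfig(n_children={"autism": 4, "typical": 3}, seed=7)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_observations(small_corpus):
    from turntaking.turns_io import corpus_latencies

    return corpus_latencies(small_corpus.utterance_objects())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_utt(role, on, off, **kw):
    """Shorthand for a single-session utterance."""
    base = dict(dyad_id="d1", child_id="c1", group="autism", visit=1,
                context="convo_parent")
    base.update(kw)
    return Utterance(speaker_role=role, onset_s=on, offset_s=off, **base)


@pytest.fixture
def exg_truth():
    return ExGaussParams(mu_s=0.859, sigma_s=0.618, beta_log=0.19)
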