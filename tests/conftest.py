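import numpy as np
import pytest

from turnalign.corpus_io import Conversation, Turn
from turnalign.features import annotate_rates, default_lexicon


def make_conversation(conv_id, roles_texts):
    """Build a Conversation from (role, text) pairs."""
    turns = [
        Turn(conversation_id=conv_id, index=i, role=role, text=text)
        for i, (role, text) in enumerate(roles_texts)
    ]
    return Conversation(id=conv_id, turns=turns)


def alternating_conversation(conv_id, n_pairs, user_text="i think so", assistant_text="the answer is"):
    pairs = []
    for _ in range(n_pairs):
        pairs.append(("user", user_text))
        pairs.append(("assistant", assistant_text))
    return make_conversation(conv_id, pairs)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """A deterministic 30-conversation synthetic corpus with its rate table."""
    from turnalign.synthetic import SyntheticSpec, generate_corpus

    spec = SyntheticSpec(n_conversations=30, n_turn_pairs=6, seed=7)
    convs, truth = generate_corpus(spec, lexicon=lexicon)
    rates = annotate_rates(convs, lexicon)
    return convs, rates, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
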