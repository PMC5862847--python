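import numpy as np
import pytest

from rpas import (
    AuthorProfile,
    Chunk,
    fixture_lexicons,
    generate_corpus,
)

BASE_RATES = {
    "article": 0.06,
    "conjunctive": 0.03,
    "preposition": 0.10,
    "pronoun": 0.05,
    "visual": 0.02,
    "haptic": 0.015,
    "olfactory": 0.008,
    "gustatory": 0.008,
}


@pytest.fixture(scope="session")
def lexicons():
    """Deterministic (particle, sensory) fixture lexicon pair."""
    return fixture_lexicons(seed=0)


@pytest.fixture(scope="session")
def two_profiles():
    """Authors differing only in their auditory-adjective usage rate."""
    return (
        AuthorProfile("alice", lexicon_rates={**BASE_RATES, "auditory": 0.02}),
        AuthorProfile("bob", lexicon_rates={**BASE_RATES, "auditory": 0.06}),
    )


@pytest.fixture(scope="session")
def small_corpus(two_profiles, lexicons):
    """10 works per author, 2000 tokens each, generated at seed 0."""
    ra, sens = lexicons
    return generate_corpus(two_profiles, 10, 2000, seed=0,
                           ra_lexicon=ra, sensory_lexicon=sens)


def make_chunk(tokens, chunk_id=1, work_id="w"):
    return Chunk.from_tokens(chunk_id, work_id, tokens)


@pytest.fixture()
def mixed_chunk(lexicons):
    """A chunk containing pronouns, particles and sensory adjectives."""
    rng = np.random.default_rng(42)
    ra, sens = lexicons
    vocab = (
        [f"bg{i}" for i in range(50)]
        + ["my", "her", "its", "his"]
        + list(ra.entries)
        + list(sens.entries)
    )
    tokens = rng.choice(vocab, size=800).tolist()
    return make_chunk(tokens)
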