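from __future__ import annotations

import random

import pytest

from termsweep.lexicon import build_default_lexicon

# word soup ingredients for randomized counting texts
_FILLER = [
    "apple", "meadow", "quartz", "violet", "harbor", "number", "stone",
    "cloud", "river", "basket", "copper", "signal", "danger", "breast",
    "cancer", "health", "website", "therapy", "hormone", "chemical",
    "toxic", "environment", "chemotherapy", "toxicity", "retardant",
    "endocrine", "disrupting", "activity", "history", "density",
]
_SEPARATORS = [" ", "  ", ", ", ". ", " - ", "-", "\n", "; ", ": ", " – "]


@pytest.fixture(scope="session")
def lexicon():
    return build_default_lexicon()


@pytest.fixture(scope="session")
def all_variants(lexicon):
    return [v for g in lexicon for v in g.variants]


def make_random_text(rng: random.Random, variants: list[str],
                     n_pieces: int = 60) -> str:
    """Word soup with planted variants, adversarial separators and case."""
    pieces = []
    for _ in range(n_pieces):
        r = rng.random()
        if r < 0.35:
            word = rng.choice(variants)
        else:
            word = rng.choice(_FILLER)
        if rng.random() < 0.2:
            word = word.upper() if rng.random() < 0.5 else word.capitalize()
        pieces.append(word)
        pieces.append(rng.choice(_SEPARATORS))
    return "".join(pieces)
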