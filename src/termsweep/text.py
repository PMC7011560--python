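"""Low-level text utilities shared by the cleaning and counting stages.

Tokenization treats a maximal run of letters/digits as one token;
punctuation and underscores are boundaries. This is deliberately the
simplest rule under which "BPA," and "pesticides." match their variants.
"""

from __future__ import annotations

import re
from typing import NamedTuple

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)

# Inter-token gap allowed inside a multi-word phrase match: whitespace
# and/or hyphen runs only.  A comma or other punctuation breaks the phrase.
PHRASE_GAP_RE = re.compile(r"[\s\-‐‑–]+")


class Token(NamedTuple):
    text: str
    start: int
    end: int


def tokenize(text: str) -> list[Token]:
    """Split *text* into letter/digit-run tokens with character offsets."""
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def tokens(text: str) -> list[str]:
    """Token strings only (no offsets)."""
    return [m.group() for m in _TOKEN_RE.finditer(text)]


def is_phrase_gap(text: str, start: int, end: int) -> bool:
    """True if text[start:end] is a legal gap between phrase tokens."""
    if start == end:
        return False  # tokens are maximal runs, so a zero gap cannot occur
    return PHRASE_GAP_RE.fullmatch(text, start, end) is not None


# -- fixed stopword lists for the English/Spanish language heuristic --------
# Function words only; none collides with a lexicon term.

SPANISH_STOPWORDS = frozenset(
    """de la que el en y a los del se las por un para con no una su al lo como
    más pero sus le ya o este sí porque esta entre cuando muy sin sobre también
    me hasta hay donde quien desde todo nos durante todos uno les ni contra
    otros ese eso ante ellos e esto mí antes algunos qué unos yo otro otras
    otra él tanto esa estos mucho quienes nada muchos cual poco ella estar
    estas algunas algo nosotros""".split()
)

ENGLISH_STOPWORDS = frozenset(
    """the of and a to in is was it for on are as with his they at be this
    have from or one had by word but not what all were we when your can said
    there use an each which she do how their if will up other about out many
    then them these so some her would make like him into time has look two
    more write go see number no way could people my than first been who its
    now find long down day did get come made may part over new""".split()
)
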