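"""Lexicon sentiment scoring on the VADER model.

Implements the valence-aware lexicon approach: each lexicon word carries a
mean valence on a [-4, 4] scale; token valences are adjusted for negation
("not good" flips and damps the valence) and degree modifiers ("very good"
boosts it), summed, and squashed to a compound score in [-1, 1] via
x / sqrt(x^2 + 15).  0 is neutral; the empty string scores 0.  The lexicon
shipped here is compact (a few hundred high-frequency sentiment words
covering news/social-media vocabulary), and the backend is a modular
component — any object with ``score(text) -> float in [-1, 1]`` can replace
it, e.g. a domain-adapted conservation lexicon.
"""

from __future__ import annotations

import math

from .records import tokenize
from ._sentlex import LEXICON

NEGATIONS = frozenset({
    "not", "no", "never", "neither", "nor", "cannot", "cant", "dont",
    "doesnt", "didnt", "isnt", "arent", "wasnt", "werent", "wont",
    "without", "hardly", "rarely",
})

BOOSTERS = {
    "very": 0.293, "extremely": 0.293, "incredibly": 0.293, "hugely": 0.293,
    "really": 0.267, "so": 0.267, "deeply": 0.267, "truly": 0.267,
    "slightly": -0.293, "somewhat": -0.293, "marginally": -0.293,
    "barely": -0.293,
}

_NEGATION_SCOPE = 3
_NEGATION_FACTOR = -0.74
_NORM_ALPHA = 15.0


class LexiconSentimentBackend:
    """Compound-score sentiment backend over a valence lexicon."""

    def __init__(self, lexicon: dict[str, float] | None = None):
        self.lexicon = dict(lexicon if lexicon is not None else LEXICON)

    def score(self, text: str) -> float:
        tokens = tokenize(text)
        total = 0.0
        for i, tok in enumerate(tokens):
            valence = self.lexicon.get(tok)
            if valence is None:
                continue
            window = tokens[max(0, i - _NEGATION_SCOPE):i]
            boost = sum(
                BOOSTERS[w] * (1 if valence > 0 else -1)
                for w in window if w in BOOSTERS
            )
            valence += boost
            if any(w in NEGATIONS for w in window):
                valence *= _NEGATION_FACTOR
            total += valence
        if total == 0.0:
            return 0.0
        compound = total / math.sqrt(total * total + _NORM_ALPHA)
        return max(-1.0, min(1.0, compound))


_default_backend: LexiconSentimentBackend | None = None


def default_backend() -> LexiconSentimentBackend:
    global _default_backend
    if _default_backend is None:
        _default_backend = LexiconSentimentBackend()
    return _default_backend
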