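"""Sentence segmentation, keyword matching, and taxon-mention snippets.

Entity mention detection: an article may discuss many things, so sentiment
and topic analysis are applied not to whole articles but to the sentence
containing a taxon keyword plus the sentence immediately preceding it (for
context).  Matching is case-insensitive, word-boundary, whole-phrase, with
an optional plural rule, and a positive hit is vetoed when it lies inside a
longer negative phrase (*lion* inside *sea lion*).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .records import ArticleRecord
from .taxonomy import KeywordSet, Phrase, phrase_str

logger = logging.getLogger(__name__)

#: Abbreviations that do not end a sentence even when followed by a capital.
ABBREVIATIONS = frozenset({
    "dr", "mr", "mrs", "ms", "prof", "sr", "jr", "st", "mt", "no", "vs",
    "etc", "e.g", "i.e", "fig", "al", "inc", "ltd", "co", "dept", "univ",
    "approx", "jan", "feb", "mar", "apr", "jun", "jul", "aug", "sep",
    "sept", "oct", "nov", "dec", "u.s", "u.k",
})


@dataclass(frozen=True)
class Sentence:
    text: str
    start: int
    end: int


_BOUNDARY_RE = re.compile(r"[.!?]+[\"'”’)\]]*\s+(?=[A-Z0-9\"'“‘(])")


def segment_sentences(text: str) -> list[Sentence]:
    """Rule-based sentence segmentation with spans into the original text.

    A boundary is terminal punctuation followed by whitespace and an
    uppercase letter or digit, unless the preceding token is a known
    abbreviation or a single initial.  Spans exclude inter-sentence
    whitespace, so slicing the text at each span reproduces each sentence.
    """
    if not text:
        return []
    cuts = []
    for m in _BOUNDARY_RE.finditer(text):
        prefix = text[:m.start()]
        last = re.search(r"([\w.’']+)$", prefix)
        if last:
            token = last.group(1).lower().rstrip(".")
            if token in ABBREVIATIONS or (len(token) == 1 and token.isalpha()):
                continue
        cuts.append(m.end())
    sentences = []
    prev = 0
    for cut in cuts + [len(text)]:
        chunk = text[prev:cut]
        stripped = chunk.strip()
        if stripped:
            start = prev + chunk.index(stripped[0])
            sentences.append(Sentence(stripped, start, start + len(stripped)))
        prev = cut
    return sentences


def phrase_pattern(phrase: Phrase, plural: bool = True) -> re.Pattern:
    """Compiled regex for a whole-phrase, word-boundary match.

    Words may be separated by whitespace or hyphens; with ``plural`` the
    final word also matches its "-s"/"-es" form.  Word boundaries prevent
    substring hits ("batch" never matches "bat").
    """
    words = [re.escape(w) for w in phrase]
    if plural:
        words[-1] += "(?:e?s)?"
    return re.compile(r"(?<![\w-])" + r"[\s\-‐]+".join(words) + r"(?![\w-])",
                      re.IGNORECASE)


@dataclass(frozen=True)
class KeywordMatch:
    keyword: Phrase
    start: int
    end: int


@dataclass(frozen=True)
class MatchResult:
    matches: tuple[KeywordMatch, ...]
    negative_present: bool


def match_keywords(text: str, k: KeywordSet, plural: bool = True) -> MatchResult:
    """All positive-keyword occurrences with span-level negative suppression.

    A positive occurrence is discarded when its span lies inside an
    occurrence of any negative phrase; ``negative_present`` flags whether any
    negative occurs anywhere, supporting the stricter document-level veto the
    search APIs apply.
    """
    neg_spans = []
    for neg in k.negatives:
        for m in phrase_pattern(neg, plural).finditer(text):
            neg_spans.append((m.start(), m.end()))
    matches = []
    for pos in sorted(k.positives):
        for m in phrase_pattern(pos, plural).finditer(text):
            if any(s <= m.start() and m.end() <= e for s, e in neg_spans):
                continue
            matches.append(KeywordMatch(pos, m.start(), m.end()))
    matches.sort(key=lambda km: (km.start, km.end))
    return MatchResult(tuple(matches), bool(neg_spans))


@dataclass(frozen=True)
class Snippet:
    """A taxon mention: the matched sentence prefixed by its predecessor."""

    article_id: str
    text: str
    matched_keyword: Phrase
    char_span: tuple[int, int]


def extract_snippets(article: ArticleRecord, k: KeywordSet,
                     plural: bool = True) -> list[Snippet]:
    """One snippet per sentence containing a surviving positive match.

    The snippet text is the mention sentence preceded by the sentence before
    it (none for a first-sentence match); multiple matches inside one
    sentence yield a single snippet.
    """
    if not article.body:
        logger.info("article %s has no body text", article.article_id)
        return []
    sentences = segment_sentences(article.body)
    result = match_keywords(article.body, k, plural=plural)
    snippets = []
    seen: set[int] = set()
    for km in result.matches:
        idx = next(
            (i for i, s in enumerate(sentences)
             if s.start <= km.start and km.end <= s.end),
            None,
        )
        if idx is None or idx in seen:
            continue
        seen.add(idx)
        parts = sentences[max(idx - 1, 0):idx + 1]
        snippets.append(Snippet(
            article_id=article.article_id,
            text=" ".join(s.text for s in parts),
            matched_keyword=km.keyword,
            char_span=(km.start, km.end),
        ))
    return snippets
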