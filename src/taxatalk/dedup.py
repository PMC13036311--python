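"""Syndicated-article detection via TF-IDF cosine similarity.

Mainstream outlets republish wire stories nearly verbatim; analyzing each
copy would double-count discourse.  Articles are vectorized with TF-IDF
(raw term counts, idf = ln((1+N)/(1+df)) + 1, L2-normalized) and every pair
published within a 60-day window is compared by cosine similarity.  The
later article of a pair exceeding 0.95 is labeled a syndicate of the
earlier one; an article below 0.95 against every predecessor in the window
is an original.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .querygen import normalize_url
from .records import ArticleRecord, tokenize

logger = logging.getLogger(__name__)


def tfidf_vectors(texts: Sequence[str]):
    """L2-normalized TF-IDF matrix (scipy sparse, docs x vocabulary).

    Uses the shared word tokenizer; vocabulary is sorted, so the column
    order is deterministic.  Empty documents yield zero rows, flagged with a
    warning.
    """
    if not texts:
        raise ValueError("empty corpus")
    vec = TfidfVectorizer(analyzer=tokenize, norm="l2",
                          smooth_idf=True, sublinear_tf=False)
    matrix = vec.fit_transform(texts)
    empties = int((matrix.getnnz(axis=1) == 0).sum())
    if empties:
        logger.warning("%d documents vectorized to zero (no tokens)", empties)
    return matrix, vec


def cosine(u, v) -> float:
    """Cosine similarity of two L2-normalized sparse rows (0 for zero vectors)."""
    return float(u.multiply(v).sum())


@dataclass(frozen=True)
class SyndicationLabel:
    article_id: str
    status: str  # "original" | "syndicate"
    parent_id: str | None
    max_similarity: float


def flag_syndicates(
    articles: Sequence[ArticleRecord],
    threshold: float = 0.95,
    window: dt.timedelta | int = 60,
    parents_original_only: bool = False,
) -> list[SyndicationLabel]:
    """Label each article original or syndicate.

    Articles are processed chronologically (ties broken by normalized URL);
    an article is a syndicate iff some earlier article within ``window``
    (endpoints inclusive) exceeds ``threshold`` cosine similarity (strict),
    with the earliest such article as parent.  By default a syndicate may
    itself be a parent (pure pairwise rule); ``parents_original_only``
    re-links parents to the root of their chain.  Articles without dates are
    excluded with a warning.
    """
    if isinstance(window, int):
        window = dt.timedelta(days=window)
    dated = [a for a in articles if a.date is not None]
    if len(dated) < len(articles):
        logger.warning("excluded %d undated articles", len(articles) - len(dated))
    if not dated:
        return []
    order = sorted(dated, key=lambda a: (a.date, normalize_url(a.url)))
    matrix, _ = tfidf_vectors([a.body for a in order])
    sims = (matrix @ matrix.T).toarray()

    labels: dict[str, SyndicationLabel] = {}
    for i, art in enumerate(order):
        best_sim = 0.0
        parent = None
        for j in range(i):
            if (art.date - order[j].date) > window:
                continue
            s = float(sims[i, j])
            best_sim = max(best_sim, s)
            if s > threshold and parent is None:
                parent = order[j]  # earliest qualifying predecessor
        if parent is not None:
            pid = parent.article_id
            if parents_original_only:
                while labels[pid].parent_id is not None:
                    pid = labels[pid].parent_id
            labels[art.article_id] = SyndicationLabel(
                art.article_id, "syndicate", pid, best_sim)
        else:
            labels[art.article_id] = SyndicationLabel(
                art.article_id, "original", None, best_sim)
    return [labels[a.article_id] for a in order]
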