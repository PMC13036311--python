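"""End-to-end orchestration: filter -> dedup -> snippets -> analytics.

Glues the stage modules together the way a monitoring run would use them:
titles are scored and filtered for relevance, relevant articles are
deduplicated per taxon, taxon-mention snippets are extracted from the
surviving originals and scored for sentiment, and volume/sentiment series
with breakpoints plus a topic co-occurrence matrix come out the other end.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

from .analytics import (
    BreakpointResult, CooccurrenceMatrix, DiscourseSeries, aggregate,
    article_sentiment, cooccurrence, detect_breakpoints,
)
from .dedup import SyndicationLabel, flag_syndicates
from .records import ArticleRecord
from .relevance import (
    RelevanceDecision, TopicInventory, decide_relevance, score_topics,
)
from .taxonomy import KeywordSet
from .textproc import extract_snippets

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    decisions: dict[str, RelevanceDecision]
    syndication: dict[str, SyndicationLabel]
    sentiment_scores: dict[str, float]
    volume_series: list[DiscourseSeries]
    sentiment_series: list[DiscourseSeries]
    breakpoints: list[BreakpointResult]
    topic_cooccurrence: CooccurrenceMatrix
    kept_articles: list[ArticleRecord]


def run_pipeline(
    articles: Sequence[ArticleRecord],
    taxa: Sequence[KeywordSet],
    inventory: TopicInventory,
    backend,
    threshold: float = 0.5,
    dedup_threshold: float = 0.95,
    window_days: int = 60,
    by: str = "biweek",
    date_range: tuple[dt.date, dt.date] | None = None,
    sentiment_backend=None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on retrieved articles.

    Sentiment is computed on each article's concatenated taxon-mention
    snippets for news and on the full text for social posts; series and
    breakpoints are computed on relevant original articles only, with
    Bonferroni correction over all series tested.
    """
    keyword_sets = {k.taxon_label: k for k in taxa}

    decisions: dict[str, RelevanceDecision] = {}
    for art in articles:
        scores = score_topics(art.title, inventory, backend)
        decisions[art.article_id] = decide_relevance(scores, inventory, threshold)
    relevant = [a for a in articles if decisions[a.article_id].relevant]
    logger.info("relevance filter kept %d / %d articles", len(relevant), len(articles))

    syndication: dict[str, SyndicationLabel] = {}
    for label in sorted({a.taxon_label for a in relevant}):
        group = [a for a in relevant if a.taxon_label == label]
        for lab in flag_syndicates(group, threshold=dedup_threshold,
                                   window=window_days):
            syndication[lab.article_id] = lab

    kept = [a for a in relevant
            if syndication[a.article_id].status == "original"]

    sentiment_scores: dict[str, float] = {}
    for art in kept:
        ks = keyword_sets.get(art.taxon_label)
        if art.source == "news" and ks is not None and art.body:
            snippets = extract_snippets(art, ks)
            sentiment_scores[art.article_id] = article_sentiment(
                (s.text for s in snippets), backend=sentiment_backend)
        else:
            sentiment_scores[art.article_id] = article_sentiment(
                [art.body or art.title], backend=sentiment_backend)

    volume_series = aggregate(kept, by=by, date_range=date_range)
    sentiment_series = aggregate(kept, by=by, metric="sentiment",
                                 sentiment_scores=sentiment_scores,
                                 date_range=date_range)
    breakpoints = detect_breakpoints(
        volume_series + sentiment_series, alpha=alpha, n_perm=n_perm, seed=seed)

    matrix = cooccurrence(
        (decisions[a.article_id].triggering_topics for a in kept),
        labels=sorted(inventory.labels),
    )
    return PipelineResult(
        decisions=decisions,
        syndication=syndication,
        sentiment_scores=sentiment_scores,
        volume_series=volume_series,
        sentiment_series=sentiment_series,
        breakpoints=breakpoints,
        topic_cooccurrence=matrix,
        kept_articles=kept,
    )
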