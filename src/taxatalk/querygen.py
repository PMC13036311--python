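"""Boolean query rendering and date-interval batching for capped search APIs.

News/search APIs such as the GDELT DOC API cap results per call (250 by
default here), so a multi-year window must be tiled into short intervals and
the per-interval result batches merged and URL-deduplicated afterwards.  No
network I/O lives here: rendering and batching are pure functions, and live
retrieval sits behind whatever adapter the caller supplies.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from urllib.parse import parse_qsl, urlencode, urlsplit, urlunsplit

from .records import ArticleRecord
from .taxonomy import KeywordSet, Phrase, phrase_str

logger = logging.getLogger(__name__)

DIALECTS = ("gdelt_doc", "twitter_v2")


@dataclass(frozen=True)
class QuerySpec:
    keywords: KeywordSet
    date_start: dt.date
    date_end: dt.date
    language: str = "en"
    max_results_per_call: int = 250

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")
        if self.max_results_per_call < 1:
            raise ValueError("max_results_per_call must be >= 1")


def _term(phrase: Phrase, quote_single: bool) -> str:
    s = phrase_str(phrase)
    return f'"{s}"' if (" " in s or quote_single) else s


def render_query(k: KeywordSet, dialect: str) -> str:
    """Render a keyword set as a boolean query string.

    Positives are OR-joined in parentheses, negatives each prefixed with the
    dialect's negation operator; term order is sorted for determinism.  The
    GDELT dialect quotes every term; the Twitter dialect quotes only
    multi-word phrases.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    quote_single = dialect == "gdelt_doc"
    pos = " OR ".join(_term(p, quote_single) for p in sorted(k.positives))
    parts = [f"({pos})"]
    for n in sorted(k.negatives):
        parts.append(f'-{_term(n, True)}')
    return " ".join(parts)


def split_intervals(
    spec: QuerySpec, granularity: dt.timedelta | int
) -> list[tuple[dt.date, dt.date]]:
    """Tile ``[date_start, date_end]`` with half-open intervals.

    Intervals are ``[start, end)`` of the given length; the last one may be
    shorter.  Their union is exactly the closed query range.
    """
    if isinstance(granularity, int):
        granularity = dt.timedelta(days=granularity)
    if granularity < dt.timedelta(days=1):
        raise ValueError("granularity must be >= 1 day")
    limit = spec.date_end + dt.timedelta(days=1)
    out = []
    start = spec.date_start
    while start < limit:
        end = min(start + granularity, limit)
        out.append((start, end))
        start = end
    return out


_TRACKING_PARAMS = ("fbclid", "gclid", "igshid", "mc_cid", "mc_eid", "ref", "s")


def normalize_url(url: str) -> str:
    """Canonicalize a URL: lowercase scheme/host, strip fragment and tracking params."""
    parts = urlsplit(url.strip())
    query = [
        (k, v) for k, v in parse_qsl(parts.query, keep_blank_values=True)
        if not k.lower().startswith("utm_") and k.lower() not in _TRACKING_PARAMS
    ]
    return urlunsplit((
        parts.scheme.lower(), parts.netloc.lower(), parts.path,
        urlencode(query), "",
    ))


def merge_batches(batches: Iterable[Sequence[ArticleRecord]]) -> list[ArticleRecord]:
    """Concatenate interval batches, dedupe by normalized URL, sort by (date, url).

    The earliest-dated record wins for a repeated URL; records missing a URL
    are dropped with a logged count.
    """
    best: dict[str, ArticleRecord] = {}
    dropped = 0
    for batch in batches:
        for rec in batch:
            if not rec.url:
                dropped += 1
                continue
            key = normalize_url(rec.url)
            cur = best.get(key)
            if cur is None or (rec.date, rec.url) < (cur.date, cur.url):
                best[key] = rec
    if dropped:
        logger.warning("dropped %d records without URLs", dropped)
    return sorted(best.values(), key=lambda r: (r.date, r.url))
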