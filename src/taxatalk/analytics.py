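"""Discourse analytics: volume/sentiment series, breakpoints, topic co-occurrence.

Volume is the count of relevant, original articles mentioning a taxon per
period (month or 14-day bin) and optionally per source country; sentiment is
the per-article compound score in [-1, 1] averaged per bin.  A single
mean-shift changepoint is sought per series with a likelihood-ratio scan and
a seeded permutation p-value, Bonferroni-corrected over the number of series
tested in the run.  Topic co-occurrence counts articles whose predicted
topic sets contain each label pair, the input for chord diagrams.
"""

from __future__ import annotations

import datetime as dt
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ArticleRecord
from .sentiment import default_backend

logger = logging.getLogger(__name__)


@dataclass
class DiscourseSeries:
    """One discourse time series (counts or mean sentiment per bin)."""

    taxon_label: str
    source: str
    bins: list[dt.date]          # bin start dates, contiguous and sorted
    values: np.ndarray
    country: str | None = None
    metric: str = "volume"

    @property
    def series_id(self) -> str:
        parts = [self.taxon_label, self.source, self.metric]
        if self.country:
            parts.append(self.country)
        return "/".join(parts)


def _bin_start(date: dt.date, by: str, anchor: dt.date) -> dt.date:
    if by == "month":
        return date.replace(day=1)
    if by == "biweek":
        offset = (date - anchor).days // 14
        return anchor + dt.timedelta(days=14 * offset)
    raise ValueError(f"unknown binning {by!r}")


def _bin_range(start: dt.date, end: dt.date, by: str, anchor: dt.date) -> list[dt.date]:
    bins = []
    cur = _bin_start(start, by, anchor)
    last = _bin_start(end, by, anchor)
    while cur <= last:
        bins.append(cur)
        if by == "month":
            cur = (cur + dt.timedelta(days=32)).replace(day=1)
        else:
            cur = cur + dt.timedelta(days=14)
    return bins


def aggregate(
    articles: Sequence[ArticleRecord],
    by: str = "month",
    group_by_country: bool = False,
    metric: str = "volume",
    sentiment_scores: Mapping[str, float] | None = None,
    date_range: tuple[dt.date, dt.date] | None = None,
) -> list[DiscourseSeries]:
    """Aggregate articles into zero-filled discourse series.

    One series per (taxon, source) — or (taxon, source, country) when
    ``group_by_country`` — over the full date range, with empty bins kept at
    zero.  ``metric="volume"`` counts articles; ``metric="sentiment"``
    averages the supplied per-article scores (bins without articles hold 0,
    the neutral score).  Biweekly bins are anchored at the range start.
    """
    dated = [a for a in articles if a.date is not None]
    if not dated:
        logger.warning("no dated articles to aggregate")
        return []
    if metric == "sentiment" and sentiment_scores is None:
        raise ValueError("sentiment metric requires sentiment_scores")
    start, end = date_range or (min(a.date for a in dated), max(a.date for a in dated))
    anchor = start
    bins = _bin_range(start, end, by, anchor)
    bin_index = {b: i for i, b in enumerate(bins)}

    rows = []
    for a in dated:
        if not (start <= a.date <= end):
            continue
        rows.append({
            "taxon": a.taxon_label, "source": a.source,
            "country": a.country if group_by_country else None,
            "bin": _bin_start(a.date, by, anchor),
            "value": (sentiment_scores[a.article_id]
                      if metric == "sentiment" else 1.0),
        })
    frame = pd.DataFrame(rows)
    if frame.empty:
        logger.warning("no articles inside the date range")
        return []
    out = []
    agg = "mean" if metric == "sentiment" else "sum"
    for (taxon, source, country), grp in frame.groupby(
            ["taxon", "source", "country"], dropna=False, sort=True):
        values = np.zeros(len(bins))
        binned = grp.groupby("bin")["value"].agg(agg)
        for b, v in binned.items():
            values[bin_index[b]] = v
        out.append(DiscourseSeries(
            taxon_label=taxon, source=source, bins=list(bins), values=values,
            country=None if pd.isna(country) else country, metric=metric,
        ))
    return out


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with population sd; constant series map to zeros."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 bins")
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def sentiment(text: str, backend=None) -> float:
    """Compound sentiment score in [-1, 1]; empty text scores 0 (neutral)."""
    if not text or not text.strip():
        return 0.0
    backend = backend or default_backend()
    s = backend.score(text)
    if not -1.0 <= s <= 1.0:
        raise RuntimeError(f"backend score out of [-1,1]: {s}")
    return s


def article_sentiment(snippet_texts: Iterable[str], backend=None) -> float:
    """Sentiment of an article's concatenated taxon-mention snippets.

    Tying the score to mention contexts keeps it about the taxon rather
    than the article's other threads; posts, being short, are scored whole.
    """
    return sentiment(" ".join(snippet_texts), backend=backend)


# ---------------------------------------------------------------------------
# Breakpoint analysis

@dataclass(frozen=True)
class BreakpointResult:
    series_id: str
    break_index: int | None     # post-break segment starts at this bin
    pre_mean: float
    post_mean: float
    statistic: float
    p_value: float
    significant: bool
    n_tests: int


def _max_shift_stat(x: np.ndarray, min_seg: int) -> tuple[np.ndarray, np.ndarray]:
    """Max mean-shift likelihood-ratio statistic per row of ``x``.

    Returns (stat, argmax split index) for each row; stat is
    n*log(SSE0/SSE1) for the best split with both segments >= min_seg.
    Vectorized over rows so permutation nulls are cheap.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    csum = np.cumsum(x, axis=1)
    csq = np.cumsum(x * x, axis=1)
    total, total_sq = csum[:, -1:], csq[:, -1:]
    sse0 = total_sq - total**2 / n
    ts = np.arange(min_seg, n - min_seg + 1)
    left_n = ts[None, :]
    left_sum = csum[:, ts - 1]
    sse_left = csq[:, ts - 1] - left_sum**2 / left_n
    right_sum = total - left_sum
    right_n = n - left_n
    sse_right = (total_sq - csq[:, ts - 1]) - right_sum**2 / right_n
    sse1 = sse_left + sse_right
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sse1 > 0, sse0 / np.maximum(sse1, 1e-300), np.inf)
        ratio = np.where(sse0 > 0, ratio, 1.0)
        stat = n * np.log(ratio)
    best = np.argmax(stat, axis=1)
    return stat[np.arange(x.shape[0]), best], ts[best]


def detect_breakpoint(
    series: DiscourseSeries | np.ndarray,
    alpha: float = 0.05,
    n_tests: int = 1,
    n_perm: int = 999,
    seed: int = 0,
    min_seg: int = 3,
) -> BreakpointResult:
    """At-most-one-changepoint test for a shift in the series mean.

    Scans every split leaving >= ``min_seg`` bins on each side, takes the
    split maximizing the Gaussian mean-shift likelihood-ratio statistic, and
    assesses it with a seeded permutation test (bin order shuffled).  The
    break is significant iff p <= alpha / n_tests (Bonferroni over the
    series tested in the run).  A constant series yields no break.
    """
    if isinstance(series, DiscourseSeries):
        values, sid = np.asarray(series.values, float), series.series_id
    else:
        values, sid = np.asarray(series, float), "series"
    n = values.size
    if n < 2 * min_seg + 2 or n < 8:
        raise ValueError(f"series too short for breakpoint analysis (n={n})")
    stat, split = _max_shift_stat(values, min_seg)
    stat, split = float(stat[0]), int(split[0])
    if values.std() == 0 or stat <= 0:
        mean = float(values.mean())
        return BreakpointResult(sid, None, mean, mean, 0.0, 1.0, False, n_tests)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = values[rng.permutation(n)]
    null_stat, _ = _max_shift_stat(perms, min_seg)
    p = (1.0 + float((null_stat >= stat).sum())) / (n_perm + 1.0)
    significant = p <= alpha / max(n_tests, 1)
    return BreakpointResult(
        series_id=sid,
        break_index=split,
        pre_mean=float(values[:split].mean()),
        post_mean=float(values[split:].mean()),
        statistic=stat,
        p_value=p,
        significant=significant,
        n_tests=n_tests,
    )


def detect_breakpoints(
    series_list: Sequence[DiscourseSeries],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    min_seg: int = 3,
) -> list[BreakpointResult]:
    """Breakpoint test per series with automatic Bonferroni m = number of series."""
    m = len(series_list)
    logger.info("breakpoint scan over %d series (Bonferroni m=%d)", m, m)
    return [
        detect_breakpoint(s, alpha=alpha, n_tests=m, n_perm=n_perm,
                          seed=seed + i, min_seg=min_seg)
        for i, s in enumerate(series_list)
    ]


# ---------------------------------------------------------------------------
# Topic co-occurrence

@dataclass
class CooccurrenceMatrix:
    labels: list[str]
    counts: np.ndarray   # symmetric; diagonal = per-topic article counts

    @property
    def marginals(self) -> np.ndarray:
        return np.diag(self.counts)

    def to_json_dict(self) -> dict:
        return {"labels": self.labels, "counts": self.counts.tolist()}


def cooccurrence(
    topic_sets: Iterable[Iterable[str]],
    labels: Sequence[str],
) -> CooccurrenceMatrix:
    """Count articles containing each topic pair (diagonal: each single topic)."""
    labels = sorted(labels)
    index = {lbl: i for i, lbl in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for topics in topic_sets:
        ts = sorted(set(topics))
        unknown = [t for t in ts if t not in index]
        if unknown:
            raise KeyError(f"topics not in label list: {unknown}")
        for i, a in enumerate(ts):
            for b in ts[i:]:
                counts[index[a], index[b]] += 1
                if a != b:
                    counts[index[b], index[a]] += 1
    return CooccurrenceMatrix(labels=labels, counts=counts)
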