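"""Shared record types and tokenization for articles and posts."""

from __future__ import annotations

import datetime as dt
import json
import re
from collections.abc import Iterable
from dataclasses import asdict, dataclass, field


@dataclass(frozen=True)
class ArticleRecord:
    """One news item or social-media post.

    Field names mirror the GDELT DOC API metadata (title, url, domain,
    date, sourcecountry) with ``source`` distinguishing news from social
    posts and ``taxon_label`` recording which folk-taxon query returned it.
    """

    article_id: str
    title: str
    url: str
    domain: str = ""
    date: dt.date | None = None
    country: str = ""
    taxon_label: str = ""
    body: str = ""
    source: str = "news"

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["date"] = self.date.isoformat() if self.date else None
        return d

    @staticmethod
    def from_json_dict(d: dict) -> "ArticleRecord":
        d = dict(d)
        if d.get("date"):
            d["date"] = dt.date.fromisoformat(d["date"])
        return ArticleRecord(**d)


def write_articles_jsonl(path, articles: Iterable[ArticleRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            fh.write(json.dumps(a.to_json_dict()) + "\n")


def read_articles_jsonl(path) -> list[ArticleRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(ArticleRecord.from_json_dict(json.loads(line)))
    return out


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokens; hyphens and punctuation split words.

    Shared by snippet matching and TF-IDF so syndication labels do not
    depend on a second, subtly different tokenizer.
    """
    return _TOKEN_RE.findall(text.lower())
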