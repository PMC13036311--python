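"""Turn keyword sets into API-ready boolean queries and date batches.

Result-capped search APIs (250 items per call) need the study period tiled
into short intervals; the batches are merged and URL-deduplicated.
"""

import datetime as dt

import taxatalk as tt

lion = tt.KeywordSet(
    "lion",
    positives=frozenset({("lion",)}),
    negatives=frozenset({("mountain", "lion"), ("sea", "lion")}),
)

for dialect in ("gdelt_doc", "twitter_v2"):
    print(f"{dialect}: {tt.render_query(lion, dialect)}")

spec = tt.QuerySpec(lion, dt.date(2019, 1, 1), dt.date(2021, 12, 31))
intervals = tt.split_intervals(spec, 14)
print(f"{len(intervals)} intervals of <=14 days tile 2019-2021; "
      f"first={intervals[0]}, last={intervals[-1]}")

# merging interval batches removes repeated URLs, keeping the earliest date
a = tt.ArticleRecord("a", "story", "https://news.example.com/item?utm_source=rss",
                     date=dt.date(2019, 1, 9))
b = tt.ArticleRecord("b", "story", "https://NEWS.example.com/item",
                     date=dt.date(2019, 1, 2))
merged = tt.merge_batches([[a], [b]])
print(f"merged 2 batch records into {len(merged)}; kept {merged[0].article_id} "
      f"dated {merged[0].date} (earliest for the normalized URL)")
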