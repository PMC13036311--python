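"""Detect syndicated (near-duplicate) articles with TF-IDF cosine similarity.

A wire story republished verbatim within the 60-day window is labeled a
syndicate of the earliest matching article; the same text far outside the
window counts as a fresh original.
"""

import datetime as dt

import taxatalk as tt

story = ("A pangolin was rescued from traffickers near the reserve gate. "
         "Rangers released it after a health check by the field vet team.")
other = ("The city council approved the new bridge budget on Thursday. "
         "Construction is expected to begin before the rains arrive.")

articles = [
    tt.ArticleRecord("orig", "Pangolin rescued", "https://a.example.com/1",
                     date=dt.date(2020, 3, 1), body=story),
    tt.ArticleRecord("copy", "Pangolin rescued", "https://b.example.net/77",
                     date=dt.date(2020, 3, 9), body=story),
    tt.ArticleRecord("late", "Pangolin rescued", "https://c.example.org/4",
                     date=dt.date(2020, 8, 1), body=story),
    tt.ArticleRecord("news", "Bridge budget", "https://d.example.org/9",
                     date=dt.date(2020, 3, 2), body=other),
]

for label in tt.flag_syndicates(articles, threshold=0.95, window=60):
    print(f"{label.article_id}: {label.status:9s} parent={label.parent_id} "
          f"max_sim={label.max_similarity:.3f}")
# "copy" is a syndicate of "orig" (similarity 1.0 inside the window);
# "late" repeats the text but 5 months later, so it is an original.
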