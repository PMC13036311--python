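"""Volume, sentiment, and breakpoint analysis of a discourse time series.

Generates a corpus whose article rate jumps from about 3 to 20 per biweekly
bin at the middle of the series, then recovers the shift with the
mean-shift permutation test (Bonferroni-corrected).
"""

import datetime as dt

import numpy as np

import taxatalk as tt

bat = tt.KeywordSet("horseshoe bat", frozenset({("horseshoe", "bat")}))
articles, truth = tt.gen_corpus(
    11, [bat], n_bins=52, break_spec={"horseshoe bat": (26, 3.0, 20.0)},
    syndication_rate=0.0, irrelevance_rate=0.0)

end = truth.start_date + dt.timedelta(days=truth.n_bins * truth.bin_days - 1)
series = tt.aggregate(articles, by="biweek",
                      date_range=(truth.start_date, end))[0]
print(f"series: {len(series.bins)} biweekly bins, "
      f"total {int(series.values.sum())} articles")
print(f"z-scored head: {np.round(tt.zscore(series.values)[:5], 2)}")

result = tt.detect_breakpoint(series, n_tests=10, seed=3)
print(f"break at bin {result.break_index} "
      f"(planted {truth.planted_breaks['horseshoe bat'][0]}), "
      f"means {result.pre_mean:.1f} -> {result.post_mean:.1f}, "
      f"p={result.p_value:.3f}, significant={result.significant}")

# sentiment of the taxon-mention snippets of the first article
art = articles[0]
snips = tt.extract_snippets(art, bat)
score = tt.article_sentiment(s.text for s in snips)
sign = truth.planted_sentiment_sign[art.article_id]
print(f"first article sentiment={score:+.2f} (planted sign {sign:+d})")
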