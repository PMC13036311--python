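"""The full pipeline on a seeded synthetic world.

Names -> folk taxonomy -> expert edits -> keywords -> corpus -> relevance
filter -> syndication dedup -> snippets/sentiment -> series/breakpoints,
with every stage checked against the planted ground truth.
"""

import datetime as dt

import taxatalk as tt
from taxatalk.taxonomy import name_set_node

species, name_truth = tt.gen_names(42)
graph, candidates = tt.build_taxonomy(species)
edited = tt.apply_edits(graph, name_truth.planted_edit_script)
print(f"{len(species)} species -> {len(tt.components(edited))} folk taxa "
      f"(planted {len(name_truth.planted_taxa)}); "
      f"conflations severed: {name_truth.conflations}")

taxa = [tt.derive_keywords(edited, name_set_node(l), list(candidates),
                           taxon_label=l)
        for l in sorted(name_truth.planted_taxa)]

articles, truth = tt.gen_corpus(42, taxa)
end = truth.start_date + dt.timedelta(days=truth.n_bins * truth.bin_days - 1)
result = tt.run_pipeline(articles, taxa, tt.DEFAULT_INVENTORY,
                         tt.KeywordTopicBackend(),
                         date_range=(truth.start_date, end), seed=0)

metrics = tt.evaluate_filter(
    {aid: d.relevant for aid, d in result.decisions.items()},
    truth.planted_relevance)
print(f"filter: precision={metrics.precision:.3f} recall={metrics.recall:.3f}")

synd_ok = sum(lab.parent_id == truth.planted_syndicates.get(aid)
              for aid, lab in result.syndication.items())
print(f"dedup: {synd_ok}/{len(result.syndication)} labels match planted parents")

for r in result.breakpoints:
    if r.significant:
        print(f"breakpoint: {r.series_id} at bin {r.break_index}, "
              f"{r.pre_mean:.1f} -> {r.post_mean:.1f} articles/bin, "
              f"p={r.p_value:.3f} (m={r.n_tests})")
planted = {t: s[0] for t, s in truth.planted_breaks.items() if s}
print(f"planted break: {planted}")

m = result.topic_cooccurrence
top = max(
    ((m.labels[i], m.labels[j], m.counts[i][j])
     for i in range(len(m.labels)) for j in range(i + 1, len(m.labels))),
    key=lambda t: t[2])
print(f"most co-occurring topic pair in kept articles: {top}")
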