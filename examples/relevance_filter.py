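"""Topic-based relevance filtering of article titles.

Scores titles against the 23-topic inventory with the deterministic lexical
backend (the NLI backend is a drop-in replacement via the same contract),
applies the any-relevant-topic > 0.5 rule, and evaluates against labels.
Also demonstrates LDA topic induction on a tiny two-theme snippet corpus.
"""

import random

import taxatalk as tt

inventory = tt.DEFAULT_INVENTORY
backend = tt.KeywordTopicBackend()

titles = {
    "t1": ("Elephant herd crosses wildlife corridor near park", True),
    "t2": ("Elephant Rovers win league match at home", False),
    "t3": ("Conservation rangers count bat colony at dusk", True),
    "t4": ("Shares of Bat Global climb after merger news", False),
}

decisions = {}
for aid, (title, _gold) in titles.items():
    scores = tt.score_topics(title, inventory, backend)
    d = tt.decide_relevance(scores, inventory)
    decisions[aid] = d.relevant
    top = sorted(d.triggering_topics)
    print(f"{aid}: relevant={d.relevant} triggered={top} :: {title}")

metrics = tt.evaluate_filter(decisions, {k: g for k, (_, g) in titles.items()})
print(f"precision={metrics.precision} recall={metrics.recall} "
      f"f1={metrics.f1} npv={metrics.npv}")

# LDA topic induction: two planted themes separate into two topics
rng = random.Random(0)
wildlife = ["bat", "roost", "colony", "forest", "cave", "insect"]
sports = ["match", "league", "goal", "coach", "season", "fans"]
docs = [[rng.choice(wildlife) for _ in range(15)] for _ in range(15)] + \
       [[rng.choice(sports) for _ in range(15)] for _ in range(15)]
model = tt.fit_lda(docs, k=2, iterations=100, seed=0)
for t, words in enumerate(tt.top_words(model, 5)):
    print(f"topic {t} top words: {words}")
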