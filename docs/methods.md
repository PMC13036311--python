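# Methods

This note documents the models and procedures implemented in taxatalk,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## Folk-taxonomy derivation

**Model.** The public refers to species by folk taxa — *bat*, *sea lion*,
*wallaby* — rather than scientific or full common names. Related species'
common names tend to share their trailing words, so the trailing word
sequence is used as the grouping signal. For every unordered pair of
normalized names the longest contiguous run of words shared *at the end of
both* is computed (a word-level specialization of longest-common-substring
matching; character substrings are never considered, so *at* is not an
ending of *bat*). Each unique ending defines a candidate taxon whose
members are **all** input names ending with it, not only the generating
pair. Every full name is also a candidate (its own singleton ending).
Candidates are partially ordered by strict subset of member sets; the
transitive reduction of that order (Hasse diagram) gives the hierarchy
edges. Species nodes and name-set nodes form an undirected graph (listing
edges species↔name set, subset edges name set↔name set); connected
components are top-level candidate folk taxa.

**Normalization.** Lowercase; apostrophes and punctuation dropped; hyphens
split into words, so *long-tongued bat* and *long tongued bat* unify.
Names empty after normalization are dropped with a logged warning, and
species with no usable English common name are skipped with a logged
count — the algorithm has nothing to group them by.

**Expert review as data.** The human review step is a declarative edit
script (remove_edge / remove_node / merge / select_taxon), applied in list
order, versioned alongside the inputs. This makes the subjective step
replayable and diffable. Removals only affect connectivity; species
records are never deleted. `merge` adds a synthetic name-set node joining
two components' label nodes.

**Keyword derivation.** For a selected name-set node, positives are its
ending plus the endings of name-set nodes below it in the hierarchy within
its post-edit component. Negatives are computed against the **pre-edit**
global ending inventory: every ending of which the selected ending is a
proper word-suffix and which is no longer in the selection's component.
Conflations severed by review therefore surface as negative keywords
(*lion* NOT *sea lion* NOT *mountain lion*). The emitted set can include
redundant longer negatives (*south american sea lion* alongside *sea
lion*); redundancy is harmless under all-must-be-absent semantics.

**Degenerate candidates.** If two distinct endings ever covered exactly
the same member set, the shortest ending would be kept as the node label
and the longer recorded as an alias, avoiding zero-information hierarchy
edges. Analysis shows this cannot arise from the algorithm's own outputs
(an ending produced by a pair is maximal for that pair), so the alias
mechanism is defensive; tests assert member-set uniqueness instead.

## Query generation

Keyword sets render to boolean queries: positives OR-joined, negatives
prefixed with `-`, phrases quoted, terms sorted for determinism. Two
dialects are provided (GDELT-DOC-style, which quotes every term, and
Twitter-style, which quotes only phrases). Result-capped APIs (default
250 per call) are handled by tiling the query period into half-open
intervals — default 14 days, a choice balancing per-interval volume
against call count — whose union is exactly the closed range. Batch
merging deduplicates by normalized URL (lowercased scheme/host, fragment
and tracking parameters stripped), keeping the earliest-dated record.
Live retrieval, authentication and scraping are deliberately out of
scope; network I/O sits behind whatever adapter the caller supplies.

## Mention snippets

Sentiment and topic analysis are applied to *entity mention* snippets: the
sentence containing a taxon keyword plus the immediately preceding
sentence for context (first-sentence matches stand alone; multiple
matches in one sentence yield one snippet). Sentence segmentation is
rule-based — terminal `.!?` followed by whitespace and an uppercase letter
or digit, with an abbreviation list (Dr., e.g., Fig., ...) and a
single-initial guard — which is deterministic, dependency-light and
adequate for news prose; it will over-segment exotic typography.

Keyword matching is case-insensitive, word-boundary and whole-phrase, with
hyphen/whitespace equivalence between words and an optional plural rule
("-s"/"-es" on the final word, default on, since news text uses plurals
heavily). A positive hit is suppressed when its span lies inside a
negative-phrase occurrence, so *sea lion* neutralizes its inner *lion*
without vetoing other *lion* mentions in the same document; the stricter
document-level veto the search APIs apply is exposed as a
`negative_present` flag.

## Relevance filtering

**Topic induction.** LDA is fit by collapsed Gibbs sampling with symmetric
priors α = 50/K, β = 0.01 (standard Griffiths–Steyvers defaults), K = 40
and 150 sweeps by default for real snippet corpora; the sampler is exact,
deterministic given a seed, and drops empty documents with a warning. The
top-20 words per topic (ties broken lexicographically) are reviewed by a
human who assigns semantic labels and merges or discards topics — captured
in config, not code. The shipped default inventory has 23 labels: 15
relevant (agriculture, climate change, conservation, energy, health,
infrastructure, natural disasters, nature, outdoor recreation, science and
technology, tourism, wildlife, habitat loss, invasive species, pollution)
and 8 irrelevant (business, crime, education, entertainment, food,
holidays, politics, sports).

**Zero-shot scoring.** Article titles are scored against every label
independently (multi-label, no cross-label normalization) by a pluggable
backend. The NLI backend phrases each label as the hypothesis "This
example is {label}." (template configurable) and uses an entailment model
via the optional `nli` extra. The shipped lexical backend scores a label
high when one of its cue words occurs in the title — deterministic,
offline, and contract-identical, so the pipeline's decision logic is
testable without model weights. A title is relevant iff any *relevant*
topic scores strictly above 0.5; irrelevant-topic scores never veto, which
makes the decision monotone in relevant-topic scores.

**Evaluation.** Precision tp/(tp+fp), recall tp/(tp+fn), F1 (harmonic
mean), and NPV tn/(tn+fn) against ground-truth labels; undefined ratios
are reported as absent rather than zero.

## Syndication detection

Articles are vectorized with TF-IDF (raw term counts,
idf = ln((1+N)/(1+df)) + 1, L2-normalized, sorted vocabulary — the
scikit-learn default formulation) over the shared word tokenizer, fitted
per taxon so cross-taxon vocabulary does not shift document frequencies.
Every pair published within 60 days of each other (a fixed-window reading
of "two months"; calendar months vary) is compared by cosine similarity;
if it strictly exceeds 0.95, the later article is a syndicate of the
earlier one, with the earliest qualifying predecessor as parent. Same-date
ties order by normalized URL. Predecessor status is ignored by default (a
syndicate can be a parent, matching the pairwise rule); an optional mode
re-links parents to the chain root. Comparison uses article bodies only.

## Discourse analytics

**Aggregation.** Counts (or mean sentiment) of relevant, original articles
per taxon, source, and optionally country, in monthly or 14-day bins
anchored at the range start, zero-filled across the whole range.
Z-scoring uses the population standard deviation, mapping constant series
to zeros.

**Sentiment.** A valence-lexicon model of the VADER family: per-word
valences on a [−4, 4] scale, negation flipping and damping (factor −0.74
within a 3-token window), degree boosters, and the compound squashing
x/√(x² + 15) into [−1, 1] with 0 neutral. The shipped lexicon is compact
(~260 high-frequency evaluative words including wildlife-coverage
vocabulary: poaching, rescue, extinction, thriving). News-article
sentiment is computed on the concatenation of the article's mention
snippets — tying tone to the taxon rather than the article's other
threads — while posts, being short, are scored whole. The backend is
modular: anything exposing `score(text) -> [−1, 1]` can replace it (e.g. a
domain-adapted conservation lexicon, which would fix known artifacts such
as *threatened species* scoring negative).

**Breakpoints.** An at-most-one-changepoint search: every split leaving at
least 3 bins per segment is scored with the Gaussian mean-shift
likelihood-ratio statistic n·log(SSE₀/SSE₁), and the maximizing split is
assessed by a seeded permutation test (bin order shuffled, 999
permutations, p = (1 + #{null ≥ obs})/(n_perm + 1)). This
single-shift-plus-permutation design was chosen over penalized
multi-changepoint machinery because one significant break per series is
the reporting unit and permutation nulls are assumption-light for counts.
Significance is Bonferroni-corrected: p ≤ α/m with m the number of series
tested in the run, computed automatically. The statistic is vectorized
over permutations, so testing hundreds of series is cheap. Measured on
simulated data (the acceptance script recomputes both numbers): detection
of a Poisson 3→20 shift at the midpoint of a 52-bin series is essentially
certain within ±1 bin even at m = 10, and the null rejection rate at
nominal α = 0.05 stays at the nominal level.

**Co-occurrence.** The symmetric matrix counting articles whose predicted
topic sets contain both labels of a pair (diagonal: single-topic counts),
exported as JSON for chord-diagram tools.

## Synthetic worlds

The generator defines the package's test conditions. `gen_names` builds
modifier×head-noun clusters ({rock, forest}×*wallaby*) with the bare head
listed for single-word-head clusters, and plants head-noun conflations
(*sea lion* after *lion*) at a configurable rate (default 0.25 over 6
clusters), together with the edit script severing each conflation and the
negatives it should generate. `gen_corpus` emits, per taxon and 14-day
bin over 52 bins, Poisson numbers of relevant originals (base mean 3;
the first taxon jumps to 20 at bin 26 by default — magnitudes chosen to
match the scale of real taxon coverage shifts), irrelevant items at a rate
making them half of the originals, and syndicated verbatim copies at a
rate making them 40% of relevant articles, dated within the 60-day window
of their parent. Relevant titles embed cue words of relevant topics;
irrelevant titles use the taxon word non-biologically (sports teams,
companies, films) with irrelevant-topic cues only. Mention sentences carry
planted positive or negative sentiment vocabulary; all other sentences are
sentiment-neutral. Each original ends with serial-unique reference tokens,
giving distinct originals the distinctive vocabulary (bylines, ids) that
keeps them apart under TF-IDF while verbatim copies still match exactly.

What this does *not* emulate: linguistic variety (templated prose, small
vocabulary), paraphrased syndication, mixed-relevance articles, sarcasm or
domain-shifted sentiment, multilingual content, and titles whose topical
cues are subtler than single words. Passing end-to-end tests therefore
demonstrates that the pipeline's logic is correct under its stated rules,
not that any particular zero-shot model or lexicon reaches a given
accuracy on real news — those numbers depend on external data and models
and must be measured per deployment (the filter-evaluation tooling is the
instrument for exactly that).

## Numerical conventions and problem sizes

Determinism everywhere: sorted iteration orders, explicit seeds for every
stochastic step (one `random.Random(seed)` per generator call; numpy
`default_rng(seed)` for permutation tests), byte-identical serialization
for identical inputs. Degenerate inputs have defined behavior: empty text
scores sentiment 0; zero TF-IDF vectors have similarity 0; constant series
yield no breakpoint (p = 1); undefined classification ratios are absent,
not 0. Test and acceptance problem sizes — 1000 suffix pairs, 200
hierarchy instances, 100 graphs, 50 syndication corpora, a 200-doc ×
100-token LDA corpus, 100 planted-shift replicates and 500 null series,
and a ~3.5k-article synthetic world — were chosen so the full suite
completes in well under a minute while leaving each check statistically
meaningful.

## Known limitations

- Hierarchy construction is O(n³) in the candidate count; fine for the
  synthetic worlds and single-order name tables, but a full multi-thousand
  name inventory would want the obvious size-bucketing optimizations.
- The Gibbs LDA sampler is a pure-Python loop: ~3 s for 20k tokens × 150
  sweeps at K = 3, proportionally slower at K = 40 on large corpora.
- The sentence splitter and plural rule are English-only, by scope.
- The permutation test assumes exchangeable bins under the null;
  autocorrelated series would need a block-permutation variant.
- `merge_batches` trusts normalized URLs as identity; mirrored content at
  different URLs is left to the syndication stage.
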