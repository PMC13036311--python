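"""Topic-based relevance filtering of retrieved article titles.

Keyword search drags in taxon names used non-biologically (Clemson Tigers,
Tiger Woods, "elephant in the room").  The filter works in two stages:

1. *Topic induction.*  Latent Dirichlet allocation over taxon-mention
   snippets reveals the thematic contexts in which taxon names appear; a
   human reviews each topic's top words, labels it, and partitions the
   labels into relevant (wildlife, conservation, tourism, ...) and
   irrelevant (sports, politics, ...) sets.  The shipped default inventory
   has 23 labels, 15 relevant and 8 irrelevant.
2. *Zero-shot title scoring.*  Each article title is scored in [0, 1]
   against every topic label, independently (multi-label), by a pluggable
   backend — an NLI entailment model phrased as "This example is {label}.",
   or a deterministic lexical mock for testing.  A title is relevant iff any
   *relevant* topic scores strictly above 0.5; irrelevant topics never veto.
"""

from __future__ import annotations

import logging
import random
import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Topic inventory

@dataclass(frozen=True)
class TopicInventory:
    relevant: frozenset[str]
    irrelevant: frozenset[str]

    def __post_init__(self) -> None:
        if self.relevant & self.irrelevant:
            raise ValueError("relevant and irrelevant topic sets must be disjoint")

    @property
    def labels(self) -> frozenset[str]:
        return self.relevant | self.irrelevant


#: The default 23-topic inventory used for news-title relevance filtering.
DEFAULT_INVENTORY = TopicInventory(
    relevant=frozenset({
        "agriculture", "climate change", "conservation", "energy", "health",
        "infrastructure", "natural disasters", "nature", "outdoor recreation",
        "science and technology", "tourism", "wildlife", "habitat loss",
        "invasive species", "pollution",
    }),
    irrelevant=frozenset({
        "business", "crime", "education", "entertainment", "food",
        "holidays", "politics", "sports",
    }),
)


# ---------------------------------------------------------------------------
# LDA by collapsed Gibbs sampling

@dataclass
class TopicModel:
    """Fitted LDA model: per-topic word and per-document topic distributions."""

    k: int
    vocab: list[str]
    topic_word: np.ndarray  # (K, V), rows sum to 1
    doc_topic: np.ndarray   # (D, K), rows sum to 1
    iterations: int
    seed: int


def fit_lda(
    docs: Sequence[Sequence[str]],
    k: int,
    iterations: int = 150,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
) -> TopicModel:
    """Fit LDA with collapsed Gibbs sampling.

    Symmetric priors default to the Griffiths–Steyvers values alpha = 50/K,
    beta = 0.01.  Empty documents are dropped with a warning (their doc-topic
    rows are uniform).  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if alpha is None:
        alpha = 50.0 / k
    kept_idx = [i for i, d in enumerate(docs) if len(d) > 0]
    if len(kept_idx) < len(docs):
        logger.warning("dropped %d empty documents", len(docs) - len(kept_idx))
    kept = [list(docs[i]) for i in kept_idx]
    vocab = sorted({w for d in kept for w in d})
    if len(vocab) < k:
        raise ValueError("vocabulary smaller than number of topics")
    windex = {w: i for i, w in enumerate(vocab)}
    v = len(vocab)

    rng = random.Random(seed)
    # Count tables as plain lists: the sampler is a tight scalar loop and
    # K is small, so Python floats beat per-token numpy dispatch.
    nwt = [[0] * k for _ in range(v)]
    ndt = [[0] * k for _ in range(len(kept))]
    nt = [0] * k
    doc_words: list[list[int]] = []
    assign: list[list[int]] = []
    for d, doc in enumerate(kept):
        ws, zs = [], []
        for w in doc:
            wi = windex[w]
            z = rng.randrange(k)
            ws.append(wi)
            zs.append(z)
            nwt[wi][z] += 1
            ndt[d][z] += 1
            nt[z] += 1
        doc_words.append(ws)
        assign.append(zs)

    vbeta = v * beta
    krange = range(k)
    for _ in range(iterations):
        for d, ws in enumerate(doc_words):
            zs = assign[d]
            nd = ndt[d]
            for i, wi in enumerate(ws):
                z = zs[i]
                row = nwt[wi]
                row[z] -= 1
                nd[z] -= 1
                nt[z] -= 1
                total = 0.0
                weights = [0.0] * k
                for t in krange:
                    wt = (row[t] + beta) * (nd[t] + alpha) / (nt[t] + vbeta)
                    weights[t] = wt
                    total += wt
                u = rng.random() * total
                acc = 0.0
                z = k - 1
                for t in krange:
                    acc += weights[t]
                    if u < acc:
                        z = t
                        break
                zs[i] = z
                row[z] += 1
                nd[z] += 1
                nt[z] += 1

    topic_word = (np.asarray(nwt, dtype=float).T + beta)
    topic_word /= topic_word.sum(axis=1, keepdims=True)
    doc_topic_kept = np.asarray(ndt, dtype=float) + alpha
    doc_topic_kept /= doc_topic_kept.sum(axis=1, keepdims=True)
    doc_topic = np.full((len(docs), k), 1.0 / k)
    for row, i in enumerate(kept_idx):
        doc_topic[i] = doc_topic_kept[row]
    return TopicModel(k=k, vocab=vocab, topic_word=topic_word,
                      doc_topic=doc_topic, iterations=iterations, seed=seed)


def top_words(model: TopicModel, n: int = 20) -> list[list[str]]:
    """The n highest-probability words per topic, ties broken lexicographically."""
    if n > len(model.vocab):
        raise ValueError("n exceeds vocabulary size")
    out = []
    for row in model.topic_word:
        order = sorted(range(len(model.vocab)),
                       key=lambda i: (-row[i], model.vocab[i]))
        out.append([model.vocab[i] for i in order[:n]])
    return out


# ---------------------------------------------------------------------------
# Zero-shot backends

DEFAULT_HYPOTHESIS_TEMPLATE = "This example is {label}."


class KeywordTopicBackend:
    """Deterministic lexical zero-shot stand-in: cue word tables per topic.

    A label scores high when any of its cue words occurs (word-boundary,
    case-insensitive) in the text, low otherwise.  Used for tests and for
    synthetic corpora whose templates embed these cues; it implements the
    same ``score`` contract as the NLI backend.
    """

    def __init__(self, cues: Mapping[str, Iterable[str]] | None = None,
                 hit: float = 0.9, miss: float = 0.05):
        self.cues = {lbl: tuple(ws) for lbl, ws in (cues or DEFAULT_CUES).items()}
        self.hit = hit
        self.miss = miss

    def score(self, text: str, labels: Iterable[str]) -> dict[str, float]:
        scores = {}
        for label in labels:
            found = False
            for cue in self.cues.get(label, ()):
                if re.search(r"\b" + re.escape(cue) + r"\b", text, re.IGNORECASE):
                    found = True
                    break
            scores[label] = self.hit if found else self.miss
        return scores


#: Cue tables for the lexical mock backend, aligned with the synthetic
#: corpus templates (see synthcorpus).
DEFAULT_CUES: dict[str, tuple[str, ...]] = {
    "wildlife": ("wildlife", "herd", "endangered", "poaching", "colony", "roost"),
    "nature": ("nature", "forest", "river", "wilderness", "ecosystem"),
    "conservation": ("conservation", "sanctuary", "reserve", "protected", "rangers"),
    "health": ("health", "virus", "disease", "outbreak", "vaccine"),
    "tourism": ("tourism", "tourists", "safari", "travellers"),
    "agriculture": ("farmers", "crops", "livestock", "harvest"),
    "climate change": ("climate", "warming", "drought", "emissions"),
    "natural disasters": ("flood", "earthquake", "hurricane", "bushfire"),
    "outdoor recreation": ("hikers", "camping", "trail", "birdwatching"),
    "science and technology": ("researchers", "study", "scientists", "genome"),
    "energy": ("turbines", "solar", "pipeline", "powerplant"),
    "infrastructure": ("bridge", "highway", "construction", "railway"),
    "habitat loss": ("deforestation", "logging", "habitat"),
    "invasive species": ("invasive",),
    "pollution": ("pollution", "plastic", "spill"),
    "sports": ("match", "league", "season", "cricket", "innings", "coach",
               "tournament", "championship"),
    "politics": ("election", "minister", "parliament", "senator", "campaign"),
    "business": ("shares", "profits", "startup", "merger", "stocks"),
    "entertainment": ("film", "album", "celebrity", "premiere", "mascot"),
    "crime": ("arrested", "robbery", "trial", "verdict"),
    "education": ("students", "curriculum", "tuition"),
    "food": ("recipe", "restaurant", "menu", "chef"),
    "holidays": ("festival", "parade", "fireworks"),
}


class NliZeroShotBackend:
    """Zero-shot multi-label scoring via an NLI entailment model.

    Requires the optional ``nli`` extra (transformers + torch); each label is
    scored independently as the entailment probability of the hypothesis
    "This example is {label}.".
    """

    def __init__(self, model_name: str = "facebook/bart-large-mnli",
                 hypothesis_template: str = DEFAULT_HYPOTHESIS_TEMPLATE):
        try:
            from transformers import pipeline
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "NliZeroShotBackend requires the 'nli' extra "
                "(pip install taxatalk[nli])"
            ) from exc
        self._pipe = pipeline("zero-shot-classification", model=model_name)
        self.hypothesis_template = hypothesis_template

    def score(self, text: str, labels: Iterable[str]) -> dict[str, float]:  # pragma: no cover
        labels = list(labels)
        res = self._pipe(text, labels, multi_label=True,
                         hypothesis_template=self.hypothesis_template)
        return dict(zip(res["labels"], res["scores"]))


def score_topics(title: str, inventory: TopicInventory, backend) -> dict[str, float]:
    """One score in [0, 1] per inventory label, via the backend."""
    scores = backend.score(title, sorted(inventory.labels))
    for label in sorted(inventory.labels):
        if label not in scores:
            raise RuntimeError(f"backend returned no score for label {label!r}")
        s = scores[label]
        if not 0.0 <= s <= 1.0:
            raise RuntimeError(f"backend score for {label!r} out of [0,1]: {s}")
    return {label: scores[label] for label in sorted(inventory.labels)}


# ---------------------------------------------------------------------------
# Decision rule and evaluation

@dataclass(frozen=True)
class RelevanceDecision:
    relevant: bool
    triggering_topics: frozenset[str]
    threshold: float = 0.5


def decide_relevance(
    scores: Mapping[str, float],
    inventory: TopicInventory,
    threshold: float = 0.5,
) -> RelevanceDecision:
    """Relevant iff any relevant-inventory topic scores strictly above threshold."""
    triggering = frozenset(t for t, s in scores.items() if s > threshold)
    return RelevanceDecision(
        relevant=bool(triggering & inventory.relevant),
        triggering_topics=triggering,
        threshold=threshold,
    )


@dataclass(frozen=True)
class FilterMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None
    npv: float | None


def evaluate_filter(
    decisions: Mapping[str, bool],
    gold_labels: Mapping[str, bool],
) -> FilterMetrics:
    """Confusion counts and precision/recall/F1/NPV against ground truth.

    Undefined ratios (zero denominators) are reported as ``None``, never 0.
    """
    if not decisions:
        raise ValueError("no decisions to evaluate")
    missing = set(decisions) - set(gold_labels)
    if missing:
        raise KeyError(f"no gold labels for ids: {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for aid, pred in decisions.items():
        gold = gold_labels[aid]
        if pred and gold:
            tp += 1
        elif pred and not gold:
            fp += 1
        elif not pred and gold:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    f1 = (2 * precision * recall / (precision + recall)
          if precision is not None and recall is not None and precision + recall > 0
          else None)
    npv = tn / (tn + fn) if tn + fn else None
    return FilterMetrics(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision,
                         recall=recall, f1=f1, npv=npv)
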