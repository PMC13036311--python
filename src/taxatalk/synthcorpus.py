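"""Seeded synthetic inputs with ground truth for every pipeline stage.

Two generators cover the pipeline's inputs end to end:

* :func:`gen_names` emits an IUCN-style species/common-name table built as
  modifier x head-noun clusters ({rock, forest} x "wallaby"), optionally
  planting head-noun conflations (the lion / sea-lion pattern) together
  with the edit script that severs them and the negative keywords the
  severed conflation should generate.

* :func:`gen_corpus` emits a dated article/post corpus with planted
  irrelevant items (taxon words used non-biologically: sports, politics,
  business), planted verbatim-or-perturbed syndicated copies inside a date
  window, piecewise-Poisson volumes with a planted mean shift, and planted
  sentiment signs injected into the taxon-mention sentences.  Article
  templates embed the cue words of the lexical mock zero-shot backend, so
  filter decisions are checkable against truth without any model download.

Everything is drawn from one ``random.Random(seed)``; identical seeds give
byte-identical corpora.  Defaults mirror the magnitudes the method targets
in the wild: biweekly bins over two years, a background rate of about 3
relevant articles per 2-week bin jumping to 20 after a planted break at the
midpoint, roughly half the retrieved items irrelevant, and roughly 40% of
articles syndicated copies.
"""

from __future__ import annotations

import datetime as dt
import random
from dataclasses import dataclass, field

from .records import ArticleRecord
from .taxonomy import (
    Edit, KeywordSet, Phrase, SpeciesRecord, name_set_node, phrase_str,
)

# ---------------------------------------------------------------------------
# Name generator vocabulary

HEAD_POOL = (
    "wallaby", "pangolin", "gorilla", "marmot", "tapir", "gibbon", "lemur",
    "otter", "badger", "serow", "duiker", "vole", "wombat", "numbat",
    "colugo", "quoll", "markhor", "saola", "dugong", "takin",
)

MODIFIER_POOL = (
    "rock", "forest", "mountain", "river", "desert", "golden", "dwarf",
    "giant", "spotted", "striped", "northern", "southern", "eastern",
    "western", "island", "crested", "banded", "silver", "red", "grey",
    "lesser", "greater", "pygmy", "highland", "lowland", "coastal",
    "sunda", "malayan", "andean", "cape",
)

#: Distinguishing first words for conflated (two-word) heads; disjoint from
#: MODIFIER_POOL so a base cluster can never accidentally list the
#: companion's head as one of its own names.
CONFLATION_WORDS = ("sea", "flying", "water", "ghost", "moon", "ant")

ORDER_POOL = ("Carnivora", "Chiroptera", "Rodentia", "Primates",
              "Diprotodontia", "Cetartiodactyla")


@dataclass
class SynthTruth:
    """Ground truth accompanying a synthetic world."""

    planted_taxa: dict[str, set[str]] = field(default_factory=dict)
    planted_species: dict[str, set[str]] = field(default_factory=dict)
    planted_edit_script: list[Edit] = field(default_factory=list)
    expected_negatives: dict[str, set[str]] = field(default_factory=dict)
    conflations: list[tuple[str, str]] = field(default_factory=list)
    planted_relevance: dict[str, bool] = field(default_factory=dict)
    planted_syndicates: dict[str, str] = field(default_factory=dict)
    planted_sentiment_sign: dict[str, int] = field(default_factory=dict)
    planted_topics: dict[str, set[str]] = field(default_factory=dict)
    planted_breaks: dict[str, tuple[int, float, float] | None] = field(default_factory=dict)
    start_date: dt.date | None = None
    n_bins: int = 0
    bin_days: int = 14


def gen_names(
    seed: int,
    n_clusters: int = 6,
    conflation_rate: float = 0.25,
    modifiers_per_cluster: tuple[int, int] = (2, 4),
) -> tuple[list[SpeciesRecord], SynthTruth]:
    """Species/common-name table with planted suffix clusters and conflations.

    Each cluster is a head noun plus modifier x head full names (the base
    cluster also lists the bare head, like *lion* itself).  With probability
    ``conflation_rate`` a cluster reuses an earlier single-word head behind a
    distinguishing word (*sea lion* after *lion*), planting exactly one
    cross-cluster subset edge, the edit that removes it, and the negative
    keywords the base taxon should acquire.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = random.Random(seed)
    heads = list(HEAD_POOL)
    rng.shuffle(heads)
    modifiers = list(MODIFIER_POOL)
    rng.shuffle(modifiers)
    conf_words = list(CONFLATION_WORDS)
    rng.shuffle(conf_words)

    truth = SynthTruth()
    species: list[SpeciesRecord] = []
    single_word_heads: list[Phrase] = []
    next_id = 1

    for c in range(n_clusters):
        conflate = (
            c > 0 and single_word_heads and conf_words
            and rng.random() < conflation_rate
        )
        if conflate:
            base = rng.choice(single_word_heads)
            head: Phrase = (conf_words.pop(), *base)
        else:
            head = (heads.pop(),)
            single_word_heads.append(head)
        k = rng.randint(*modifiers_per_cluster)
        mods = [modifiers.pop() for _ in range(min(k, len(modifiers)))]
        names: list[Phrase] = [(m, *head) for m in mods]
        if len(head) == 1:
            names.append(head)  # the bare head is itself a listed name
        label = phrase_str(head)
        order = ORDER_POOL[c % len(ORDER_POOL)]
        ids = set()
        for j, name in enumerate(names):
            tid = f"T{next_id:04d}"
            next_id += 1
            ids.add(tid)
            species.append(SpeciesRecord(
                taxon_id=tid,
                scientific_name=f"Synthetus {label.replace(' ', '')}i{j}",
                common_names=(name,),
                order_name=order,
            ))
        truth.planted_taxa[label] = {phrase_str(n) for n in names}
        truth.planted_species[label] = ids
        if conflate:
            base_label = phrase_str(base)
            truth.conflations.append((base_label, label))
            truth.planted_edit_script.append(
                Edit.remove_edge(name_set_node(label), name_set_node(base_label))
            )
            negs = truth.expected_negatives.setdefault(base_label, set())
            negs.add(label)
            negs.update(phrase_str(n) for n in names)
    return species, truth


# ---------------------------------------------------------------------------
# Corpus generator vocabulary

PLACES = (
    "Karamja", "Veldhaven", "Norpool", "Ashby Vale", "Tarn Hollow",
    "Quarrow", "Eastmere", "Bindura", "Loketo", "Sarnwick", "Dunmorra",
    "Kivalo", "Pemberton Flats", "Ruvima", "Oxhollow", "Jandara",
    "Morwich", "Talvora", "Greyfen", "Ubanda",
)

PEOPLE = (
    "Amara Ndiaye", "Tomas Velez", "Priya Raman", "Janek Kowal",
    "Lindiwe Dube", "Rafael Ortiz", "Mei Lin Chou", "Oskar Brandt",
    "Fatima Zahra", "Declan Murphy", "Yuki Tanaka", "Helena Voss",
    "Samuel Okafor", "Ingrid Halvorsen", "Mateo Silva", "Anya Petrova",
)

DOMAINS = (
    "dailyherald.example.com", "globewire.example.net", "metrotimes.example.org",
    "thecourier.example.com", "newsdesk.example.net", "regionpost.example.org",
    "morningledger.example.com", "stateobserver.example.net",
)

COUNTRIES = ("US", "GB", "AU", "ZA", "IN", "CA", "KE", "SG")

# (template, topic labels it cues) — cue words match relevance.DEFAULT_CUES.
RELEVANT_TITLES = (
    ("Conservation rangers report {kw} numbers rising near {place}",
     ("conservation",)),
    ("Wildlife survey finds {kw} herd expanding across {place}",
     ("wildlife",)),
    ("Researchers study virus found in {kw} droppings",
     ("science and technology", "health")),
    ("New nature reserve shelters {kw} habitat in {place}",
     ("nature", "conservation", "habitat loss")),
    ("Tourism surge as safari visitors seek the {kw} of {place}",
     ("tourism",)),
    ("Farmers adapt crops after {kw} sightings in {place}",
     ("agriculture",)),
    ("Climate shifts push {kw} range toward {place}, drought study warns",
     ("climate change", "science and technology")),
)

IRRELEVANT_TITLES = (
    ("{Kw} captain steers league match to a tense finish", ("sports",)),
    ("{Kw} Rovers clinch tournament opener in {place}", ("sports",)),
    ("{Kw} party gains ground in {place} election", ("politics",)),
    ("Shares of {Kw} Holdings jump after merger talks", ("business",)),
    ("{Kw} film premiere draws crowds in {place}", ("entertainment",)),
    ("New restaurant menu in {place} riffs on the {kw} name", ("food",)),
)

POSITIVE_MENTIONS = (
    "Local guides say the {kw} is thriving here and praised the wonderful recovery around {place}.",
    "Visitors love watching the {kw}, calling the sightings a great success for {place}.",
    "The {kw} population is flourishing, welcome news celebrated across {place}.",
)

NEGATIVE_MENTIONS = (
    "Officials report the {kw} suffered a tragic decline after disease killed dozens near {place}.",
    "Poaching has left the {kw} in crisis, a devastating loss for {place}.",
    "A grim survey warns the {kw} faces extinction as habitat destruction spreads in {place}.",
)

NEUTRAL_SENTENCES = (
    "The regional office released its quarterly field bulletin on Tuesday.",
    "Surveyors from {place} logged their counts along the northern transect.",
    "The briefing was attended by delegates from twelve districts.",
    "Field teams compiled their tallies before the end of the month.",
    "Correspondent {person} filed this dispatch from {place}.",
    "The committee will reconvene at its usual venue next quarter.",
    "Copies of the annex were circulated to the liaison offices.",
)

# Every original ends with these: the serial-unique codes act as the
# distinctive vocabulary real outlets contribute (bylines, datelines, ids),
# keeping distinct originals well below the syndication threshold while
# verbatim copies still match exactly.
TAG_SENTENCES = (
    "Reference file {code} was archived by the documentation unit.",
    "Dispatch {code2} was relayed to the bulletin desk overnight.",
)

IRRELEVANT_BODIES = (
    "The scoreboard at {place} read {code} at the final whistle. "
    "Supporters of the {kw} side streamed out after the league match. "
    "Coach {person} said the season schedule leaves little room to rest.",
    "Analysts at {place} tracked ticker {code} through the session. "
    "The {kw} brand gained ground after the merger briefing. "
    "Spokesperson {person} declined to discuss the shares further.",
    "Organisers in {place} confirmed booth {code} for the premiere. "
    "The {kw} film poster drew a long queue of onlookers. "
    "Producer {person} thanked the crew before the screening.",
)


def _fill(template: str, rng: random.Random, kw: str, uid: str,
          uid2: str = "") -> str:
    return template.format(
        kw=kw,
        Kw=kw.title(),
        place=rng.choice(PLACES),
        person=rng.choice(PEOPLE),
        code=uid,
        code2=uid2,
    )


def gen_corpus(
    seed: int,
    taxa: list[KeywordSet],
    n_bins: int = 52,
    bin_days: int = 14,
    base_mean: float = 3.0,
    break_spec: dict[str, tuple[int, float, float]] | None = None,
    syndication_rate: float = 0.4,
    irrelevance_rate: float = 0.5,
    perturbation: float = 0.0,
    window_days: int = 60,
    start_date: dt.date = dt.date(2019, 1, 1),
    source: str = "news",
) -> tuple[list[ArticleRecord], SynthTruth]:
    """Dated article corpus with planted relevance, syndication, sentiment, breaks.

    Per taxon and per bin, the number of relevant original articles is
    Poisson with the bin mean given by ``break_spec`` (default: the first
    taxon shifts ``base_mean`` -> 20 at the middle bin, the rest stay flat);
    irrelevant articles arrive at a rate making them the ``irrelevance_rate``
    fraction of original (non-syndicated) items in expectation, and each
    relevant original spawns syndicated
    copies (verbatim at ``perturbation`` 0, dated within ``window_days``) at
    a rate making copies the ``syndication_rate`` fraction of relevant
    articles.  Truth records every planted label.
    """
    for name, rate in (("syndication_rate", syndication_rate),
                       ("irrelevance_rate", irrelevance_rate)):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    if break_spec is None:
        break_spec = {}
        if taxa:
            break_spec[taxa[0].taxon_label] = (n_bins // 2, base_mean, 20.0)
    for label, (b, pre, post) in break_spec.items():
        if not 0 < b < n_bins:
            raise ValueError(f"break bin {b} for {label!r} outside series")

    rng = random.Random(seed)
    irr_factor = irrelevance_rate / (1.0 - irrelevance_rate)
    synd_factor = syndication_rate / (1.0 - syndication_rate)

    truth = SynthTruth(start_date=start_date, n_bins=n_bins, bin_days=bin_days)
    articles: list[ArticleRecord] = []
    serial = 0

    def _poisson(lam: float) -> int:
        # Knuth's method; lambdas here are small.
        L = pow(2.718281828459045, -lam)
        k, p = 0, 1.0
        while True:
            p *= rng.random()
            if p <= L:
                return k
            k += 1

    for ks in taxa:
        label = ks.taxon_label
        kw = label
        spec = break_spec.get(label)
        truth.planted_breaks[label] = spec
        for b in range(n_bins):
            if spec is not None:
                mean = spec[1] if b < spec[0] else spec[2]
            else:
                mean = base_mean
            bin_start = start_date + dt.timedelta(days=b * bin_days)
            n_rel = _poisson(mean)
            n_irr = _poisson(mean * irr_factor)
            bin_articles: list[ArticleRecord] = []
            for _ in range(n_rel):
                serial += 1
                aid = f"a{serial:06d}"
                uid, uid2 = f"rf{serial:06d}", f"dx{serial:06d}"
                sign = rng.choice((1, -1))
                title_tpl, topics = rng.choice(RELEVANT_TITLES)
                mention_tpl = rng.choice(
                    POSITIVE_MENTIONS if sign > 0 else NEGATIVE_MENTIONS)
                context = rng.sample(NEUTRAL_SENTENCES, rng.randint(2, 3))
                sentences = [_fill(s, rng, kw, uid) for s in context]
                sentences.insert(rng.randrange(1, len(sentences) + 1),
                                 _fill(mention_tpl, rng, kw, uid))
                sentences += [_fill(s, rng, kw, uid, uid2)
                              for s in TAG_SENTENCES]
                art = ArticleRecord(
                    article_id=aid,
                    title=_fill(title_tpl, rng, kw, uid),
                    url=f"https://{rng.choice(DOMAINS)}/{label.replace(' ', '-')}/{aid}",
                    domain=rng.choice(DOMAINS),
                    date=bin_start + dt.timedelta(days=rng.randrange(bin_days)),
                    country=rng.choice(COUNTRIES),
                    taxon_label=label,
                    body=" ".join(sentences),
                    source=source,
                )
                bin_articles.append(art)
                truth.planted_relevance[aid] = True
                truth.planted_sentiment_sign[aid] = sign
                truth.planted_topics[aid] = set(topics)
                # Syndicated copies of this original.
                for _c in range(_poisson(synd_factor)):
                    serial += 1
                    sid_ = f"a{serial:06d}"
                    lag = rng.randrange(1, max(2, window_days - bin_days))
                    body = art.body
                    if perturbation > 0 and rng.random() < perturbation:
                        body = body + " " + _fill(
                            rng.choice(NEUTRAL_SENTENCES), rng, kw,
                            f"px{rng.randrange(10**6):06d}")
                    copy = ArticleRecord(
                        article_id=sid_,
                        title=art.title,
                        url=f"https://{rng.choice(DOMAINS)}/wire/{sid_}",
                        domain=rng.choice(DOMAINS),
                        date=art.date + dt.timedelta(days=lag),
                        country=rng.choice(COUNTRIES),
                        taxon_label=label,
                        body=body,
                        source=source,
                    )
                    bin_articles.append(copy)
                    truth.planted_relevance[sid_] = True
                    truth.planted_sentiment_sign[sid_] = sign
                    truth.planted_topics[sid_] = set(topics)
                    truth.planted_syndicates[sid_] = aid
            for _ in range(n_irr):
                serial += 1
                aid = f"a{serial:06d}"
                uid = f"x{serial:06d}"
                title_tpl, topics = rng.choice(IRRELEVANT_TITLES)
                art = ArticleRecord(
                    article_id=aid,
                    title=_fill(title_tpl, rng, kw, uid),
                    url=f"https://{rng.choice(DOMAINS)}/{label.replace(' ', '-')}/{aid}",
                    domain=rng.choice(DOMAINS),
                    date=bin_start + dt.timedelta(days=rng.randrange(bin_days)),
                    country=rng.choice(COUNTRIES),
                    taxon_label=label,
                    body=_fill(rng.choice(IRRELEVANT_BODIES), rng, kw, uid),
                    source=source,
                )
                bin_articles.append(art)
                truth.planted_relevance[aid] = False
                truth.planted_topics[aid] = set(topics)
            articles.extend(bin_articles)
    articles.sort(key=lambda a: (a.date, a.url))
    return articles, truth
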