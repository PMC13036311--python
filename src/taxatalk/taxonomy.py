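"""Folk-taxonomy derivation from species common names.

Everyday ("folk") groupings of organisms — *bat*, *sea lion*, *wallaby* —
rarely coincide with Linnaean taxa, but they do leave a structural trace in
common names: names of species the public perceives as similar tend to share
their trailing words.  This module exploits that trace.  It extracts every
longest shared word-ending from pairs of common names, treats each unique
ending as a candidate folk taxon (the set of all full names ending with it),
organizes the candidates into a subset hierarchy (Hasse diagram), joins
species and name sets into an undirected graph whose connected components are
top-level candidate taxa, applies a declarative expert edit script to sever
conflations (e.g. *sea lion* vs. *lion*), and finally derives search keyword
sets with negative terms for the conflations that were severed.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: A phrase is an ordered tuple of lowercase word tokens.
Phrase = tuple[str, ...]

_PUNCT_KEEP_HYPHEN = str.maketrans("", "", "".join(
    c for c in "!\"#$%&'()*+,./:;<=>?@[\\]^_`{|}~’‘“”"
))


def normalize_name(raw: str) -> Phrase:
    """Normalize a raw common name into a :data:`Phrase`.

    Lowercases, drops punctuation (apostrophes included), splits hyphens into
    separate words, and collapses whitespace.  Raises ``ValueError`` if
    nothing survives; callers ingesting tables should catch this and drop the
    record with a logged warning.
    """
    text = raw.lower().replace("-", " ").replace("‐", " ").translate(_PUNCT_KEEP_HYPHEN)
    words = tuple(w for w in text.split() if w)
    if not words:
        raise ValueError(f"name {raw!r} is empty after normalization")
    return words


def phrase_str(p: Phrase) -> str:
    return " ".join(p)


def shared_ending(a: Phrase, b: Phrase) -> Phrase:
    """Longest contiguous run of words shared at the end of both phrases.

    Word-level, never character-level: ``("mountain","lion")`` and
    ``("sea","lion")`` share ``("lion",)``; *bat* shares nothing with *cat*.
    Returns the empty tuple when the last words differ.
    """
    n = 0
    while n < len(a) and n < len(b) and a[-1 - n] == b[-1 - n]:
        n += 1
    return a[len(a) - n:] if n else ()


def is_word_suffix(suffix: Phrase, phrase: Phrase) -> bool:
    """True if ``phrase`` ends, word-wise, with ``suffix``."""
    if not suffix or len(suffix) > len(phrase):
        return False
    return phrase[len(phrase) - len(suffix):] == tuple(suffix)


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with its (normalized) English common names."""

    taxon_id: str
    scientific_name: str
    common_names: tuple[Phrase, ...]
    order_name: str = ""


@dataclass(frozen=True)
class TaxonCandidate:
    """A prospective folk taxon: a shared name ending and everything it covers.

    ``aliases`` holds longer endings whose member set coincided exactly with
    this one; the shortest ending is kept as the canonical label.
    """

    ending: Phrase
    member_names: frozenset[Phrase]
    member_species: frozenset[str]
    aliases: frozenset[Phrase] = frozenset()

    def __post_init__(self) -> None:
        for name in self.member_names:
            if not (name == self.ending or is_word_suffix(self.ending, name)):
                raise ValueError(
                    f"member {phrase_str(name)!r} does not end with "
                    f"{phrase_str(self.ending)!r}"
                )


def _ending_sort_key(e: Phrase) -> tuple[int, int, Phrase]:
    return (len(e), len(phrase_str(e)), e)


def build_candidates(
    names: Iterable[Phrase],
    listings: Mapping[Phrase, Iterable[str]],
) -> dict[Phrase, TaxonCandidate]:
    """Candidate folk taxa from every pairwise shared ending plus every full name.

    One candidate per unique non-empty ending; its members are *all* input
    names ending with that phrase (not just the generating pair).  Candidates
    whose member sets coincide are merged, keeping the shortest ending as
    canonical and recording longer ones as aliases — identical sets carry no
    hierarchy information and would create degenerate Hasse edges.
    """
    names = sorted(set(names))
    endings: set[Phrase] = set(names)
    # Pairs sharing no last word contribute nothing; bucket by last word so
    # the pass over pairs stays near-linear on realistic name tables.
    by_last: dict[str, list[Phrase]] = defaultdict(list)
    for n in names:
        by_last[n[-1]].append(n)
    for bucket in by_last.values():
        for i, a in enumerate(bucket):
            for b in bucket[i + 1:]:
                e = shared_ending(a, b)
                if e:
                    endings.add(e)

    member_map: dict[Phrase, frozenset[Phrase]] = {
        e: frozenset(n for n in by_last.get(e[-1], ()) if is_word_suffix(e, n))
        for e in endings
    }

    by_members: dict[frozenset[Phrase], list[Phrase]] = defaultdict(list)
    for e, members in member_map.items():
        by_members[members].append(e)

    out: dict[Phrase, TaxonCandidate] = {}
    for members, es in by_members.items():
        es.sort(key=_ending_sort_key)
        canonical, aliases = es[0], es[1:]
        species = frozenset(
            sp for n in members for sp in listings.get(n, ())
        )
        out[canonical] = TaxonCandidate(
            ending=canonical,
            member_names=members,
            member_species=species,
            aliases=frozenset(aliases),
        )
    return out


def canonical_ending_map(candidates: Mapping[Phrase, TaxonCandidate]) -> dict[Phrase, Phrase]:
    """Map every ending (canonical or alias) to its canonical ending."""
    out: dict[Phrase, Phrase] = {}
    for e, cand in candidates.items():
        out[e] = e
        for a in cand.aliases:
            out[a] = e
    return out


def immediate_subset_edges(
    candidates: Mapping[Phrase, TaxonCandidate],
) -> set[tuple[Phrase, Phrase]]:
    """Hasse diagram of the strict-subset order on candidate member sets.

    Emits ``(child, parent)`` iff child's members are a strict subset of
    parent's and no third candidate sits strictly between them — i.e. the
    transitive reduction of the subset partial order.
    """
    items = sorted(candidates.items())
    sets = {e: c.member_names for e, c in items}
    edges: set[tuple[Phrase, Phrase]] = set()
    for a, sa in sets.items():
        for b, sb in sets.items():
            if a == b or not (sa < sb):
                continue
            if any(
                sa < sc < sb
                for c, sc in sets.items()
                if c != a and c != b
            ):
                continue
            edges.add((a, b))
    return edges


SPECIES = "species"
NAME_SET = "name_set"
LISTING = "listing"
SUBSET = "subset"
MERGE = "merge"

#: Graph nodes are ``(kind, id)`` pairs; for name sets the id is the
#: space-joined canonical ending.
Node = tuple[str, str]


def species_node(taxon_id: str) -> Node:
    return (SPECIES, taxon_id)


def name_set_node(ending: Phrase | str) -> Node:
    return (NAME_SET, ending if isinstance(ending, str) else phrase_str(ending))


def build_graph(
    species: Sequence[SpeciesRecord],
    candidates: Mapping[Phrase, TaxonCandidate],
    hasse: Iterable[tuple[Phrase, Phrase]],
) -> nx.Graph:
    """Undirected graph of species and name-set nodes.

    Listing edges join each species to the candidate holding each of its full
    names; subset edges realize the Hasse pairs, carrying a ``child``
    attribute so the superset direction remains recoverable from the
    undirected graph.
    """
    canon = canonical_ending_map(candidates)
    g = nx.Graph()
    for e, cand in sorted(candidates.items()):
        g.add_node(
            name_set_node(e),
            kind=NAME_SET,
            ending=phrase_str(e),
            members=sorted(phrase_str(m) for m in cand.member_names),
            aliases=sorted(phrase_str(a) for a in cand.aliases),
        )
    for rec in species:
        g.add_node(species_node(rec.taxon_id), kind=SPECIES,
                   scientific_name=rec.scientific_name, order=rec.order_name)
        for name in rec.common_names:
            if name not in canon:
                raise ValueError(
                    f"species {rec.taxon_id} lists {phrase_str(name)!r} "
                    "with no matching candidate"
                )
            g.add_edge(species_node(rec.taxon_id), name_set_node(canon[name]),
                       kind=LISTING)
    for child, parent in sorted(hasse):
        g.add_edge(name_set_node(child), name_set_node(parent), kind=SUBSET,
                   child=name_set_node(child))
    return g


def components(graph: nx.Graph) -> dict[Node, frozenset[Node]]:
    """Connected components, each labeled by its smallest node id."""
    out: dict[Node, frozenset[Node]] = {}
    for comp in nx.connected_components(graph):
        label = min(comp)
        out[label] = frozenset(comp)
    return out


# ---------------------------------------------------------------------------
# Expert edit scripts

@dataclass(frozen=True)
class Edit:
    """One reviewed edit: remove_edge, remove_node, merge, or select_taxon."""

    op: str
    a: Node | None = None
    b: Node | None = None
    node: Node | None = None
    label: str = ""

    @staticmethod
    def remove_edge(a: Node, b: Node) -> "Edit":
        return Edit(op="remove_edge", a=a, b=b)

    @staticmethod
    def remove_node(node: Node) -> "Edit":
        return Edit(op="remove_node", node=node)

    @staticmethod
    def merge(a: Node, b: Node) -> "Edit":
        return Edit(op="merge", a=a, b=b)

    @staticmethod
    def select_taxon(node: Node, label: str) -> "Edit":
        return Edit(op="select_taxon", node=node, label=label)


EditScript = Sequence[Edit]


def apply_edits(graph: nx.Graph, edits: EditScript) -> nx.Graph:
    """Apply a reviewed edit script in order; returns an edited copy.

    Edits model the human review step as a versioned, replayable artifact.
    A dangling reference is a hard error naming the offending edit index.
    ``merge`` joins two components by adding a synthetic name-set node
    connected to each component's label node; removals only affect
    connectivity, never species records.
    """
    g = graph.copy()
    g.graph.setdefault("selected", {})
    for i, edit in enumerate(edits):
        if edit.op == "remove_edge":
            if not g.has_edge(edit.a, edit.b):
                raise KeyError(f"edit {i}: no edge {edit.a} -- {edit.b}")
            g.remove_edge(edit.a, edit.b)
        elif edit.op == "remove_node":
            if edit.node not in g:
                raise KeyError(f"edit {i}: no node {edit.node}")
            if g.nodes[edit.node].get("kind") == SPECIES:
                raise ValueError(f"edit {i}: species nodes cannot be removed")
            g.remove_node(edit.node)
        elif edit.op == "merge":
            comps = components(g)
            for lbl in (edit.a, edit.b):
                if lbl not in comps:
                    raise KeyError(f"edit {i}: no component labeled {lbl}")
            merged = name_set_node(f"merged:{edit.a[1]}+{edit.b[1]}")
            g.add_node(merged, kind=NAME_SET, ending="", members=[], aliases=[],
                       synthetic=True)
            g.add_edge(merged, edit.a, kind=MERGE)
            g.add_edge(merged, edit.b, kind=MERGE)
        elif edit.op == "select_taxon":
            if edit.node not in g:
                raise KeyError(f"edit {i}: no node {edit.node}")
            g.graph["selected"][edit.node] = edit.label
        else:
            raise ValueError(f"edit {i}: unknown op {edit.op!r}")
    return g


# ---------------------------------------------------------------------------
# Keyword derivation

@dataclass(frozen=True)
class KeywordSet:
    """Search keywords for one folk taxon.

    At least one positive must be present in a search result; every negative
    must be absent.  Negatives carry the positives as proper word-suffixes by
    construction (e.g. *lion* NOT *sea lion*).
    """

    taxon_label: str
    positives: frozenset[Phrase]
    negatives: frozenset[Phrase] = frozenset()

    def __post_init__(self) -> None:
        if not self.positives:
            raise ValueError("positives must be non-empty")
        if self.positives & self.negatives:
            raise ValueError("a phrase cannot be both positive and negative")

    def to_json_dict(self) -> dict:
        return {
            "taxon_label": self.taxon_label,
            "positives": sorted(phrase_str(p) for p in self.positives),
            "negatives": sorted(phrase_str(n) for n in self.negatives),
        }

    @staticmethod
    def from_json_dict(d: dict) -> "KeywordSet":
        return KeywordSet(
            taxon_label=d["taxon_label"],
            positives=frozenset(tuple(p.split()) for p in d["positives"]),
            negatives=frozenset(tuple(n.split()) for n in d["negatives"]),
        )


def _subset_descendants(graph: nx.Graph, selected: Node) -> set[Node]:
    """Name-set nodes below ``selected`` in the subset hierarchy (selected excluded)."""
    seen = {selected}
    frontier = [selected]
    while frontier:
        node = frontier.pop()
        for nbr in graph.neighbors(node):
            data = graph.edges[node, nbr]
            if data.get("kind") == SUBSET and data.get("child") == nbr and nbr not in seen:
                seen.add(nbr)
                frontier.append(nbr)
    seen.discard(selected)
    return seen


def derive_keywords(
    graph: nx.Graph,
    selected: Node,
    all_endings: Iterable[Phrase],
    taxon_label: str | None = None,
) -> KeywordSet:
    """Keyword set for a selected name-set node of the (edited) graph.

    Positives: the node's own ending plus the endings of every name-set node
    below it in the subset hierarchy within its current component.  Negatives:
    every ending of the *pre-edit* global inventory of which the selected
    ending is a proper word-suffix and whose node no longer shares a component
    with the selection — exactly the conflations the edit script severed.
    """
    if selected not in graph:
        raise KeyError(f"no node {selected}")
    comp = nx.node_connected_component(graph, selected)
    sel_ending = tuple(graph.nodes[selected]["ending"].split())
    positives = {sel_ending}
    for node in _subset_descendants(graph, selected):
        if node in comp:
            positives.add(tuple(graph.nodes[node]["ending"].split()))
    negatives = set()
    for e in all_endings:
        e = tuple(e)
        if e != sel_ending and is_word_suffix(sel_ending, e) and len(e) > len(sel_ending):
            node = name_set_node(e)
            if node not in graph or node not in comp:
                negatives.add(e)
    negatives -= positives
    return KeywordSet(
        taxon_label=taxon_label or phrase_str(sel_ending),
        positives=frozenset(positives),
        negatives=frozenset(negatives),
    )


# ---------------------------------------------------------------------------
# Convenience pipeline + serialization

def build_taxonomy(
    species: Sequence[SpeciesRecord],
) -> tuple[nx.Graph, dict[Phrase, TaxonCandidate]]:
    """Full automatic stage: candidates, Hasse edges, graph (pre-edit)."""
    usable = [r for r in species if r.common_names]
    skipped = len(species) - len(usable)
    if skipped:
        logger.warning("skipped %d species without common names", skipped)
    listings: dict[Phrase, set[str]] = defaultdict(set)
    for rec in usable:
        for name in rec.common_names:
            listings[name].add(rec.taxon_id)
    candidates = build_candidates(listings.keys(), listings)
    hasse = immediate_subset_edges(candidates)
    graph = build_graph(usable, candidates, hasse)
    return graph, candidates


def graph_to_json(graph: nx.Graph) -> str:
    """Deterministic JSON node/edge-list serialization."""
    nodes = [
        {"id": list(n), **{k: v for k, v in sorted(graph.nodes[n].items())}}
        for n in sorted(graph.nodes)
    ]
    edges = [
        {
            "a": list(a), "b": list(b),
            **{k: (list(v) if isinstance(v, tuple) else v)
               for k, v in sorted(graph.edges[a, b].items())},
        }
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges)
    ]
    return json.dumps({"nodes": nodes, "edges": edges}, indent=1, sort_keys=False)
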