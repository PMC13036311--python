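"""Folk-taxonomy derivation: endings, candidates, hierarchy, edits, keywords."""

import itertools
import random

import networkx as nx
import pytest

import taxatalk as tt
from taxatalk.taxonomy import (
    Edit, NAME_SET, SPECIES, name_set_node, species_node,
)


def p(s: str) -> tuple:
    return tuple(s.split())


# ---------------------------------------------------------------------------
# normalize_name / shared_ending

@pytest.mark.parametrize("raw,expected", [
    ("South American Sea Lion", ("south", "american", "sea", "lion")),
    ("Long-tongued Bat", ("long", "tongued", "bat")),
    ("  Gorilla ", ("gorilla",)),
    ("Geoffroy's Cat", ("geoffroys", "cat")),
])
def test_normalize_name(raw, expected):
    assert tt.normalize_name(raw) == expected


def test_normalize_name_rejects_empty():
    with pytest.raises(ValueError):
        tt.normalize_name(" -- ")


@pytest.mark.parametrize("a,b,expected", [
    ("south american sea lion", "californian sea lion", "sea lion"),
    ("mountain lion", "sea lion", "lion"),
    ("pangolin", "gorilla", ""),
    ("flying fox", "fox", "fox"),
])
def test_shared_ending_examples(a, b, expected):
    assert tt.shared_ending(p(a), p(b)) == p(expected)
    assert tt.shared_ending(p(b), p(a)) == p(expected)


def test_shared_ending_identity():
    for s in ("lion", "greater horseshoe bat"):
        assert tt.shared_ending(p(s), p(s)) == p(s)


def _dp_suffix_oracle(a: tuple, b: tuple) -> tuple:
    """Word-level longest-common-substring DP, keeping only matches that
    terminate at the end of both sequences."""
    best = 0
    table = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                table[i][j] = table[i - 1][j - 1] + 1
                if i == len(a) and j == len(b):
                    best = table[i][j]
    return a[len(a) - best:] if best else ()


def test_shared_ending_matches_dp_oracle_on_random_pairs():
    rng = random.Random(7)
    words = ["bat", "lion", "sea", "fox", "horseshoe", "greater", "lesser",
             "long", "tongued", "mountain", "flying", "vampire"]
    for _ in range(1000):
        a = tuple(rng.choices(words, k=rng.randint(1, 5)))
        b = tuple(rng.choices(words, k=rng.randint(1, 5)))
        assert tt.shared_ending(a, b) == _dp_suffix_oracle(a, b)


def test_word_suffix_is_whole_word():
    from taxatalk.taxonomy import is_word_suffix
    assert is_word_suffix(p("fox"), p("flying fox"))
    assert not is_word_suffix(p("at"), p("bat"))
    assert not is_word_suffix(p("sea lion"), p("lion"))


# ---------------------------------------------------------------------------
# build_candidates

def test_build_candidates_three_name_example():
    names = {p("south american sea lion"), p("californian sea lion"),
             p("mountain lion")}
    cands = tt.build_candidates(names, {n: {f"S{i}"} for i, n in enumerate(sorted(names))})
    by_ending = {tt.phrase_str(e): c for e, c in cands.items()}
    assert set(by_ending) == {
        "sea lion", "lion", "south american sea lion",
        "californian sea lion", "mountain lion",
    }
    assert len(by_ending["sea lion"].member_names) == 2
    assert len(by_ending["lion"].member_names) == 3
    for c in cands.values():
        for m in c.member_names:
            assert m == c.ending or tt.shared_ending(m, c.ending) == c.ending


def test_build_candidates_single_name():
    cands = tt.build_candidates({p("gorilla")}, {p("gorilla"): {"T1"}})
    assert set(cands) == {p("gorilla")}
    assert cands[p("gorilla")].member_species == {"T1"}


def test_build_candidates_disjoint_last_words():
    names = {p("pangolin"), p("gorilla")}
    cands = tt.build_candidates(names, {n: set() for n in names})
    assert set(cands) == names


def test_build_candidates_member_sets_unique_per_ending():
    # Distinct endings carry distinct member sets: a pair generating ending e
    # differs in the word just before e, so no longer ending can cover the
    # same names.  The alias slot therefore stays empty on generated inputs.
    rng = random.Random(13)
    words = ["sea", "lion", "bat", "rock", "forest", "big", "cat"]
    for _ in range(50):
        names = {tuple(rng.choices(words, k=rng.randint(1, 4)))
                 for _ in range(rng.randint(1, 10))}
        cands = tt.build_candidates(names, {n: set() for n in names})
        member_sets = [c.member_names for c in cands.values()]
        assert len(member_sets) == len(set(member_sets))
        assert all(c.aliases == frozenset() for c in cands.values())


# ---------------------------------------------------------------------------
# immediate_subset_edges

def _mk_candidates(sets: dict[str, set[str]]):
    return {
        p(e): tt.TaxonCandidate(
            ending=p(e),
            member_names=frozenset(p(e) if m == e else (m, *p(e)) for m in ms),
            member_species=frozenset(),
        )
        for e, ms in sets.items()
    }


def test_hasse_chain_skips_transitive_edge():
    cands = {
        p("a b c"): tt.TaxonCandidate(p("a b c"), frozenset({p("a b c")}), frozenset()),
        p("b c"): tt.TaxonCandidate(p("b c"), frozenset({p("a b c"), p("x b c")}), frozenset()),
        p("c"): tt.TaxonCandidate(p("c"), frozenset({p("a b c"), p("x b c"), p("y c")}), frozenset()),
    }
    edges = tt.immediate_subset_edges(cands)
    assert (p("a b c"), p("b c")) in edges
    assert (p("b c"), p("c")) in edges
    assert (p("a b c"), p("c")) not in edges


def test_hasse_disjoint_sets_no_edges():
    cands = {
        p("a"): tt.TaxonCandidate(p("a"), frozenset({p("x a")}), frozenset()),
        p("b"): tt.TaxonCandidate(p("b"), frozenset({p("y b")}), frozenset()),
    }
    assert tt.immediate_subset_edges(cands) == set()


def _brute_force_reduction(sets):
    """O(n^3) triple-loop transitive reduction of the strict-subset order."""
    keys = list(sets)
    edges = set()
    for a in keys:
        for b in keys:
            if a != b and sets[a] < sets[b]:
                if not any(sets[a] < sets[c] < sets[b]
                           for c in keys if c not in (a, b)):
                    edges.add((a, b))
    return edges


def test_hasse_matches_brute_force_on_random_instances():
    rng = random.Random(3)
    for _ in range(60):
        n = rng.randint(1, 12)
        universe = list(range(10))
        member_sets = {}
        used = set()
        for i in range(n):
            s = frozenset(rng.sample(universe, rng.randint(1, 8)))
            if s in used:
                continue
            used.add(s)
            member_sets[(f"e{i}",)] = s
        cands = {
            e: tt.TaxonCandidate(
                e, frozenset((str(x), *e) for x in s), frozenset())
            for e, s in member_sets.items()
        }
        got = tt.immediate_subset_edges(cands)
        want = _brute_force_reduction(
            {e: cands[e].member_names for e in cands})
        assert got == want


# ---------------------------------------------------------------------------
# graph, components, edits

def test_build_graph_single_species():
    rec = tt.SpeciesRecord("T1", "Gorilla gorilla", (p("gorilla"),))
    g, cands = tt.build_taxonomy([rec])
    assert g.number_of_nodes() == 2
    assert g.number_of_edges() == 1
    assert tt.components(g) == {
        min(g.nodes): frozenset(g.nodes),
    }


def test_shared_name_links_species(sea_lion_species):
    dassie = tt.SpeciesRecord("T5", "Procavia capensis",
                              (p("dassie"), p("rock hyrax")))
    hyrax = tt.SpeciesRecord("T6", "Heterohyrax brucei", (p("rock hyrax"),))
    g, _ = tt.build_taxonomy([dassie, hyrax])
    comps = tt.components(g)
    assert len(comps) == 1  # linked through the shared listing


def test_carnivora_toy_one_component_then_three(sea_lion_species):
    g, cands = tt.build_taxonomy(sea_lion_species)
    assert len(tt.components(g)) == 1
    edits = [
        Edit.remove_edge(name_set_node("sea lion"), name_set_node("lion")),
        Edit.remove_edge(name_set_node("mountain lion"), name_set_node("lion")),
    ]
    g2 = tt.apply_edits(g, edits)
    assert len(tt.components(g2)) == 3
    # original graph untouched
    assert len(tt.components(g)) == 1


def test_apply_edits_empty_script_is_identity(sea_lion_species):
    g, _ = tt.build_taxonomy(sea_lion_species)
    g2 = tt.apply_edits(g, [])
    assert set(g.nodes) == set(g2.nodes) and set(g.edges) == set(g2.edges)


def test_apply_edits_dangling_reference_names_index(sea_lion_species):
    g, _ = tt.build_taxonomy(sea_lion_species)
    with pytest.raises(KeyError, match="edit 0"):
        tt.apply_edits(g, [Edit.remove_edge(name_set_node("x"), name_set_node("y"))])


def test_merge_joins_components():
    wood = tt.SpeciesRecord("T1", "Marmota monax", (p("woodchuck"),))
    marm = tt.SpeciesRecord("T2", "Marmota marmota", (p("alpine marmot"),))
    g, _ = tt.build_taxonomy([wood, marm])
    comps = tt.components(g)
    assert len(comps) == 2
    labels = sorted(comps)
    g2 = tt.apply_edits(g, [Edit.merge(labels[0], labels[1])])
    assert len(tt.components(g2)) == 1


def test_species_nodes_cannot_be_removed(sea_lion_species):
    g, _ = tt.build_taxonomy(sea_lion_species)
    with pytest.raises(ValueError):
        tt.apply_edits(g, [Edit.remove_node(species_node("T1"))])


def _union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return {min(g): frozenset(g) for g in groups.values()}


def test_components_match_union_find_on_random_graphs():
    rng = random.Random(11)
    for _ in range(40):
        n = rng.randint(1, 200)
        g = nx.gnm_random_graph(n, rng.randint(0, 2 * n), seed=rng.randint(0, 10**6))
        got = tt.components(g)
        want = _union_find_components(list(g.nodes), list(g.edges))
        assert got == want


def test_components_empty_graph():
    assert tt.components(nx.Graph()) == {}


# ---------------------------------------------------------------------------
# keywords

def test_lion_keywords_after_pruning(sea_lion_species):
    g, cands = tt.build_taxonomy(sea_lion_species)
    g2 = tt.apply_edits(g, [
        Edit.remove_edge(name_set_node("sea lion"), name_set_node("lion")),
        Edit.remove_edge(name_set_node("mountain lion"), name_set_node("lion")),
    ])
    ks = tt.derive_keywords(g2, name_set_node("lion"), list(cands))
    assert p("lion") in ks.positives
    negs = {tt.phrase_str(n) for n in ks.negatives}
    assert {"mountain lion", "sea lion"} <= negs
    # positives and negatives never overlap, and every negative extends a positive
    assert not ks.positives & ks.negatives
    for n in ks.negatives:
        assert any(tt.shared_ending(n, pos) == pos for pos in ks.positives)


def test_keywords_without_conflation_have_no_negatives():
    recs = [tt.SpeciesRecord("T1", "S p", (p("rock wallaby"),)),
            tt.SpeciesRecord("T2", "S q", (p("forest wallaby"),))]
    g, cands = tt.build_taxonomy(recs)
    ks = tt.derive_keywords(g, name_set_node("wallaby"), list(cands))
    assert ks.negatives == frozenset()
    assert {tt.phrase_str(x) for x in ks.positives} == {
        "wallaby", "rock wallaby", "forest wallaby"}


def test_bear_node_removal_gives_individual_taxa():
    recs = [tt.SpeciesRecord(f"T{i}", f"Ursus {i}", (p(n),))
            for i, n in enumerate(["black bear", "polar bear", "sloth bear"])]
    g, cands = tt.build_taxonomy(recs)
    g2 = tt.apply_edits(g, [Edit.remove_node(name_set_node("bear"))])
    assert len(tt.components(g2)) == 3
    for name in ("black bear", "polar bear", "sloth bear"):
        ks = tt.derive_keywords(g2, name_set_node(name), list(cands))
        assert p(name) in ks.positives
        assert ks.negatives == frozenset()


def test_keyword_matching_excludes_pruned_sibling_names(sea_lion_species):
    """Matching semantics: no member name of a pruned-away taxon matches."""
    g, cands = tt.build_taxonomy(sea_lion_species)
    g2 = tt.apply_edits(g, [
        Edit.remove_edge(name_set_node("sea lion"), name_set_node("lion")),
        Edit.remove_edge(name_set_node("mountain lion"), name_set_node("lion")),
    ])
    ks = tt.derive_keywords(g2, name_set_node("lion"), list(cands))
    for sibling in ("south american sea lion", "californian sea lion",
                    "mountain lion"):
        res = tt.match_keywords(f"A {sibling} was seen.", ks)
        assert res.matches == ()
    assert tt.match_keywords("A lion was seen.", ks).matches


def test_graph_serialization_deterministic(sea_lion_species):
    g1, _ = tt.build_taxonomy(sea_lion_species)
    g2, _ = tt.build_taxonomy(list(sea_lion_species))
    assert tt.graph_to_json(g1) == tt.graph_to_json(g2)


def test_subset_edges_form_dag(sea_lion_species):
    g, cands = tt.build_taxonomy(sea_lion_species)
    dag = nx.DiGraph()
    for a, b, data in g.edges(data=True):
        if data.get("kind") == "subset":
            child = data["child"]
            parent = b if child == a else a
            dag.add_edge(child, parent)
    assert nx.is_directed_acyclic_graph(dag)
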