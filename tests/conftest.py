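import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import taxatalk as tt

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SEA_LION_NAMES = [
    "South American sea lion", "Californian sea lion", "mountain lion",
]


@pytest.fixture(scope="session")
def sea_lion_species():
    """The four-species Carnivora toy: two sea lions, the mountain lion, the lion."""
    raw = [
        ("T1", "Otaria flavescens", "South American sea lion"),
        ("T2", "Zalophus californianus", "Californian sea lion"),
        ("T3", "Puma concolor", "mountain lion"),
        ("T4", "Panthera leo", "lion"),
    ]
    return [
        tt.SpeciesRecord(tid, sci, (tt.normalize_name(name),), "Carnivora")
        for tid, sci, name in raw
    ]


@pytest.fixture(scope="session")
def synthetic_world():
    """Seeded synthetic world: names, taxonomy, keywords, corpus, truth."""
    species, name_truth = tt.gen_names(42)
    graph, candidates = tt.build_taxonomy(species)
    edited = tt.apply_edits(graph, name_truth.planted_edit_script)
    taxa = [
        tt.derive_keywords(edited, ("name_set", label), list(candidates),
                           taxon_label=label)
        for label in sorted(name_truth.planted_taxa)
    ]
    articles, corpus_truth = tt.gen_corpus(42, taxa)
    return {
        "species": species,
        "name_truth": name_truth,
        "graph": graph,
        "edited": edited,
        "candidates": candidates,
        "taxa": taxa,
        "articles": articles,
        "corpus_truth": corpus_truth,
    }
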