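"""Derive folk taxa from common names: the sea-lion/lion conflation.

Builds the name-ending graph for four Carnivora species, shows the
conflation created by the shared ending *lion*, severs it with an edit
script, and derives search keywords with negative terms.
"""

import taxatalk as tt
from taxatalk.taxonomy import Edit, name_set_node

species = [
    tt.SpeciesRecord("T1", "Otaria flavescens",
                     (tt.normalize_name("South American sea lion"),), "Carnivora"),
    tt.SpeciesRecord("T2", "Zalophus californianus",
                     (tt.normalize_name("Californian sea lion"),), "Carnivora"),
    tt.SpeciesRecord("T3", "Puma concolor",
                     (tt.normalize_name("mountain lion"),), "Carnivora"),
    tt.SpeciesRecord("T4", "Panthera leo",
                     (tt.normalize_name("lion"),), "Carnivora"),
]

graph, candidates = tt.build_taxonomy(species)
print("candidate folk taxa (ending: members):")
for ending, cand in sorted(candidates.items()):
    print(f"  {tt.phrase_str(ending)}: "
          f"{sorted(tt.phrase_str(m) for m in cand.member_names)}")
print(f"components before review: {len(tt.components(graph))}")

# Expert review: sea lions and mountain lions are not "lions" to the public.
edits = [
    Edit.remove_edge(name_set_node("sea lion"), name_set_node("lion")),
    Edit.remove_edge(name_set_node("mountain lion"), name_set_node("lion")),
]
edited = tt.apply_edits(graph, edits)
print(f"components after pruning:  {len(tt.components(edited))}")

for label in ("lion", "sea lion"):
    ks = tt.derive_keywords(edited, name_set_node(label), list(candidates))
    print(f"keywords[{label}]: positives="
          f"{sorted(map(tt.phrase_str, ks.positives))} "
          f"negatives={sorted(map(tt.phrase_str, ks.negatives))}")

# The negatives guarantee a search for "lion" never matches a pruned sibling:
ks = tt.derive_keywords(edited, name_set_node("lion"), list(candidates))
for text in ("A sea lion surfaced offshore", "The lion pride rested"):
    hits = tt.match_keywords(text, ks).matches
    print(f"match({text!r}) -> {len(hits)} hit(s)")
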