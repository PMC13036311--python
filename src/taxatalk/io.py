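"""Reading and writing the pipeline's table and config formats.

Species/common-name tables arrive as UTF-8 CSV with one row per name
(columns: taxon_id, scientific_name, common_name, order_name); edit scripts
and keyword sets travel as JSON so the expert-review step is a versioned,
replayable file rather than an interactive session.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from .taxonomy import (
    Edit, KeywordSet, SpeciesRecord, normalize_name,
)

logger = logging.getLogger(__name__)


def read_species_csv(path) -> list[SpeciesRecord]:
    """Load a species/common-name table, one row per (species, name).

    Names failing normalization are dropped with a warning; species ending
    up with no usable common name are kept (the taxonomy builder skips and
    counts them).
    """
    rows: dict[str, dict] = {}
    bad = 0
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            tid = row["taxon_id"].strip()
            rec = rows.setdefault(tid, {
                "scientific_name": row.get("scientific_name", "").strip(),
                "order_name": row.get("order_name", "").strip(),
                "names": [],
            })
            raw = row.get("common_name", "")
            try:
                name = normalize_name(raw)
            except ValueError:
                bad += 1
                continue
            if name not in rec["names"]:
                rec["names"].append(name)
    if bad:
        logger.warning("dropped %d unusable common names", bad)
    return [
        SpeciesRecord(taxon_id=tid, scientific_name=rec["scientific_name"],
                      common_names=tuple(rec["names"]),
                      order_name=rec["order_name"])
        for tid, rec in sorted(rows.items())
    ]


def _node(pair) -> tuple[str, str]:
    kind, nid = pair
    return (kind, nid)


def read_edit_script(path) -> list[Edit]:
    """Load a JSON edit script: a list of {"op": ..., ...} objects."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    edits = []
    for i, d in enumerate(raw):
        op = d.get("op")
        if op == "remove_edge":
            edits.append(Edit.remove_edge(_node(d["a"]), _node(d["b"])))
        elif op == "remove_node":
            edits.append(Edit.remove_node(_node(d["node"])))
        elif op == "merge":
            edits.append(Edit.merge(_node(d["a"]), _node(d["b"])))
        elif op == "select_taxon":
            edits.append(Edit.select_taxon(_node(d["node"]), d["label"]))
        else:
            raise ValueError(f"edit {i}: unknown op {op!r}")
    return edits


def write_keyword_sets(path, keyword_sets) -> None:
    """Write keyword sets as a JSON array of {taxon_label, positives, negatives}."""
    payload = [k.to_json_dict() for k in
               sorted(keyword_sets, key=lambda k: k.taxon_label)]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def read_keyword_sets(path) -> list[KeywordSet]:
    with open(path, encoding="utf-8") as fh:
        return [KeywordSet.from_json_dict(d) for d in json.load(fh)]
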