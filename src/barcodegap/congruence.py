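"""Congruence of delimitation partitions with reference taxonomy.

Each nominal species is compared with each partition and assigned one of
five categories:

* ``MATCH``   — all its sequences in one cluster, with no identified
  sequence of another species in that cluster;
* ``SINGLE``  — a MATCH whose species has exactly one sequence;
* ``MERGE``   — one cluster, but shared with other identified species;
* ``SPLIT``   — two or more clusters, all pure;
* ``COMPLEX`` — two or more clusters, at least one shared.

Sequences not identified to species are never classified and never make a
cluster impure.  Agreement across a panel of methods is tabulated per
species ("high congruence" when all, or all but one, methods agree), and
each method can be scored against the panel's modal consensus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .io_formats import Partition

__all__ = [
    "CATEGORIES",
    "CongruenceRecord",
    "classify_species",
    "classify_all",
    "congruence_table",
    "method_consensus_score",
]

CATEGORIES = ("MATCH", "SINGLE", "MERGE", "SPLIT", "COMPLEX")


@dataclass(frozen=True)
class CongruenceRecord:
    species: str
    method: str
    category: str
    n_clusters_touched: int
    impure: bool


def classify_species(
    p: Partition, labels: Mapping[str, str | None], species: str
) -> CongruenceRecord:
    """Classify one species against one partition (see module docstring)."""
    members = [
        seq_id for seq_id, sp in labels.items() if sp == species and seq_id in p.assignment
    ]
    if not members:
        raise ValueError(f"species {species!r} absent from partition coverage")
    touched = {p.assignment[m] for m in members}
    impure = False
    for seq_id, g in p.assignment.items():
        if g not in touched:
            continue
        sp = labels.get(seq_id)
        if sp is not None and sp != species:
            impure = True
            break
    if len(touched) == 1:
        if impure:
            category = "MERGE"
        elif len(members) == 1:
            category = "SINGLE"
        else:
            category = "MATCH"
    else:
        category = "COMPLEX" if impure else "SPLIT"
    return CongruenceRecord(species, p.name, category, len(touched), impure)


def classify_all(
    p: Partition, labels: Mapping[str, str | None]
) -> dict[str, CongruenceRecord]:
    """Classify every identified species covered by the partition."""
    species = sorted(
        {sp for seq_id, sp in labels.items() if sp is not None and seq_id in p.assignment}
    )
    return {sp: classify_species(p, labels, sp) for sp in species}


def congruence_table(
    partitions: list[Partition], labels: Mapping[str, str | None]
) -> pd.DataFrame:
    """Per-species category counts across a panel of partitions.

    The ``high_congruence`` column holds the agreed category when all
    methods agree, the category in parentheses when all but one agree, and
    is empty otherwise.
    """
    if not partitions:
        raise ValueError("need at least one partition")
    records = [classify_all(p, labels) for p in partitions]
    species = sorted(set().union(*(set(r) for r in records)))
    n_methods = len(partitions)
    rows = []
    for sp in species:
        counts = Counter(r[sp].category for r in records if sp in r)
        row = {"species": sp}
        for cat in CATEGORIES:
            row[cat] = counts.get(cat, 0)
        top, top_n = counts.most_common(1)[0]
        if top_n == n_methods:
            row["high_congruence"] = top
        elif top_n == n_methods - 1:
            row["high_congruence"] = f"({top.capitalize()})"
        else:
            row["high_congruence"] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=["species", *CATEGORIES, "high_congruence"])


def method_consensus_score(
    partitions: list[Partition], labels: Mapping[str, str | None]
) -> dict[str, int]:
    """Disagreements of each method with the panel's modal category.

    Per species the consensus is the modal category across methods; ties
    mean no consensus and the species is skipped for every method.  Each
    method's score is the number of species where it departs from the
    consensus (lower is better).
    """
    if len(partitions) < 3:
        raise ValueError("need at least 3 partitions for a consensus")
    records = [classify_all(p, labels) for p in partitions]
    species = sorted(set().union(*(set(r) for r in records)))
    scores = {p.name: 0 for p in partitions}
    for sp in species:
        cats = [r[sp].category for r in records if sp in r]
        counts = Counter(cats).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            continue  # tied mode: no consensus for this species
        consensus = counts[0][0]
        for p, r in zip(partitions, records):
            if sp in r and r[sp].category != consensus:
                scores[p.name] += 1
    return scores
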