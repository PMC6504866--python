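"""Haplotype collapsing.

Tree-based delimitation methods misbehave on duplicate sequences, so a
barcode library is reduced to unique haplotypes before analysis.  Two passes
are made:

* Pass 1 emulates greedy identity clustering: two records are duplicates
  when they agree at every column where both carry an unambiguous base
  (A/C/G/T) *and* the less complete record's informative positions fall
  within the span of the more complete one.  Ambiguity codes and N match
  any base; gaps are missing data, not a fifth state.
* Pass 2 re-checks the survivors with a plain pairwise-identity criterion
  (zero observed differences over ≥1 compared site, no span condition),
  catching staggered-coverage pairs that slipped through pass 1.

Within every duplicate set the record with the greatest ungapped length is
kept (ties: lexicographically smallest id).  Collapsing never eliminates an
identified species: if a duplicate set spans several species, one
representative per species is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Alignment, SequenceRecord

__all__ = ["HaplotypeMap", "collapse_haplotypes", "assert_species_preserved"]


@dataclass
class HaplotypeMap:
    """Bookkeeping of which sequences each kept haplotype represents."""

    represents: dict[str, list[str]] = field(default_factory=dict)

    def multiplicity(self, kept_id: str) -> int:
        """Represented sequence count for a kept id, including itself."""
        return 1 + len(self.represents[kept_id])

    @property
    def kept_ids(self) -> list[str]:
        return list(self.represents)

    @property
    def total(self) -> int:
        return sum(self.multiplicity(k) for k in self.represents)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kept_id\tmultiplicity\trepresented_ids\n")
            for kept, removed in self.represents.items():
                fh.write(f"{kept}\t{self.multiplicity(kept)}\t{','.join(removed)}\n")


_BASES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    """Unambiguous bases as 0..3, everything else (N/ambiguity/gap) as -1."""
    return np.array([_BASES.get(ch, -1) for ch in seq], dtype=np.int8)


def _duplicate_pair(a: np.ndarray, b: np.ndarray, require_span: bool) -> bool:
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return False
    if (a[both] != b[both]).any():
        return False
    if not require_span:
        return True
    # the record with fewer informative sites must lie within the span of
    # the other's informative range
    pos_a = np.flatnonzero(a >= 0)
    pos_b = np.flatnonzero(b >= 0)
    if len(pos_a) <= len(pos_b):
        short, long_ = pos_a, pos_b
    else:
        short, long_ = pos_b, pos_a
    return bool(long_[0] <= short[0] and short[-1] <= long_[-1])


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _keep_key(rec: SequenceRecord) -> tuple[int, str]:
    # longest first; ties to the lexicographically smallest id
    return (-rec.ungapped_length, rec.id)


def _collapse_pass(aln: Alignment, require_span: bool) -> tuple[Alignment, dict[str, str]]:
    """One duplicate-elimination pass.

    Returns the surviving alignment and a removed-id -> kept-id map.
    """
    records = aln.records
    n = len(records)
    codes = [_encode(r.seq) for r in records]
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if _duplicate_pair(codes[i], codes[j], require_span):
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)

    kept_idx: set[int] = set()
    assigned_to: dict[str, str] = {}
    for members in clusters.values():
        # keep one record per identified species in the set (plus one for
        # the unidentified members) so no species is eliminated
        by_species: dict[str | None, list[int]] = {}
        for i in members:
            by_species.setdefault(records[i].label.species, []).append(i)
        overall_best = min(members, key=lambda i: _keep_key(records[i]))
        species_keeper: dict[str | None, int] = {}
        for sp, idxs in by_species.items():
            if sp is None:
                continue
            species_keeper[sp] = min(idxs, key=lambda i: _keep_key(records[i]))
        if None in by_species and not species_keeper:
            species_keeper[None] = overall_best
        kept_idx.update(species_keeper.values())
        for i in members:
            if i in species_keeper.values():
                continue
            sp = records[i].label.species
            keeper = species_keeper.get(sp)
            if keeper is None:  # unidentified member: attach to best kept
                keeper = min(species_keeper.values(), key=lambda k: _keep_key(records[k]))
            assigned_to[records[i].id] = records[keeper].id

    survivors = [r for i, r in enumerate(records) if i in kept_idx]
    return Alignment(survivors), assigned_to


def collapse_haplotypes(aln: Alignment) -> tuple[Alignment, HaplotypeMap]:
    """Collapse a library to unique haplotypes (two passes, see module doc)."""
    if not len(aln):
        raise ValueError("empty alignment")
    pass1, removed1 = _collapse_pass(aln, require_span=True)
    pass2, removed2 = _collapse_pass(pass1, require_span=False)

    # chase pass-1 removals through pass 2 so every id maps to a survivor
    final_of: dict[str, str] = {}
    for rid, kept in removed1.items():
        final_of[rid] = removed2.get(kept, kept)
    final_of.update(removed2)

    hmap = HaplotypeMap({r.id: [] for r in pass2})
    for rid, kept in final_of.items():
        hmap.represents[kept].append(rid)
    for lst in hmap.represents.values():
        lst.sort()

    ok, missing = assert_species_preserved(aln, pass2)
    if not ok:  # guarded by the per-species keeper rule; defensive only
        raise AssertionError(f"species eliminated by collapse: {missing}")
    return pass2, hmap


def assert_species_preserved(before: Alignment, after: Alignment) -> tuple[bool, list[str]]:
    """Check no identified species was eliminated by collapsing.

    Returns ``(True, [])`` when the identified species-name sets are equal,
    else ``(False, missing_names)``.
    """
    names_before = {r.label.species for r in before if r.label.identified}
    names_after = {r.label.species for r in after if r.label.identified}
    missing = sorted(names_before - names_after)
    return (not missing, missing)
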