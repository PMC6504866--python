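"""Screening for likely misidentified sequences.

In curated reference libraries, a mislabeled specimen shows up as a
sequence that is far from everything sharing its label yet very close to a
different species.  The screen makes that observation an explicit rule: a
sequence is flagged when

* its minimum distance to any sequence sharing its label exceeds
  ``t_self`` (or it is the sole bearer of its label), and
* its minimum distance to some *other* identified species is at most
  ``t_other``.

Defaults (t_self = 0.05, t_other = 0.02) reflect the empirical scale of
COI barcode libraries, where intraspecific distances mostly sit below 0.05
and interspecific distances above it.  Flags are advisory: they are written
to a corrections file (id TAB corrected_species) for a human to confirm or
edit before any relabeling happens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distances import DistanceMatrix

__all__ = ["MisidFlag", "flag_misidentifications", "write_flags", "read_corrections"]


@dataclass(frozen=True)
class MisidFlag:
    id: str
    labeled_species: str
    nearest_own: float | None
    nearest_other_species: str
    nearest_other: float
    severity: str  # species_level | genus_level | family_level
    evidence: str


def _genus(species: str) -> str:
    return species.split()[0]


def flag_misidentifications(
    m: DistanceMatrix,
    labels: Mapping[str, str | None],
    t_self: float = 0.05,
    t_other: float = 0.02,
    genus_to_family: Mapping[str, str] | None = None,
) -> list[MisidFlag]:
    """Flag identified sequences whose label conflicts with their neighbours.

    Severity is taken from the taxonomic rank of the conflict: the nearest
    other species in the same genus -> ``species_level``; another genus ->
    ``genus_level``; another family (when a genus -> family map is given)
    -> ``family_level``.  Output order follows ``m.ids``.
    """
    members: dict[str, list[int]] = {}
    for seq_id in m.ids:
        sp = labels.get(seq_id)
        if sp is not None:
            members.setdefault(sp, []).append(m.index[seq_id])

    flags: list[MisidFlag] = []
    for seq_id in m.ids:
        sp = labels.get(seq_id)
        if sp is None:
            continue
        i = m.index[seq_id]
        own = [j for j in members[sp] if j != i]
        nearest_own = None
        if own:
            vals = m.d[i, own]
            vals = vals[~np.isnan(vals)]
            if len(vals):
                nearest_own = float(vals.min())
        if nearest_own is not None and nearest_own <= t_self:
            continue
        nearest_other_species, nearest_other = None, None
        for other, idx in members.items():
            if other == sp:
                continue
            vals = m.d[i, idx]
            vals = vals[~np.isnan(vals)]
            if not len(vals):
                continue
            lo = float(vals.min())
            if nearest_other is None or lo < nearest_other:
                nearest_other_species, nearest_other = other, lo
        if nearest_other is None or nearest_other > t_other:
            continue
        if _genus(nearest_other_species) == _genus(sp):
            severity = "species_level"
        elif genus_to_family is not None and genus_to_family.get(
            _genus(nearest_other_species)
        ) != genus_to_family.get(_genus(sp)):
            severity = "family_level"
        else:
            severity = "genus_level"
        own_txt = "sole bearer of label" if nearest_own is None else f"nearest conspecific {nearest_own:.4f}"
        flags.append(
            MisidFlag(
                id=seq_id,
                labeled_species=sp,
                nearest_own=nearest_own,
                nearest_other_species=nearest_other_species,
                nearest_other=nearest_other,
                severity=severity,
                evidence=(
                    f"{own_txt} > {t_self}; "
                    f"{nearest_other:.4f} from {nearest_other_species} <= {t_other}"
                ),
            )
        )
    return flags


def write_flags(flags: list[MisidFlag], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tlabeled_species\tnearest_own\tnearest_other_species\t"
            "nearest_other\tseverity\tevidence\n"
        )
        for f in flags:
            own = "" if f.nearest_own is None else f"{f.nearest_own:.6f}"
            fh.write(
                f"{f.id}\t{f.labeled_species}\t{own}\t{f.nearest_other_species}\t"
                f"{f.nearest_other:.6f}\t{f.severity}\t{f.evidence}\n"
            )


def write_corrections_template(flags: list[MisidFlag], path) -> None:
    """Proposed relabelings (id TAB corrected_species) for human sign-off."""
    with open(path, "w") as fh:
        fh.write("#id\tcorrected_species\n")
        for f in flags:
            fh.write(f"{f.id}\t{f.nearest_other_species}\n")


def read_corrections(path) -> dict[str, str]:
    """Read a confirmed corrections file (id TAB corrected_species)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, _, sp = line.partition("\t")
            out[seq_id.strip()] = sp.strip()
    return out
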