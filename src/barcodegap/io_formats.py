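"""Reading and writing barcode-library files.

A reference barcode library is an aligned set of COI sequences whose FASTA
headers carry the specimen identifier and, when available, a binomial
species identification.  Two header dialects are accepted:

* ``>id|Genus epithet`` — pipe-separated (the library's native style);
* ``>id Genus epithet`` — whitespace-separated (BOLD-style exports).

Species delimitation results arrive as two-column TSV files (sequence id,
group id) with optional ``#key=value`` metadata lines, so partitions
produced by external tools (GMYC, bPTP, mPTP, RESL) can be ingested
alongside the ones computed here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "TaxonLabel",
    "SequenceRecord",
    "Alignment",
    "Partition",
    "read_alignment",
    "write_alignment",
    "apply_length_filter",
    "crop_alignment",
    "read_partition",
    "write_partition",
    "species_labels",
]

# IUPAC nucleotide alphabet plus gap; 'U' is normalised to 'T' on input.
IUPAC_CHARS = frozenset("ACGTNRYSWKMBDHV-")

# Epithet tokens that mark an identification as not-to-species.  Matched on
# the first whitespace token of the epithet, case-insensitively, ignoring a
# trailing dot and trailing digits ("sp.", "sp2", "aff. grisescens", ...).
PLACEHOLDER_EPITHETS = frozenset({"sp", "spp", "aff", "cf", "nr"})

_PLACEHOLDER_RE = re.compile(
    r"^(" + "|".join(sorted(PLACEHOLDER_EPITHETS)) + r")\.?\d*$", re.IGNORECASE
)


@dataclass(frozen=True)
class TaxonLabel:
    """Parsed taxonomic identification of one sequence."""

    genus: str = ""
    epithet: str = ""

    @property
    def identified(self) -> bool:
        """True iff identified to species level.

        Requires both a genus and an epithet, and the epithet must not be a
        placeholder such as "sp.", "aff." or "cf.".
        """
        if not self.genus or not self.epithet:
            return False
        first = self.epithet.split()[0]
        return _PLACEHOLDER_RE.match(first) is None

    @property
    def species(self) -> str | None:
        """Binomial name, or None when not identified to species."""
        if not self.identified:
            return None
        return f"{self.genus} {self.epithet}"

    def __str__(self) -> str:
        return f"{self.genus} {self.epithet}".strip()


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its identification."""

    id: str
    label: TaxonLabel
    seq: str

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap characters (bp)."""
        return len(self.seq) - self.seq.count("-")


@dataclass
class Alignment:
    """An ordered collection of equal-length aligned sequences."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id: {dup!r}")
        widths = {len(r.seq) for r in self.records}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].seq) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


@dataclass
class Partition:
    """A species-delimitation result: sequence id -> dense group integer."""

    method: str
    assignment: dict[str, int]
    params: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def name(self) -> str:
        """Method name disambiguated by parameters (for panel tables)."""
        if not self.params:
            return self.method or "partition"
        inner = ",".join(f"{k}={v}" for k, v in sorted(self.params.items()))
        return f"{self.method}[{inner}]"

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for seq_id, g in self.assignment.items():
            out.setdefault(g, []).append(seq_id)
        return out

    def renumbered(self) -> "Partition":
        """Return an equivalent partition with dense group ids assigned in
        order of first appearance."""
        mapping: dict[int, int] = {}
        assignment = {}
        for seq_id, g in self.assignment.items():
            if g not in mapping:
                mapping[g] = len(mapping)
            assignment[seq_id] = mapping[g]
        return Partition(self.method, assignment, dict(self.params))


def _parse_label(text: str) -> TaxonLabel:
    text = text.strip()
    if not text:
        return TaxonLabel()
    parts = text.split(None, 1)
    genus = parts[0]
    epithet = parts[1] if len(parts) > 1 else ""
    return TaxonLabel(genus=genus, epithet=epithet)


def parse_header(header: str) -> tuple[str, TaxonLabel]:
    """Split a FASTA header into sequence id and taxon label.

    Accepts ``id|Genus epithet`` and BOLD-style ``id Genus epithet``.
    """
    header = header.strip()
    if "|" in header:
        seq_id, _, rest = header.partition("|")
        return seq_id.strip(), _parse_label(rest)
    parts = header.split(None, 1)
    return parts[0], _parse_label(parts[1] if len(parts) > 1 else "")


def _clean_sequence(raw: str, seq_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_CHARS:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {pos + 1} "
                f"in sequence {seq_id!r}"
            )
    return seq


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased and U is mapped to T.  Shorter sequences are
    right-padded with gaps to the longest record so the result is
    rectangular; padding does not change any record's ungapped length.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, label = parse_header(rec.description)
        if seq_id in seen:
            raise ValueError(f"duplicate sequence id: {seq_id!r}")
        seen.add(seq_id)
        records.append(SequenceRecord(seq_id, label, _clean_sequence(str(rec.seq), seq_id)))
    if not records:
        raise ValueError(f"no sequences in {path}")
    width = max(len(r.seq) for r in records)
    records = [
        replace(r, seq=r.seq + "-" * (width - len(r.seq))) if len(r.seq) < width else r
        for r in records
    ]
    return Alignment(records)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as FASTA with ``id|Genus epithet`` headers."""
    bio = []
    for r in aln:
        label = str(r.label)
        name = f"{r.id}|{label}" if label else r.id
        bio.append(_BioSeqRecord(Seq(r.seq), id=name, description=""))
    SeqIO.write(bio, str(path), "fasta-2line")


def apply_length_filter(aln: Alignment, min_bp: int, allowlist: set[str] | None = None) -> Alignment:
    """Keep records strictly longer than ``min_bp`` ungapped bases.

    Records whose id is in ``allowlist`` are retained regardless of length
    (the curated exceptions of the library).  Order is preserved.
    """
    if min_bp <= 0:
        raise ValueError("min_bp must be positive")
    allowlist = allowlist or set()
    kept = [r for r in aln if r.ungapped_length > min_bp or r.id in allowlist]
    return Alignment(kept)


def crop_alignment(aln: Alignment, start_col: int, width: int) -> Alignment:
    """Slice every record to columns ``[start_col, start_col + width)``."""
    if width <= 0:
        raise ValueError("crop width must be positive")
    if start_col < 0 or start_col + width > aln.n_columns:
        raise ValueError(
            f"crop window [{start_col}, {start_col + width}) outside "
            f"alignment of {aln.n_columns} columns"
        )
    return Alignment(
        [replace(r, seq=r.seq[start_col : start_col + width]) for r in aln]
    )


def read_partition(path) -> Partition:
    """Read a two-column partition TSV (sequence id, group id).

    Lines beginning ``#`` hold metadata; ``#method=NAME`` names the method.
    Group ids are normalised to dense integers in order of first appearance.
    """
    method = ""
    params: dict = {}
    raw: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key.strip() == "method":
                    method = value.strip()
                elif value:
                    params[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>group'")
            seq_id, group = fields[0].strip(), fields[1].strip()
            if seq_id in raw:
                if raw[seq_id] != group:
                    raise ValueError(
                        f"{path}: id {seq_id!r} assigned to both "
                        f"{raw[seq_id]!r} and {group!r}"
                    )
                warnings.warn(f"{path}: duplicate row for id {seq_id!r}; deduped")
                continue
            raw[seq_id] = group
    if not raw:
        raise ValueError(f"no assignments in {path}")
    dense: dict[str, int] = {}
    assignment = {}
    for seq_id, group in raw.items():
        if group not in dense:
            dense[group] = len(dense)
        assignment[seq_id] = dense[group]
    return Partition(method=method, assignment=assignment, params=params)


def write_partition(p: Partition, path) -> None:
    with open(path, "w") as fh:
        if p.method:
            fh.write(f"#method={p.method}\n")
        for key, value in p.params.items():
            fh.write(f"#{key}={value}\n")
        for seq_id, g in p.assignment.items():
            fh.write(f"{seq_id}\t{g}\n")


def species_labels(aln: Alignment) -> dict[str, str | None]:
    """Map sequence id -> binomial species name (None if unidentified)."""
    return {r.id: r.label.species for r in aln}
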