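import pytest

from barcodegap.io_formats import Alignment, SequenceRecord, TaxonLabel


def make_record(seq_id: str, label: str, seq: str) -> SequenceRecord:
    """Build a record from an 'id', 'Genus epithet' label and sequence."""
    parts = label.split(None, 1) if label else []
    tl = TaxonLabel(parts[0] if parts else "", parts[1] if len(parts) > 1 else "")
    return SequenceRecord(seq_id, tl, seq)


def make_alignment(rows: list[tuple[str, str, str]]) -> Alignment:
    """Alignment from (id, label, seq) rows."""
    return Alignment([make_record(*row) for row in rows])


@pytest.fixture
def two_cluster_alignment() -> Alignment:
    """Two well-separated species of three sequences each (40 columns)."""
    base_a = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"
    base_b = "TGCATGCATGCATGCATGCATGCATGCATGCATGCATGCA"
    rows = [
        ("a1", "Alpha una", base_a),
        ("a2", "Alpha una", base_a[:-1] + "C"),
        ("a3", "Alpha una", "G" + base_a[1:]),
        ("b1", "Beta dua", base_b),
        ("b2", "Beta dua", base_b[:-1] + "G"),
        ("b3", "Beta dua", "A" + base_b[1:]),
    ]
    return make_alignment(rows)
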