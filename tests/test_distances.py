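import math

import numpy as np
import pytest

from barcodegap.distances import (
    SiteCounts,
    bootstrap_se,
    distance_matrix,
    high_intraspecific_species,
    k2p,
    low_interspecific_pairs,
    mean_intraspecific,
    p_distance,
    site_counts,
    species_summaries,
    tn93,
)
from barcodegap.io_formats import species_labels

from conftest import make_alignment, make_record

EQUAL = (0.25, 0.25, 0.25, 0.25)


def test_site_counts_identical_pair():
    a = make_record("a", "", "ACGT" * 25)
    b = make_record("b", "", "ACGT" * 25)
    c = site_counts(a, b)
    assert (c.L, c.P, c.Q) == (100, 0.0, 0.0)


def test_site_counts_transitions_and_transversions():
    # 100 sites: 10 A<->G (transitions) and 5 A<->C (transversions)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    c = site_counts(make_record("a", "", a), make_record("b", "", b))
    assert c.L == 100
    assert c.P == pytest.approx(0.10)
    assert c.Q == pytest.approx(0.05)
    assert c.P1 == pytest.approx(0.10)  # all transitions are purine here
    assert c.P2 == 0.0


def test_site_counts_pairwise_deletion():
    a = make_record("a", "", "ACGTN-RA")
    b = make_record("b", "", "ACGTAAAN")
    c = site_counts(a, b)
    # columns 5,6,7,8 carry N/gap/ambiguity in one record -> excluded
    assert c.L == 4
    assert c.P == c.Q == 0.0


def test_k2p_closed_form():
    c = SiteCounts(100, 0.10, 0.0, 0.05, EQUAL)
    expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
    assert k2p(c) == pytest.approx(expected, abs=1e-12)
    assert k2p(c) == pytest.approx(0.170181, abs=5e-7)


def test_k2p_degenerate_cases():
    assert k2p(SiteCounts(100, 0.0, 0.0, 0.0, EQUAL)) == 0.0
    assert math.isnan(k2p(SiteCounts(100, 0.5, 0.0, 0.0, EQUAL)))  # saturation
    assert math.isnan(k2p(SiteCounts(0, 0.0, 0.0, 0.0, EQUAL)))


def test_tn93_reduces_to_k2p_under_equal_frequencies():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p_half = rng.uniform(0, 0.15)
        q = rng.uniform(0, 0.2)
        c = SiteCounts(500, p_half, p_half, q, EQUAL)
        expected = k2p(c)
        got = tn93(c)
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9)


def test_tn93_example_matches_k2p_value():
    c = SiteCounts(200, 0.05, 0.05, 0.05, EQUAL)
    assert tn93(c) == pytest.approx(
        k2p(SiteCounts(200, 0.10, 0.0, 0.05, EQUAL)), abs=1e-12
    )


def test_tn93_degenerate_cases():
    assert tn93(SiteCounts(100, 0.0, 0.0, 0.0, (0.3, 0.2, 0.2, 0.3))) == 0.0
    assert math.isnan(tn93(SiteCounts(100, 0.3, 0.2, 0.3, EQUAL)))  # saturated


def test_p_distance_is_raw_proportion():
    c = SiteCounts(100, 0.06, 0.04, 0.05, EQUAL)
    assert p_distance(c) == pytest.approx(0.15)


def test_correction_only_inflates():
    rng = np.random.default_rng(7)
    for _ in range(200):
        p_half = rng.uniform(0, 0.1)
        q = rng.uniform(0, 0.1)
        c = SiteCounts(300, p_half, p_half, q, EQUAL)
        assert k2p(c) >= p_distance(c) - 1e-12


def test_distance_matrix_matches_per_pair_oracle():
    aln = make_alignment(
        [
            ("a", "", "ACGTACGTAC"),
            ("b", "", "ACGTACGTGC"),
            ("c", "", "TCGAACGTAC"),
            ("d", "", "ACGTCCGTAN"),
        ]
    )
    m = distance_matrix(aln, "K2P")
    assert np.allclose(np.diag(m.d), 0)
    assert np.allclose(m.d, m.d.T, equal_nan=True)
    for i, a in enumerate(aln.records):
        for j, b in enumerate(aln.records):
            if i < j:
                assert m.d[i, j] == pytest.approx(k2p(site_counts(a, b)), abs=1e-12)


def test_distance_matrix_identical_records_zero():
    aln = make_alignment([(f"s{i}", "", "ACGTACGT") for i in range(3)])
    m = distance_matrix(aln, "K2P")
    assert np.all(m.d == 0)


def test_species_summaries_basic():
    aln = make_alignment(
        [
            ("a1", "Alpha una", "AAAAAAAAAA"),
            ("a2", "Alpha una", "AAAAAAAAAA"),
            ("b1", "Beta dua", "AAAAAGGGGG"),
            ("b2", "Beta dua", "AAAAGGGGGG"),
            ("c1", "Gamma tria", "GGGGGGGGGG"),  # singleton
            ("u1", "Alpha sp.", "AAAAAAAAAG"),  # unidentified: ignored
        ]
    )
    m = distance_matrix(aln, "p")
    summaries = species_summaries(m, species_labels(aln))
    by_name = {s.species: s for s in summaries}
    assert set(by_name) == {"Alpha una", "Beta dua", "Gamma tria"}
    alpha = by_name["Alpha una"]
    assert alpha.max_intra == 0.0 and alpha.mean_intra == 0.0
    assert alpha.nearest_species == "Beta dua"
    assert alpha.min_inter == pytest.approx(0.5)  # min over {0.5, 0.6}
    beta = by_name["Beta dua"]
    assert beta.nearest_species == "Gamma tria"
    assert beta.min_inter == pytest.approx(0.4)  # symmetric with Gamma's
    gamma = by_name["Gamma tria"]
    assert gamma.max_intra is None and gamma.mean_intra is None  # singleton
    assert gamma.min_inter == pytest.approx(0.4)
    assert gamma.nearest_species == "Beta dua"


def test_species_summaries_respects_exclusions():
    aln = make_alignment(
        [
            ("a1", "Alpha una", "AAAAAAAAAA"),
            ("a2", "Alpha una", "AAAAAAAAAA"),
            ("bad", "Alpha una", "GGGGGGGGGG"),  # flagged misidentification
            ("b1", "Beta dua", "AAGGGGGGGG"),
        ]
    )
    m = distance_matrix(aln, "p")
    summaries = species_summaries(m, species_labels(aln), exclude_ids={"bad"})
    alpha = next(s for s in summaries if s.species == "Alpha una")
    assert alpha.n == 2
    assert alpha.max_intra == 0.0


def test_threshold_reports():
    aln = make_alignment(
        [
            ("a1", "Alpha una", "A" * 100),
            ("a2", "Alpha una", "A" * 97 + "GGG"),
            ("b1", "Beta dua", "AA" + "A" * 98),  # 0 from a1: below cutoff
        ]
    )
    m = distance_matrix(aln, "p")
    summaries = species_summaries(m, species_labels(aln))
    low = low_interspecific_pairs(summaries, cutoff=0.03)
    assert len(low) == 1
    assert set(low.iloc[0][["species_a", "species_b"]]) == {"Alpha una", "Beta dua"}
    high = high_intraspecific_species(summaries, cutoff=0.02)
    assert list(high["species"]) == ["Alpha una"]


def test_bootstrap_se_zero_for_constant_alignment():
    aln = make_alignment(
        [("a1", "Alpha una", "ACGT" * 10), ("a2", "Alpha una", "ACGT" * 10)]
    )
    se = bootstrap_se(aln, species_labels(aln), mean_intraspecific, reps=50, seed=1)
    assert se == 0.0


def test_bootstrap_se_deterministic_given_seed(two_cluster_alignment):
    labels = species_labels(two_cluster_alignment)
    a = bootstrap_se(two_cluster_alignment, labels, mean_intraspecific, reps=100, seed=9)
    b = bootstrap_se(two_cluster_alignment, labels, mean_intraspecific, reps=100, seed=9)
    assert a == b
    assert a > 0


def test_bootstrap_se_matches_oversampled_run(two_cluster_alignment):
    labels = species_labels(two_cluster_alignment)
    se = bootstrap_se(two_cluster_alignment, labels, mean_intraspecific, reps=500, seed=2)
    oracle = bootstrap_se(
        two_cluster_alignment, labels, mean_intraspecific, reps=10_000, seed=99
    )
    assert se == pytest.approx(oracle, rel=0.2)
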