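"""Alignment, p-distance, similarity values and group distance tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodeid import (
    AlignedPair, BarcodeRecord, UndefinedDistance, align_pair,
    distance_matrix, group_distances, k2p_distance, p_distance,
    read_distance_matrix, similarity_value, write_distance_matrix,
)

from _oracles import brute_force_alignment


def rec(i, seq):
    return BarcodeRecord(id=f"r{i}", sequence=seq)


# --- pairwise alignment -----------------------------------------------------

def test_identical_sequences_align_gapless_with_score_length(library):
    r = library[0][0]
    pair = align_pair(r, r)
    assert pair.seq_a == pair.seq_b == r.sequence
    assert pair.score == len(r.sequence)


@pytest.mark.parametrize("a,b", [("ACGT", "ACT"), ("ACGT", "AGT"),
                                 ("AACGT", "ACG")])
def test_alignment_score_matches_exhaustive_enumeration(a, b):
    oracle_score, oracle_cols = brute_force_alignment(a, b)
    pair = align_pair(rec(1, a), rec(2, b))
    assert pair.score == oracle_score
    assert pair.columns == oracle_cols


def test_acgt_vs_act_uses_one_gap_over_four_columns():
    pair = align_pair(rec(1, "ACGT"), rec(2, "ACT"))
    assert pair.columns == 4
    assert pair.seq_a.count("-") + pair.seq_b.count("-") == 1


def test_alignment_score_is_symmetric(library):
    records, _ = library
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.choice(len(records), 2, replace=False)
        assert align_pair(records[a], records[b]).score == \
            align_pair(records[b], records[a]).score


def test_empty_sequence_rejected():
    with pytest.raises(Exception):
        align_pair(rec(1, "ACGT"), BarcodeRecord(id="e", sequence="A").with_sequence(""))


# --- p-distance -------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ("ACGT", "ACGT", 0.0),
    ("AAAA", "AAAT", 0.25),
    ("AC-GTN", "ACAGTT", 0.0),   # gap and N columns dropped; 4 compared sites
])
def test_p_distance_hand_cases(a, b, expected):
    assert p_distance(AlignedPair(a, b, 0.0)) == expected


def test_zero_overlap_is_undefined_not_zero():
    with pytest.raises(UndefinedDistance):
        p_distance(AlignedPair("AA--", "--TT", 0.0))


@given(st.data())
@settings(max_examples=50, deadline=None, derandomize=True)
def test_masking_a_mismatch_site_never_increases_p(data):
    n = data.draw(st.integers(8, 40))
    a = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    b = data.draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    mism = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not mism or len(mism) == n:
        return
    p0 = p_distance(AlignedPair(a, b, 0.0))
    i = mism[0]
    masked = a[:i] + "N" + a[i + 1:]
    assert p_distance(AlignedPair(masked, b, 0.0)) <= p0


def test_sv_plus_100p_is_100_and_sv_symmetric(library):
    records, _ = library
    rng = np.random.default_rng(1)
    for _ in range(30):
        i, j = rng.choice(len(records), 2, replace=False)
        a, b = records[i], records[j]
        sv = similarity_value(a, b)
        p = p_distance(align_pair(a, b))
        assert sv == pytest.approx(100 * (1 - p))
        assert sv == pytest.approx(similarity_value(b, a))
        assert 0 <= sv <= 100


def test_terminal_overhang_is_missing_data_not_mismatch():
    full = rec(1, "ATGGCAGCATTAGCA")
    fragment = rec(2, "GCAGCATTA")   # internal slice of full
    assert similarity_value(full, fragment) == 100.0


# --- K2P --------------------------------------------------------------------

def test_k2p_identical_pair_is_zero():
    assert k2p_distance(AlignedPair("ACGT", "ACGT", 0.0)) == 0.0


def test_k2p_transversion_only_matches_closed_form():
    # 2 transversions (A<->C) over 8 sites: P=0, Q=0.25
    a, b = "AAAAAAAA", "CCAAAAAA"
    Q = 0.25
    expected = -0.5 * np.log(1 - Q) - 0.25 * np.log(1 - 2 * Q)
    assert k2p_distance(AlignedPair(a, b, 0.0)) == pytest.approx(expected)


def test_k2p_at_least_p_distance(library):
    records, _ = library
    rng = np.random.default_rng(2)
    for _ in range(20):
        i, j = rng.choice(len(records), 2, replace=False)
        pair = align_pair(records[i], records[j])
        assert k2p_distance(pair) >= p_distance(pair)


def test_k2p_saturation_is_undefined():
    with pytest.raises(UndefinedDistance, match="saturat"):
        k2p_distance(AlignedPair("AAAA", "GGGG", 0.0))  # P=1: log arg <= 0


# --- matrices and group means ----------------------------------------------

def test_matrix_invariants_and_round_trip(library, tmp_path):
    records, _ = library
    dm = distance_matrix(records[:25], aligned=True)
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
    assert dm.data.min() >= 0 and dm.data.max() <= 1
    path = tmp_path / "dm.tsv"
    write_distance_matrix(dm, path)
    back = read_distance_matrix(path)
    assert list(back.ids) == list(dm.ids)
    assert np.allclose(back.data, dm.data, atol=1e-6)


def test_phylip_square_matrix_accepted(tmp_path):
    path = tmp_path / "dm.phy"
    path.write_text("3\nA 0.0 0.1 0.2\nB 0.1 0.0 0.3\nC 0.2 0.3 0.0\n")
    dm = read_distance_matrix(path)
    assert list(dm.ids) == ["A", "B", "C"]
    assert dm["A", "C"] == 0.2


def test_aligned_and_pairwise_routes_agree_on_equal_length(library):
    records, _ = library
    subset = records[:8]
    fast = distance_matrix(subset, aligned=True)
    slow = distance_matrix(subset, aligned=False)
    assert np.allclose(fast.data, slow.data)


def test_group_means_two_identical_groups():
    a = [rec(i, "A" * 10) for i in range(2)]
    b = [rec(i + 2, "A" * 9 + "T") for i in range(2)]
    dm = distance_matrix(a + b, aligned=True)
    table = group_distances(dm, {r.id: ("A" if r.id in {"r0", "r1"} else "B")
                                 for r in a + b})
    within = table.within.set_index("group")
    assert within.loc["A"].mean_within == 0.0
    assert within.loc["B"].mean_within == 0.0
    assert table.between.iloc[0].mean_between == pytest.approx(0.1)


def test_singleton_group_within_is_undefined_not_zero():
    records = [rec(0, "AAAA"), rec(1, "AAAT"), rec(2, "AATT")]
    dm = distance_matrix(records, aligned=True)
    table = group_distances(dm, {"r0": "solo", "r1": "pair", "r2": "pair"})
    within = table.within.set_index("group")
    assert np.isnan(within.loc["solo"].mean_within)
    assert within.loc["pair"].mean_within == 0.25


def test_within_species_below_congeneric_between_means(library):
    records, truth = library
    dm = distance_matrix(records, aligned=True)
    table = group_distances(dm, {r.id: r.lineage.species for r in records})
    info = truth.drop_duplicates("species").set_index("species")
    worst_within = table.within.mean_within.max()
    congeneric = [
        row.mean_between for row in table.between.itertuples()
        if info.loc[row.group_a].genus == info.loc[row.group_b].genus
    ]
    assert worst_within < min(congeneric)
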