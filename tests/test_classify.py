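"""Tier rule, hit lists, diagnostic characters and MOTU verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from barcodeid import (
    BarcodeRecord, DiagnosticCharacterClassifier, Lineage,
    ThresholdTaxonClassifier, assign_rank, best_hits, motu_verdict,
    rank_from_sv, simulate_queries,
)
from barcodeid.classify import AssignmentError

from conftest import DEFAULT_DIVERGENCE


# --- tier rule --------------------------------------------------------------

@pytest.mark.parametrize("sv,rank", [
    (100.0, "species"), (99.0, "species"), (98.0, "species"),
    (97.999, "genus"), (93.0, "genus"), (92.0, "genus"),
    (91.999, "family"), (85.9, "family"), (85.0, "family"),
    (84.999, "unassigned"), (0.0, "unassigned"),
])
def test_tier_rule_boundaries(sv, rank):
    assert rank_from_sv(sv) == rank


@given(st.floats(min_value=0, max_value=100, allow_nan=False))
@settings(max_examples=200, derandomize=True)
def test_tier_rule_is_total_and_single_valued(sv):
    assert rank_from_sv(sv) in {"species", "genus", "family", "unassigned"}


def test_non_decreasing_thresholds_rejected():
    with pytest.raises(AssignmentError):
        rank_from_sv(95.0, tiers=(92, 98, 85))


# --- hit lists and rank assignment -----------------------------------------

def lin(f=None, g=None, s=None):
    return Lineage(family=f, genus=g, species=s)


def test_identical_query_hits_its_reference_at_sv_100(library):
    records, _ = library
    query = BarcodeRecord(id="q", sequence=records[5].sequence)
    hits = best_hits(query, records, k=3)
    assert hits.best().reference_id == records[5].id
    assert hits.best().sv == 100.0


def test_k_larger_than_library_returns_full_ranking(library):
    records, _ = library
    hits = best_hits(BarcodeRecord(id="q", sequence=records[0].sequence),
                     records[:10], k=999)
    assert len(hits.hits) == 10
    svs = hits.hits.sv.to_numpy()
    assert (svs[:-1] >= svs[1:]).all()


def test_sv_ties_break_by_reference_id():
    seq = "ACGT" * 30
    refs = [
        BarcodeRecord(id=n, sequence=seq, lineage=lin("F", "G", f"S{n}"),
                      role="reference")
        for n in ("zeta", "alpha", "mid")
    ]
    hits = best_hits(BarcodeRecord(id="q", sequence=seq), refs, k=3)
    assert list(hits.hits.reference_id) == ["alpha", "mid", "zeta"]


def test_assignment_truncates_taxon_to_granted_rank(library):
    records, _ = library
    q, _ = simulate_queries(records, n_conspecific=0, n_novel_species=1,
                            n_novel_genus=0, seed=9,
                            divergence=DEFAULT_DIVERGENCE)
    a = assign_rank(best_hits(q[0], records, k=5))
    assert a.rank == "genus"
    assert a.taxon.species is None
    assert a.taxon.genus is not None
    assert a.taxon_name == a.taxon.genus


def test_empty_hit_list_is_unassigned():
    a = assign_rank(
        type("H", (), {"hits": pd.DataFrame(), "query_id": "q",
                       "best": None})()
    )
    assert a.rank == "unassigned" and a.taxon_name is None


def test_threshold_classifier_sklearn_protocol(library):
    records, _ = library
    clf = ThresholdTaxonClassifier(tiers=(98, 92, 85), k=3)
    assert clone(clf).get_params()["k"] == 3
    clf.fit(records[:24])
    query = BarcodeRecord(id="q", sequence=records[0].sequence)
    assert clf.predict([query])[0] == records[0].lineage.species
    assert clf.predict_rank([query])[0] == "species"
    table = clf.assign([query])
    assert list(table.columns[:4]) == ["query_id", "rank", "taxon", "best_sv"]
    assert table.iloc[0].n_hits >= 1


def test_conspecific_queries_top_hit_is_conspecific(library, queries):
    records, truth = library
    q, qtruth = queries
    clf = ThresholdTaxonClassifier().fit(records)
    con = [r for r in q if r.id.startswith("Q-CON")]
    hit_species = [h.best().species for h in clf.hit_lists(con)]
    expected = qtruth.set_index("id").species
    agree = np.mean([hs == expected[r.id] for r, hs in zip(con, hit_species)])
    assert agree >= 0.95


# --- diagnostic characters --------------------------------------------------

def test_single_fixed_column_is_diagnostic_for_both_species():
    x = ["ACGTACGT", "ACGTACGT", "ACGAACGT", "ACGAACGT"]
    y = ["sp1", "sp1", "sp2", "sp2"]
    dcc = DiagnosticCharacterClassifier().fit(x, y)
    assert dcc.diagnostics_["sp1"] == [(3, "T")]
    assert dcc.diagnostics_["sp2"] == [(3, "A")]
    assert dcc.predict(["ACGTACGT"])[0] == "sp1"
    assert dcc.predict(["ACGAACGT"])[0] == "sp2"


def test_ambiguous_state_at_diagnostic_column_is_no_call():
    dcc = DiagnosticCharacterClassifier().fit(
        ["ACGTACGT", "ACGAACGT"], ["sp1", "sp2"])
    assert dcc.predict(["ACGNACGT"])[0] == ""


def test_undiagnosable_species_recorded_and_never_called():
    # sp2 and sp3 share every state somewhere: no pure column for them
    x = ["AAAAT", "AAAAC", "AAAAC"]
    y = ["sp1", "sp2", "sp3"]
    dcc = DiagnosticCharacterClassifier().fit(x, y)
    assert set(dcc.undiagnosable_) == {"sp2", "sp3"}
    assert dcc.predict(["AAAAC"])[0] == ""


def test_character_accuracy_on_conspecific_queries(library, queries):
    records, _ = library
    q, qtruth = queries
    dcc = DiagnosticCharacterClassifier().fit(
        records, [r.lineage.species for r in records])
    con = [r for r in q if r.id.startswith("Q-CON")]
    calls = dcc.predict(con)
    expected = qtruth.set_index("id").species
    acc = np.mean([c == expected[r.id] for r, c in zip(con, calls)])
    assert acc >= 0.90


# --- MOTU verdicts ----------------------------------------------------------

def test_congeners_at_within_species_magnitude_are_merged_signal():
    # between 0.009 vs within 0.004: no barcode gap at ratio 5
    assert motu_verdict(0.004, 0.009) == "merged-signal"


def test_zero_within_and_clear_between_is_distinct():
    assert motu_verdict(0.000, 0.059) == "distinct"
    assert motu_verdict(0.000, 0.070) == "distinct"


def test_equal_within_and_between_is_ambiguous():
    assert motu_verdict(0.01, 0.01) == "ambiguous"


def test_undefined_within_uses_absolute_cutoff():
    assert motu_verdict(None, 0.05) == "distinct"
    assert motu_verdict(float("nan"), 0.01) == "ambiguous"


def test_clean_gap_with_large_ratio_is_distinct():
    assert motu_verdict(0.004, 0.08, max_within=0.01, min_between=0.05) \
        == "distinct"
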