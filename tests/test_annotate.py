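"""Edit-distance matching against the specificity database and motif-based
annotation propagation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tilrep.annotate import (
    DbMatch,
    SpecificityRecord,
    annotate_clusters,
    candidate_sets,
    category_counts,
    levenshtein,
    match_database,
    read_specificity_db,
    write_specificity_db,
)
from tilrep.model import AAEntry, AARepertoire
from tilrep.motifs import MotifCluster, MotifScore

from conftest import random_peptide

PEPTIDE = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=12)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("CASSF", "CASSF", 0),
        ("CASSLGG", "CASSIGG", 1),
        ("kitten", "sitting", 3),
        ("", "AC", 2),
    ],
)
def test_levenshtein_examples(a, b, expected):
    assert levenshtein(a, b) == expected


@given(PEPTIDE, PEPTIDE, PEPTIDE)
def test_levenshtein_is_a_metric(a, b, c):
    assert levenshtein(a, b) == dp_levenshtein(a, b)
    assert levenshtein(a, b) == levenshtein(b, a)
    assert (levenshtein(a, b) == 0) == (a == b)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def _db(*entries):
    return [SpecificityRecord(aa, cat, "src") for aa, cat in entries]


def test_match_database_distance_rules():
    db = _db(("CASSLGGSGEQFF", "cancer"), ("CASTPNYSNQPQHF", "pathogens"))
    res = match_database(
        ["CASSLGGSGEQFF", "CASSLGGSGEQYF", "CASSWWWWWWWFF"], db
    )
    assert [m.distance for m in res["CASSLGGSGEQFF"]] == [0]
    assert [m.distance for m in res["CASSLGGSGEQYF"]] == [1]
    assert res["CASSWWWWWWWFF"] == []


@pytest.mark.parametrize("seed", range(3))
def test_match_database_equals_bruteforce(seed):
    rng = np.random.default_rng(seed)
    queries = [random_peptide(rng, 8, 14) for _ in range(60)]
    db = [
        SpecificityRecord(random_peptide(rng, 8, 14), "cancer", "")
        for _ in range(120)
    ]
    got = match_database(queries, db, max_dist=1)
    for q in queries:
        expected = {
            (rec.cdr3_aa, dp_levenshtein(q, rec.cdr3_aa))
            for rec in db
            if dp_levenshtein(q, rec.cdr3_aa) <= 1
        }
        assert {(m.record.cdr3_aa, m.distance) for m in got[q]} == expected


def test_match_database_rejects_empty_db():
    with pytest.raises(ValueError, match="empty"):
        match_database(["CASSF"], [])


def test_db_csv_roundtrip_and_malformed_rows(tmp_path):
    db = _db(("CASSLGGSGEQFF", "cancer"), ("CASSF", "allergy"))
    path = tmp_path / "db.csv"
    write_specificity_db(db, path)
    assert read_specificity_db(path) == db
    bad = tmp_path / "bad.csv"
    bad.write_text("cdr3aa,category,source\nCASSF,prions,x\n")
    with pytest.raises(ValueError, match="row 1"):
        read_specificity_db(bad)


def _cluster(motif, members, biopsy="Q1"):
    score = MotifScore(0.01, 0.01, (len(members), 100, 1, 1000))
    return MotifCluster(motif=motif, members=tuple((m, 0.002) for m in members), biopsy=biopsy, score=score)


def test_candidate_sets_rules():
    aa_rep = AARepertoire(
        "s",
        [
            AAEntry("CASSAAAAAQYF", 200, 0.002, 1),
            AAEntry("CASSCCCCCQYF", 50, 0.0005, 1),
            AAEntry("CASSDDDDDQYF", 99750, 0.9975, 1),
        ],
    )
    clusters = [_cluster("AAAA", ["CASSAAAAAQYF"])]
    sets = candidate_sets(aa_rep, None, clusters, freq_threshold=0.001)
    assert sets.high_freq == {"CASSAAAAAQYF", "CASSDDDDDQYF"}
    assert sets.clustered == {"CASSAAAAAQYF"}
    assert sets.public == frozenset()
    assert sets.sizes == {"high_freq": 2, "public": 0, "clustered": 1}
    with pytest.raises(ValueError, match="freq_threshold"):
        candidate_sets(aa_rep, None, clusters, freq_threshold=1.5)
    empty = candidate_sets(aa_rep, None, [], freq_threshold=0.001)
    assert empty.clustered == frozenset()


def test_annotation_propagates_cancer_across_cluster():
    members = ["CASSAAAAAQYF", "CASSAAAACQYF", "CASSAAAADQYF", "CASSAAAAEQYF"]
    cluster = _cluster("AAAA", members)
    rec = SpecificityRecord("CASSAAAAAQYF", "cancer", "melanoma")
    matches = {members[0]: [DbMatch(members[0], rec, 0)]}
    table = annotate_clusters([cluster], matches)
    assert len(table) == 4
    assert (table["categories"] == "cancer").all()
    assert (table["direct"] == "cancer").sum() == 1
    assert (table["propagated"] == "cancer").sum() == 3
    counts = category_counts(table)
    row = counts[counts["category"] == "cancer"].iloc[0]
    assert row["direct"] == 1 and row["direct_plus_propagated"] == 4
    # monotonicity: propagation can only add sequences
    assert (counts["direct_plus_propagated"] >= counts["direct"]).all()


def test_non_cancer_matches_not_propagated():
    members = ["CASSAAAAAQYF", "CASSAAAACQYF"]
    cluster = _cluster("AAAA", members)
    rec = SpecificityRecord("CASSAAAAAQYF", "pathogens", "CMV")
    matches = {members[0]: [DbMatch(members[0], rec, 1)]}
    table = annotate_clusters([cluster], matches)
    assert len(table) == 1
    assert table.iloc[0]["direct"] == "pathogens"
    assert (table["propagated"] == "").all()


def test_annotation_empty_when_no_matches():
    table = annotate_clusters([_cluster("AAAA", ["CASSAAAAAQYF"])], {})
    assert table.empty


def test_multi_category_sequence_keeps_all():
    members = ["CASSAAAAAQYF"]
    cluster = _cluster("AAAA", members)
    matches = {
        members[0]: [
            DbMatch(members[0], SpecificityRecord("CASSAAAAAQYF", "cancer", ""), 0),
            DbMatch(members[0], SpecificityRecord("CASSAAAACQYF", "allergy", ""), 1),
        ]
    }
    table = annotate_clusters([cluster], matches)
    assert table.iloc[0]["categories"] == "allergy;cancer"
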