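"""Motif enumeration, wildcard matching, enrichment scores and clustering."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from tilrep.germline import AA_ALPHABET
from tilrep.io import collapse_by_aa
from tilrep.model import AAEntry, AARepertoire
from tilrep.motifs import (
    cluster_by_motifs,
    enumerate_motifs,
    motif_matches,
    motif_sharing,
    score_motif,
    validate_motif,
)
from tilrep.synthetic import RepertoireSpec, generate_repertoire, reference_spec


def _aa_rep(seqs_counts, sample_id="s", patient="P01"):
    total = sum(c for _, c in seqs_counts)
    return AARepertoire(
        sample_id,
        [AAEntry(a, c, c / total, 1) for a, c in seqs_counts],
        patient_id=patient,
    )


def _uniform(seqs, **kw):
    return _aa_rep([(s, 1) for s in seqs], **kw)


def test_exact_4mer_enumeration_of_interior():
    motifs = enumerate_motifs(["CASSLGGSGEQFF"], k_exact=(4,), k_wild=())
    assert set(motifs) == {"SLGG", "LGGS", "GGSG", "GSGE", "SGEQ"}
    assert all(motifs[m] == {"CASSLGGSGEQFF"} for m in motifs)


@pytest.mark.parametrize(
    "seq,motif",
    [
        ("CASSLGGSGEQFF", "SLGG%GE"),  # % replacing an internal S
        ("CASTPNYSNQPQHF", "%NYSNQP"),  # leading wildcard
    ],
)
def test_worked_wildcard_motifs_enumerated_and_matched(seq, motif):
    assert motif_matches(motif, seq)
    motifs = enumerate_motifs([seq], k_exact=(), k_wild=(7,))
    assert motif in motifs and seq in motifs[motif]


def test_motif_grammar():
    validate_motif("SLGG%GE")
    validate_motif("%NYSNQP")
    for bad in ["SL", "SLGGSGEQ", "S%G%E", "SLGG%"]:
        with pytest.raises(ValueError):
            validate_motif(bad)


def test_short_interior_contributes_nothing():
    assert enumerate_motifs(["CASSF"], k_exact=(3,), k_wild=()) == {}


@given(
    st.text(alphabet=AA_ALPHABET, min_size=8, max_size=16),
    st.integers(min_value=0, max_value=3),
)
def test_wildcard_matches_union_of_substitutions(seq, pos):
    """A pattern with % matches exactly when some single-residue
    substitution of the wildcard matches exactly."""
    interior = seq[3:-2]
    if len(interior) < 5:
        return
    window = interior[:5]
    pos = min(pos, 3)
    pattern = window[:pos] + "%" + window[pos + 1 :]
    expected = any(
        motif_matches(pattern[:pos] + res + pattern[pos + 1 :], seq)
        for res in AA_ALPHABET
    )
    assert motif_matches(pattern, seq) == expected


@pytest.mark.parametrize("seed", range(4))
def test_fisher_score_equals_hypergeometric_tail(seed):
    """One-sided Fisher exact p equals the independent hypergeometric
    survival function on random tables (50 per seed)."""
    rng = np.random.default_rng(seed)
    for _ in range(50):
        n_s = int(rng.integers(5, 200))
        n_r = int(rng.integers(5, 2000))
        a = int(rng.integers(1, n_s + 1))
        c = int(rng.integers(0, n_r + 1))
        from tilrep.motifs import _fisher

        p = _fisher(a, n_s, c, n_r)
        expected = hypergeom.sf(a - 1, n_s + n_r, a + c, n_s)
        assert abs(p - expected) < 1e-10


def test_strong_enrichment_scores_small():
    sample = _uniform(["CASSLGGSGEQFF"] * 0 + [f"CASSLGGSG{AA_ALPHABET[i % 20]}QYF" for i in range(100)])
    carriers = [e.cdr3_aa for e in sample.entries if motif_matches("LGGS", e.cdr3_aa)]
    assert len(carriers) == 100
    ref = _uniform(
        [f"CASSYYY{AA_ALPHABET[i % 20]}{AA_ALPHABET[(i // 20) % 20]}QYF" for i in range(990)]
        + ["CASSLGGSGAQYF"] * 10
    )
    score = score_motif("LGGS", sample, ref, b=200, seed=0)
    assert score.fisher_score < 1e-3


def test_fisher_monotone_in_sample_carriers():
    from tilrep.motifs import _fisher

    prev = 1.0
    for a in range(1, 50):
        p = _fisher(a, 100, 5, 1000)
        assert p <= prev + 1e-15
        prev = p


def test_expansion_score_floor_for_top_clones():
    seqs = [(f"CASSLGGSG{AA_ALPHABET[i % 20]}{AA_ALPHABET[i // 20]}QYF", 1) for i in range(100)]
    # the two motif carriers hold nearly all frequency
    seqs[0] = ("CASSWWGGHTQYF", 5000)
    seqs[1] = ("CASSAWGGHTQYF", 4000)
    sample = _aa_rep(seqs)
    ref = _uniform([f"CASSYYYY{AA_ALPHABET[i % 20]}QYF" for i in range(500)])
    score = score_motif("WGGHT", sample, ref, b=1000, seed=1)
    assert score.expansion_score <= 2 / 1001


def test_expansion_score_reproducible_and_converged():
    rng = np.random.default_rng(5)
    seqs = {}
    for i in range(140):
        seqs[f"CASS{''.join(rng.choice(list(AA_ALPHABET), 6))}QYF"] = int(rng.integers(1, 50))
    for i in range(10):  # shared motif carriers with mid-range counts
        seqs[f"CASSWGGH{AA_ALPHABET[i]}TQYF"] = int(rng.integers(10, 60))
    sample = _aa_rep(sorted(seqs.items()))
    ref = _uniform([f"CASSYYY{AA_ALPHABET[i % 20]}{AA_ALPHABET[(i // 20) % 20]}QYF" for i in range(400)])
    s1 = score_motif("WGGH", sample, ref, b=1000, seed=7)
    s2 = score_motif("WGGH", sample, ref, b=1000, seed=7)
    assert s1 == s2
    s3 = score_motif("WGGH", sample, ref, b=10000, seed=8)
    assert abs(s1.expansion_score - s3.expansion_score) <= 0.03


def test_cluster_membership_contract_and_planted_recovery():
    sample = generate_repertoire(
        RepertoireSpec(
            n_clonotypes=200,
            seed=21,
            planted_motifs=(("SLGG%GE", 30),),
            clone_size_law=("geometric", 0.3),
        ),
        "s",
    )
    ref = generate_repertoire(
        reference_spec(2000, seed=22, planted_motifs=(("SLGG%GE", 20),)), "r"
    )
    clusters = cluster_by_motifs(
        collapse_by_aa(sample), collapse_by_aa(ref), b=300, seed=0
    )
    by_motif = {cl.motif: cl for cl in clusters}
    assert "SLGG%GE" in by_motif
    for cl in clusters:
        for s, _f in cl.members:
            assert motif_matches(cl.motif, s)
        assert 0 < cl.score.fisher_score <= 0.5
        assert 0 < cl.score.expansion_score <= 0.5


def test_nested_exact_motif_suppressed():
    carriers = [f"CASSLGGSGE{AA_ALPHABET[i]}FF" for i in range(10)]
    background = [f"CASTWW{AA_ALPHABET[i % 20]}YY{AA_ALPHABET[(i * 7) % 20]}NQFF" for i in range(90)]
    sample = _uniform(carriers + background)
    ref = _uniform([f"CASSYQY{AA_ALPHABET[i % 20]}{AA_ALPHABET[(i // 20) % 20]}TQYF" for i in range(400)])
    clusters = cluster_by_motifs(sample, ref, fisher_max=0.5, expansion_max=1.0, b=100, seed=0)
    motifs = {cl.motif for cl in clusters}
    carrier_sets = {cl.motif: frozenset(s for s, _ in cl.members) for cl in clusters}
    # every kept exact motif is either not contained in a longer passing
    # motif, or differs from it in carriers
    for m in motifs:
        if "%" in m:
            continue
        for other in motifs:
            if other != m and len(other) > len(m) and m in other:
                assert carrier_sets[other] != carrier_sets[m]


def test_motif_sharing_table():
    sample_a = generate_repertoire(
        RepertoireSpec(n_clonotypes=150, seed=31, planted_motifs=(("SLGG%GE", 25),)),
        "a",
        patient_id="Q14",
    )
    sample_b = generate_repertoire(
        RepertoireSpec(n_clonotypes=150, seed=32, planted_motifs=(("SLGG%GE", 25),)),
        "b",
        patient_id="Q1",
    )
    ref = generate_repertoire(reference_spec(1500, seed=33), "r")
    ref_aa = collapse_by_aa(ref)
    clusters = {
        rep.patient_id: cluster_by_motifs(collapse_by_aa(rep), ref_aa, b=200, seed=0)
        for rep in (sample_a, sample_b)
    }
    table = motif_sharing(clusters)
    assert table.loc["SLGG%GE", "n_biopsies"] == 2
    private = table[table["n_biopsies"] == 1]
    assert (private[["Q1", "Q14"]].sum(axis=1) == 1).all()
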