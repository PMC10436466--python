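"""Contracts of the synthetic V(D)J repertoire and cohort generator."""

import numpy as np
import pytest

from tilrep.germline import translate
from tilrep.io import collapse_by_aa, merge_samples
from tilrep.features import length_summary
from tilrep.model import Cohort
from tilrep.motifs import motif_matches
from tilrep.stats import convergence
from tilrep.synthetic import (
    CohortSpec,
    DbSpec,
    RepertoireSpec,
    cd4_til_spec,
    cd8_til_spec,
    generate_cohort,
    generate_repertoire,
    generate_specificity_db,
    mixed_initial_repertoire,
)


def test_same_seed_gives_identical_repertoires():
    spec = RepertoireSpec(n_clonotypes=150, seed=7, convergence_rate=0.1)
    r1 = generate_repertoire(spec, "s")
    r2 = generate_repertoire(spec, "s")
    assert r1 == r2


def test_different_seeds_differ():
    r1 = generate_repertoire(RepertoireSpec(n_clonotypes=50, seed=1), "s")
    r2 = generate_repertoire(RepertoireSpec(n_clonotypes=50, seed=2), "s")
    assert r1 != r2


def test_frequencies_sum_to_one_and_translation_consistent(small_repertoire):
    assert abs(small_repertoire.freq_sum() - 1.0) < 1e-9
    for c in small_repertoire.clonotypes:
        assert translate(c.cdr3_nt) == c.cdr3_aa
        assert c.v_end is not None and c.j_start is not None
        assert 0 <= c.v_end <= c.j_start <= len(c.cdr3_nt)


def test_zero_convergence_rate_gives_singleton_nt_variants():
    rep = generate_repertoire(
        RepertoireSpec(n_clonotypes=100, seed=3, convergence_rate=0.0), "s"
    )
    aa = collapse_by_aa(rep)
    assert aa.richness == 100
    assert all(e.nt_variant_count == 1 for e in aa.entries)
    assert convergence(aa).cr_level == 1.0


def test_convergence_rate_raises_cr_level():
    """Pooled CR level responds to the convergence knob across seeds."""
    wins = 0
    for seed in range(20):
        conv = generate_repertoire(
            RepertoireSpec(n_clonotypes=300, seed=seed, convergence_rate=0.3), "a"
        )
        none = generate_repertoire(
            RepertoireSpec(n_clonotypes=300, seed=seed, convergence_rate=0.0), "b"
        )
        if (
            convergence(collapse_by_aa(conv)).cr_level
            > convergence(collapse_by_aa(none)).cr_level
        ):
            wins += 1
    assert wins == 20


def test_ndn_length_mean_recovered():
    """Monte-Carlo: the generator's own NDN distribution is recovered by the
    downstream length summary within 0.2 nt at n=5000."""
    for mean, sd in [(14.4, 3.1), (11.4, 2.2)]:
        rep = generate_repertoire(
            RepertoireSpec(
                n_clonotypes=5000, ndn_length_mean=mean, ndn_length_sd=sd, seed=42
            ),
            "s",
        )
        assert abs(length_summary(rep).ndn_mean - mean) < 0.2


def test_planted_motif_carriers_embedded_in_interior():
    spec = RepertoireSpec(n_clonotypes=200, seed=5, planted_motifs=(("SLGG%GE", 25),))
    rep = generate_repertoire(spec, "s")
    carriers = {c.cdr3_aa for c in rep.clonotypes if motif_matches("SLGG%GE", c.cdr3_aa)}
    assert len(carriers) == 25
    for c in rep.clonotypes:
        assert translate(c.cdr3_nt) == c.cdr3_aa


def test_planted_motif_errors():
    with pytest.raises(ValueError, match="feasible CDR3 interior"):
        generate_repertoire(
            RepertoireSpec(
                n_clonotypes=10,
                ndn_length_mean=0.0,
                ndn_length_sd=0.0,
                planted_motifs=(("SLGGSGE", 2),),
            ),
            "s",
        )
    with pytest.raises(ValueError, match="exceed"):
        RepertoireSpec(n_clonotypes=5, planted_motifs=(("SLGG", 10),)).validate()


def test_nonproductive_injection_rate():
    rep = generate_repertoire(
        RepertoireSpec(n_clonotypes=400, seed=9, nonproductive_rate=0.2), "s"
    )
    bad = [c for c in rep.clonotypes if "*" in c.cdr3_aa or "_" in c.cdr3_aa]
    assert 0.05 < len(bad) / 400 < 0.35
    # frameshifted clones are genuinely out of frame
    for c in bad:
        assert "*" in c.cdr3_aa or len(c.cdr3_nt) % 3 != 0


def test_cohort_public_injection_exact_share():
    spec = CohortSpec(
        n_patients=3,
        slices_per_patient=1,
        compartments=(("CD4", RepertoireSpec(n_clonotypes=80)),),
        public_injection=(("CASSPGLICEQYF", 2),),
        reference_size=100,
        seed=4,
    )
    cohort = generate_cohort(spec)
    patients_with = {
        r.patient_id
        for r in cohort.repertoires
        if any(c.cdr3_aa == "CASSPGLICEQYF" for c in r.clonotypes)
    }
    assert len(patients_with) == 2


def test_cohort_structure_and_slice_merge_union():
    spec = CohortSpec(
        n_patients=2,
        slices_per_patient=2,
        compartments=(
            ("CD4", RepertoireSpec(n_clonotypes=60)),
            ("CD8", RepertoireSpec(n_clonotypes=60)),
        ),
        reference_size=150,
        seed=8,
    )
    cohort = generate_cohort(spec)
    assert len(cohort) == 2 * 2 * 2
    assert cohort.reference is not None and len(cohort.reference) >= 150
    slices = cohort.select("P01", "CD4")
    merged = merge_samples(slices)
    union = set()
    for s in slices:
        union |= {c.key for c in s.clonotypes}
    assert {c.key for c in merged.clonotypes} == union


def test_cd4_cd8_presets_order_ndn_lengths():
    """CD4-like junctions are longer than CD8-like in 20/20 seeds."""
    wins = 0
    for seed in range(20):
        r4 = generate_repertoire(cd4_til_spec(400, seed=seed), "a")
        r8 = generate_repertoire(cd8_til_spec(400, seed=seed), "b")
        if length_summary(r4).ndn_mean > length_summary(r8).ndn_mean:
            wins += 1
    assert wins >= 19


def test_mixed_initial_diversity_tracks_composition():
    lo = mixed_initial_repertoire(20.0, n_clonotypes=800, seed=3)
    hi = mixed_initial_repertoire(80.0, n_clonotypes=800, seed=3)
    from tilrep.stats import normalized_shannon_wiener

    assert normalized_shannon_wiener(hi).nsw < normalized_shannon_wiener(lo).nsw


def test_specificity_db_generation():
    spec = DbSpec(
        n_records=(("cancer", 10),),
        overlap_with_cohort=(("CASSLGGSGEQFF", "cancer", 0), ("CASTPNYSNQPQHF", "pathogens", 1)),
        seed=6,
    )
    db = generate_specificity_db(spec)
    assert generate_specificity_db(spec) == db  # deterministic
    cancer = [r for r in db if r.category == "cancer"]
    assert len(cancer) == 11
    assert any(r.cdr3_aa == "CASSLGGSGEQFF" for r in db)
    from tilrep.annotate import levenshtein

    assert any(
        r.category == "pathogens" and levenshtein(r.cdr3_aa, "CASTPNYSNQPQHF") == 1
        for r in db
    )
    with pytest.raises(ValueError, match="empty"):
        DbSpec().validate()
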