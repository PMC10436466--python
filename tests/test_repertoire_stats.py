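"""Diversity, convergent recombination, publicity and their crosstab."""

import math

import numpy as np
import pytest

from tilrep.io import collapse_by_aa
from tilrep.model import AAEntry, AARepertoire, Clonotype, Repertoire
from tilrep.stats import (
    convergence,
    crosstab_from_flags,
    normalized_shannon_wiener,
    public_sequences,
    publicity_convergence_crosstab,
)
from tilrep.synthetic import CohortSpec, RepertoireSpec, generate_cohort

from conftest import random_repertoire


def _rep_from_freqs(freqs):
    counts = [int(round(f * 10000)) for f in freqs]
    clones = [
        Clonotype(
            cdr3_nt=f"{'ACGT'[i % 4] * 3}{'ACG'[i % 3] * 3}" + "AAA" * i,
            cdr3_aa="X",
            v_call="V",
            j_call="J",
            count=c,
        )
        for i, c in enumerate(counts)
    ]
    return Repertoire("s", clones).normalized()


def test_nsw_uniform_is_one():
    res = normalized_shannon_wiener(_rep_from_freqs([0.25] * 4))
    assert res.nsw == pytest.approx(1.0)
    assert res.S == 4


def test_nsw_singleton_is_zero_by_convention():
    res = normalized_shannon_wiener(_rep_from_freqs([1.0]))
    assert res.nsw == 0.0 and res.H == 0.0 and res.S == 1


def test_nsw_frozen_example():
    # H = -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397208, nsw = H / ln 3
    res = normalized_shannon_wiener(_rep_from_freqs([0.5, 0.25, 0.25]))
    assert res.H == pytest.approx(1.039721, abs=1e-6)
    assert res.nsw == pytest.approx(0.946395, abs=1e-6)


def test_nsw_rejects_unnormalized():
    rep = _rep_from_freqs([0.5, 0.5])
    bad = Repertoire(
        "s",
        [Clonotype(c.cdr3_nt, c.cdr3_aa, c.v_call, c.j_call, count=c.count, freq=0.4) for c in rep.clonotypes],
    )
    with pytest.raises(ValueError, match="not normalized"):
        normalized_shannon_wiener(bad)


@pytest.mark.parametrize("seed", range(10))
def test_nsw_matches_bruteforce_oracle(seed):
    """High-precision independent accumulation agrees to 1e-12."""
    rng = np.random.default_rng(seed)
    rep = random_repertoire(rng, int(rng.integers(5, 60)))
    res = normalized_shannon_wiener(rep)
    h = -math.fsum(c.freq * math.log(c.freq) for c in rep.clonotypes if c.freq > 0)
    assert abs(res.H - h) < 1e-12
    assert abs(res.nsw - h / math.log(len(rep.clonotypes))) < 1e-12
    assert res.H <= math.log(res.S) + 1e-12


def _aa(entries):
    total = sum(c for _, c, _ in entries)
    return AARepertoire(
        "s", [AAEntry(a, c, c / total, v) for a, c, v in entries]
    )


def test_cr_level_counts_variants():
    aa = _aa([("A" * 8, 2, 2), ("C" * 8, 1, 1), ("D" * 8, 1, 1), ("E" * 8, 1, 1)])
    res = convergence(aa)
    assert res.cr_level == pytest.approx(1.25)
    assert res.convergent["A" * 8] and not res.convergent["C" * 8]


def test_cr_level_floor_is_one():
    aa = _aa([("A" * 8, 5, 1), ("C" * 8, 1, 1)])
    res = convergence(aa)
    assert res.cr_level == 1.0
    assert not any(res.convergent.values())


def test_cr_invariant_under_count_rescaling(small_repertoire):
    from dataclasses import replace

    aa1 = collapse_by_aa(small_repertoire)
    scaled = replace(
        small_repertoire,
        clonotypes=[replace(c, count=c.count * 7) for c in small_repertoire.clonotypes],
    ).normalized()
    aa2 = collapse_by_aa(scaled)
    assert convergence(aa1).cr_level == pytest.approx(convergence(aa2).cr_level)


def _publicity_cohort(n_patients=3, inject=(("CASSPGLICEQYF", 2),)):
    return generate_cohort(
        CohortSpec(
            n_patients=n_patients,
            slices_per_patient=2,
            compartments=(("CD4", RepertoireSpec(n_clonotypes=80)),),
            public_injection=inject,
            reference_size=100,
            seed=13,
        )
    )


def test_public_sequences_injected_flagged():
    cohort = _publicity_cohort()
    pub = public_sequences(cohort, "CD4")
    assert "CASSPGLICEQYF" in pub.public
    assert pub.share["CASSPGLICEQYF"] == 2
    assert 0 <= pub.percent_public <= 100
    assert pub.n_biopsies == 3


def test_public_share_ceiling_is_all_patients():
    cohort = _publicity_cohort(inject=(("CASSPGLICEQYF", 3),))
    pub = public_sequences(cohort, "CD4")
    assert pub.share["CASSPGLICEQYF"] == 3


def test_public_requires_two_biopsies():
    cohort = _publicity_cohort(n_patients=1, inject=())
    with pytest.raises(ValueError, match="2 biopsies"):
        public_sequences(cohort, "CD4")


def test_merging_slices_never_decreases_share():
    """Share counts are computed on patient-merged data: a sequence present
    in any slice of a patient counts for that patient exactly once."""
    from tilrep.model import Cohort

    cohort = _publicity_cohort()
    pub = public_sequences(cohort, "CD4")
    slice1_only = Cohort(
        [r for r in cohort.repertoires if "_S1_" in r.sample_id],
        reference=cohort.reference,
    )
    pub1 = public_sequences(slice1_only, "CD4")
    for aa, k in pub1.share.items():
        assert pub.share[aa] >= k


def test_crosstab_toy_counts():
    public = {"A": True, "B": True, "C": False, "D": False, "E": False}
    conv = {"A": True, "B": True, "C": False, "D": False, "E": False}
    ct = crosstab_from_flags(public, conv)
    assert (
        ct.public_convergent,
        ct.public_nonconvergent,
        ct.private_convergent,
        ct.private_nonconvergent,
    ) == (2, 0, 0, 3)
    assert ct.total == 5
    assert ct.pct_public_given_convergent == 100.0
    assert ct.pct_public_given_nonconvergent == 0.0


def test_crosstab_universe_mismatch_errors():
    with pytest.raises(ValueError, match="universes"):
        crosstab_from_flags({"A": True}, {"B": False})


def test_crosstab_on_cohort_public_more_convergent():
    """Injected publics carry two nt variants, so the public row concentrates
    in the convergent column."""
    cohort = _publicity_cohort()
    ct = publicity_convergence_crosstab(cohort, "CD4")
    assert ct.public_convergent >= 1
    assert ct.pct_public_given_convergent > ct.pct_public_given_nonconvergent


def test_crosstab_empty_public_row():
    cohort = _publicity_cohort(inject=())
    ct = publicity_convergence_crosstab(cohort, "CD4")
    if ct.public_convergent + ct.public_nonconvergent == 0:
        assert ct.total > 0
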