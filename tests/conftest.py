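import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tilrep.germline import AA_ALPHABET
from tilrep.model import Clonotype, Repertoire
from tilrep.synthetic import RepertoireSpec, generate_repertoire, reference_spec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def random_peptide(rng: np.random.Generator, lo: int = 5, hi: int = 18) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA_ALPHABET[int(k)] for k in rng.integers(0, 20, size=n))


def random_repertoire(rng: np.random.Generator, n: int = 30) -> Repertoire:
    """A hand-built repertoire with random counts/sequences, independent of
    the synthetic generator (for oracle-equivalence tests)."""
    clones = []
    seen = set()
    while len(clones) < n:
        aa = "C" + random_peptide(rng, 6, 14) + "F"
        nt = "".join(rng.choice(list("ACGT"), size=3 * len(aa)))
        if nt in seen:
            continue
        seen.add(nt)
        L = len(nt)
        v_end = int(rng.integers(3, L // 2))
        j_start = int(rng.integers(v_end, L - 3))
        clones.append(
            Clonotype(
                cdr3_nt=nt,
                cdr3_aa=aa,
                v_call=f"TRBV{int(rng.integers(1, 9))}",
                j_call=f"TRBJ{int(rng.integers(1, 7))}",
                count=int(rng.integers(1, 500)),
                v_end=v_end,
                j_start=j_start,
            )
        )
    return Repertoire(sample_id="random", clonotypes=clones).normalized()


@pytest.fixture
def rng():
    return np.random.default_rng(20230804)


@pytest.fixture
def small_repertoire():
    return generate_repertoire(
        reference_spec(n_clonotypes=120, seed=11, convergence_rate=0.1),
        "S1",
        patient_id="P01",
        compartment="CD4",
    )
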