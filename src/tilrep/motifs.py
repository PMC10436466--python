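"""Enrichment-based discovery of local CDR3aa motifs.

Short (3-7 residue) amino-acid patterns, optionally carrying one
single-residue wildcard ``%``, are enumerated from the CDR3 *interior*
(the first 3 and last 2 residues — germline-dominated positions — are
excluded) and scored against a background reference repertoire:

* *Fisher score* — one-sided Fisher exact p-value of the 2x2 table
  [carriers / non-carriers] x [sample / reference], counting distinct
  amino-acid clonotypes; small values mean sample enrichment.
* *Expansion score* — permutation p-value that the summed clonotype
  frequency of the motif's carriers exceeds that of random same-size
  clonotype sets; small values mean the motif sits in expanded clones.

Motifs passing both thresholds become clusters of all matching sample
sequences — groups with a high probability of sharing antigen
specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .model import AARepertoire

__all__ = [
    "WILDCARD",
    "validate_motif",
    "motif_matches",
    "enumerate_motifs",
    "MotifScore",
    "MotifCluster",
    "score_motif",
    "cluster_by_motifs",
    "motif_sharing",
]

WILDCARD = "%"
MIN_MOTIF_LEN = 3
MAX_MOTIF_LEN = 7

#: interior convention: germline-dominated flanks excluded from motif space
N_EXCLUDE = 3
C_EXCLUDE = 2


def validate_motif(pattern: str) -> None:
    """Grammar: length 3-7 over the 20-aa alphabet, at most one ``%``
    wildcard, never in the last position."""
    if not MIN_MOTIF_LEN <= len(pattern) <= MAX_MOTIF_LEN:
        raise ValueError(f"motif {pattern!r}: length must be {MIN_MOTIF_LEN}-{MAX_MOTIF_LEN}")
    if pattern.count(WILDCARD) > 1:
        raise ValueError(f"motif {pattern!r}: at most one wildcard allowed")
    if pattern.endswith(WILDCARD):
        raise ValueError(f"motif {pattern!r}: wildcard must not be the last position")
    from .germline import AA_ALPHABET

    bad = [ch for ch in pattern if ch != WILDCARD and ch not in AA_ALPHABET]
    if bad:
        raise ValueError(f"motif {pattern!r}: invalid residues {bad}")


def _interior(seq: str) -> str:
    if len(seq) <= N_EXCLUDE + C_EXCLUDE:
        return ""
    return seq[N_EXCLUDE : len(seq) - C_EXCLUDE]


def motif_matches(pattern: str, cdr3_aa: str, interior: bool = True) -> bool:
    """Wildcard-aware containment of ``pattern`` in a CDR3aa sequence
    (within the interior region by default)."""
    target = _interior(cdr3_aa) if interior else cdr3_aa
    m = len(pattern)
    if m > len(target):
        return False
    if WILDCARD not in pattern:
        return pattern in target
    for i in range(len(target) - m + 1):
        window = target[i : i + m]
        if all(pc == WILDCARD or pc == wc for pc, wc in zip(pattern, window)):
            return True
    return False


def enumerate_motifs(
    aa_sequences: Iterable[str],
    k_exact: Sequence[int] = (3, 4, 5),
    k_wild: Sequence[int] = (5, 6, 7),
) -> dict[str, set]:
    """Map every motif occurring in the sequences' CDR3 interiors to its
    (deduplicated) carrier set.

    Exact contiguous k-mers are taken for ``k_exact``; single-wildcard
    patterns replace one position (any but the last) of windows with
    lengths in ``k_wild``.  Sequences whose interior is shorter than the
    smallest k contribute nothing.
    """
    out: dict[str, set] = {}
    for seq in aa_sequences:
        interior = _interior(seq)
        n = len(interior)
        for k in k_exact:
            for i in range(n - k + 1):
                out.setdefault(interior[i : i + k], set()).add(seq)
        for k in k_wild:
            for i in range(n - k + 1):
                window = interior[i : i + k]
                for j in range(k - 1):  # wildcard anywhere but the last position
                    pattern = window[:j] + WILDCARD + window[j + 1 :]
                    out.setdefault(pattern, set()).add(seq)
    return out


@dataclass(frozen=True)
class MotifScore:
    fisher_score: float  # one-sided Fisher exact p, sample enrichment
    expansion_score: float  # permutation p, carrier frequency concentration
    support: tuple  # (n sample carriers, sample size, n ref carriers, ref size)


@dataclass(frozen=True)
class MotifCluster:
    motif: str
    members: tuple  # of (cdr3_aa, freq)
    biopsy: str
    score: MotifScore

    @property
    def n_members(self) -> int:
        return len(self.members)


def _fisher(a: int, n_sample: int, c: int, n_ref: int) -> float:
    table = [[a, c], [n_sample - a, n_ref - c]]
    return float(fisher_exact(table, alternative="greater")[1])


def _null_carrier_sums(
    freqs: np.ndarray, m: int, b: int, rng: np.random.Generator
) -> np.ndarray:
    """B sums of m frequencies drawn without replacement."""
    n = len(freqs)
    out = np.empty(b, dtype=float)
    for i in range(b):
        idx = rng.choice(n, size=m, replace=False)
        out[i] = freqs[idx].sum()
    return out


def _expansion_p(observed: float, null_sums: np.ndarray) -> float:
    b = len(null_sums)
    return (1.0 + int((null_sums >= observed - 1e-15).sum())) / (b + 1.0)


def score_motif(
    motif: str,
    sample_aa_rep: AARepertoire,
    reference_aa_rep: AARepertoire,
    b: int = 1000,
    seed: int = 0,
    _null_cache: Optional[dict] = None,
    _ref_carrier_count: Optional[int] = None,
) -> MotifScore:
    """Fisher and expansion scores of one motif (see module docstring)."""
    if len(reference_aa_rep) == 0:
        raise ValueError("reference repertoire is empty")
    validate_motif(motif)
    carriers = [e for e in sample_aa_rep.entries if motif_matches(motif, e.cdr3_aa)]
    if not carriers:
        raise ValueError(f"motif {motif!r} has no carrier in the sample")
    a = len(carriers)
    n_sample = sample_aa_rep.richness
    if _ref_carrier_count is None:
        c = sum(1 for e in reference_aa_rep.entries if motif_matches(motif, e.cdr3_aa))
    else:
        c = _ref_carrier_count
    n_ref = reference_aa_rep.richness
    fisher = _fisher(a, n_sample, c, n_ref)

    freqs = np.asarray([e.freq for e in sample_aa_rep.entries], dtype=float)
    observed = float(sum(e.freq for e in carriers))
    rng = np.random.default_rng(seed)
    if _null_cache is not None and a in _null_cache:
        null_sums = _null_cache[a]
    else:
        null_sums = _null_carrier_sums(freqs, a, b, rng)
        if _null_cache is not None:
            _null_cache[a] = null_sums
    expansion = _expansion_p(observed, null_sums)
    return MotifScore(
        fisher_score=fisher,
        expansion_score=expansion,
        support=(a, n_sample, c, n_ref),
    )


def cluster_by_motifs(
    sample_aa_rep: AARepertoire,
    reference_aa_rep: AARepertoire,
    fisher_max: float = 0.5,
    expansion_max: float = 0.5,
    k_exact: Sequence[int] = (3, 4, 5),
    k_wild: Sequence[int] = (5, 6, 7),
    min_carriers: int = 2,
    b: int = 1000,
    seed: int = 0,
) -> list[MotifCluster]:
    """All motifs passing both score thresholds, as clusters of their
    matching sample sequences.

    The expansion permutation null is shared between motifs with the same
    carrier count (the null depends only on the subset size).  Exact
    motifs fully contained in a passing longer motif with an identical
    carrier set are suppressed as redundant.
    """
    for name, thr in (("fisher_max", fisher_max), ("expansion_max", expansion_max)):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must be in (0,1], got {thr}")
    if len(reference_aa_rep) == 0:
        raise ValueError("reference repertoire is empty")

    sample_seqs = sample_aa_rep.sequences
    freq_by_seq = {e.cdr3_aa: e.freq for e in sample_aa_rep.entries}
    sample_motifs = enumerate_motifs(sample_seqs, k_exact, k_wild)
    ref_motifs = enumerate_motifs(reference_aa_rep.sequences, k_exact, k_wild)

    n_sample = sample_aa_rep.richness
    n_ref = reference_aa_rep.richness
    freqs = np.asarray([e.freq for e in sample_aa_rep.entries], dtype=float)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    passing: list[MotifCluster] = []
    for motif in sorted(sample_motifs):
        carriers = sample_motifs[motif]
        a = len(carriers)
        if a < min_carriers:
            continue
        c = len(ref_motifs.get(motif, ()))
        fisher = _fisher(a, n_sample, c, n_ref)
        if fisher > fisher_max:
            continue
        observed = float(sum(freq_by_seq[s] for s in carriers))
        if a not in null_cache:
            null_cache[a] = _null_carrier_sums(freqs, a, b, rng)
        expansion = _expansion_p(observed, null_cache[a])
        if expansion > expansion_max:
            continue
        members = tuple(sorted((s, freq_by_seq[s]) for s in carriers))
        passing.append(
            MotifCluster(
                motif=motif,
                members=members,
                biopsy=sample_aa_rep.patient_id or sample_aa_rep.sample_id,
                score=MotifScore(fisher, expansion, (a, n_sample, c, n_ref)),
            )
        )

    # suppress nested exact motifs with identical carrier sets
    carrier_sets = {cl.motif: frozenset(s for s, _ in cl.members) for cl in passing}
    kept = []
    for cl in passing:
        if WILDCARD not in cl.motif:
            redundant = any(
                other.motif != cl.motif
                and len(other.motif) > len(cl.motif)
                and cl.motif in other.motif
                and carrier_sets[other.motif] == carrier_sets[cl.motif]
                for other in passing
            )
            if redundant:
                continue
        kept.append(cl)
    kept.sort(key=lambda cl: (cl.score.fisher_score, cl.motif))
    return kept


def motif_sharing(clusters_by_biopsy: dict) -> pd.DataFrame:
    """UpSet-style motif x biopsy incidence table.

    One row per motif, one 0/1 column per biopsy, plus ``n_biopsies``
    (the motif's share count) — motifs with ``n_biopsies >= 2`` are the
    shared ones.
    """
    biopsies = sorted(clusters_by_biopsy)
    rows: dict[str, dict] = {}
    for biopsy in biopsies:
        for cl in clusters_by_biopsy[biopsy]:
            rows.setdefault(cl.motif, {bp: 0 for bp in biopsies})[biopsy] = 1
    df = pd.DataFrame.from_dict(rows, orient="index", columns=biopsies).fillna(0).astype(int)
    df.index.name = "motif"
    df = df.sort_index()
    df["n_biopsies"] = df[biopsies].sum(axis=1) if biopsies else 0
    return df
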