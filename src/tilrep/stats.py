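"""Repertoire-level diversity, convergence and publicity statistics.

* Normalized Shannon-Wiener diversity: H / ln(S) over clonotype
  frequencies, 1 for a maximally even repertoire, 0 for a monoclonal one
  (S = 1 is defined as 0 by convention — the maximally clonal limit).
* Convergent recombination (CR): the mean number of distinct CDR3nt
  variants per distinct CDR3aa sequence; a CDR3aa is *convergent* when at
  least two nucleotide rearrangements encode it.
* Publicity: a CDR3aa is *public* when it appears in at least
  ``min_share`` patient-merged biopsies of a compartment, *private*
  otherwise; publicity is always computed after per-patient slice merging
  (sharing between slices of one biopsy never counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

from .io import collapse_by_aa, merge_samples
from .model import AARepertoire, Cohort, Repertoire, FREQ_TOL

__all__ = [
    "DiversityResult",
    "ConvergenceResult",
    "PublicityResult",
    "CrossTab",
    "normalized_shannon_wiener",
    "convergence",
    "public_sequences",
    "publicity_convergence_crosstab",
    "crosstab_from_flags",
]


@dataclass(frozen=True)
class DiversityResult:
    H: float  # Shannon entropy, nats
    S: int  # richness
    nsw: float  # normalized Shannon-Wiener index in [0,1]


@dataclass(frozen=True)
class ConvergenceResult:
    cr_level: float  # distinct nt / distinct aa, >= 1
    nt_variant_counts: dict  # cdr3_aa -> n distinct nt
    convergent: dict  # cdr3_aa -> bool (>= 2 variants)


@dataclass(frozen=True)
class PublicityResult:
    share: dict  # cdr3_aa -> n distinct biopsies carrying it
    public: set  # cdr3_aa with share >= min_share
    min_share: int
    n_biopsies: int
    percent_public: float  # of distinct aa sequences


@dataclass(frozen=True)
class CrossTab:
    """2x2 publicity x convergence counts over one aa universe."""

    public_convergent: int
    public_nonconvergent: int
    private_convergent: int
    private_nonconvergent: int

    @property
    def total(self) -> int:
        return (
            self.public_convergent
            + self.public_nonconvergent
            + self.private_convergent
            + self.private_nonconvergent
        )

    @property
    def pct_public_given_convergent(self) -> float:
        denom = self.public_convergent + self.private_convergent
        return 100.0 * self.public_convergent / denom if denom else math.nan

    @property
    def pct_public_given_nonconvergent(self) -> float:
        denom = self.public_nonconvergent + self.private_nonconvergent
        return 100.0 * self.public_nonconvergent / denom if denom else math.nan


def normalized_shannon_wiener(
    rep: Union[Repertoire, AARepertoire], level: str = "nt"
) -> DiversityResult:
    """Shannon entropy and normalized Shannon-Wiener index.

    ``level="nt"`` treats each nucleotide clonotype separately (the
    default); ``level="aa"`` collapses to amino-acid clonotypes first.
    Frequencies must already be normalized.
    """
    if level not in ("nt", "aa"):
        raise ValueError(f"unknown level {level!r}")
    if isinstance(rep, AARepertoire):
        freqs = [e.freq for e in rep.entries]
    elif level == "aa":
        freqs = [e.freq for e in collapse_by_aa(rep).entries]
    else:
        freqs = [c.freq for c in rep.clonotypes]
    if not freqs:
        raise ValueError("empty repertoire")
    f = np.asarray(freqs, dtype=float)
    if abs(f.sum() - 1.0) > FREQ_TOL:
        raise ValueError(
            f"frequencies not normalized (sum={f.sum():.8f}); call .normalized() first"
        )
    nz = f[f > 0]
    h = float(-(nz * np.log(nz)).sum())
    s = len(f)
    nsw = h / math.log(s) if s >= 2 else 0.0
    return DiversityResult(H=h, S=s, nsw=nsw)


def convergence(aa_rep: AARepertoire) -> ConvergenceResult:
    """CR level and per-CDR3aa convergent flags of a collapsed repertoire."""
    if len(aa_rep) == 0:
        raise ValueError(f"sample {aa_rep.sample_id}: empty repertoire")
    variant_counts = {e.cdr3_aa: e.nt_variant_count for e in aa_rep.entries}
    total_nt = sum(variant_counts.values())
    cr = total_nt / len(variant_counts)
    flags = {aa: (n >= 2) for aa, n in variant_counts.items()}
    return ConvergenceResult(cr_level=cr, nt_variant_counts=variant_counts, convergent=flags)


def _patient_merged_aa(cohort: Cohort, compartment: str) -> dict[str, AARepertoire]:
    """Per-patient slice-merged, aa-collapsed repertoires of one compartment."""
    out: dict[str, AARepertoire] = {}
    for patient in cohort.patients:
        reps = cohort.select(patient, compartment)
        if reps:
            out[patient] = collapse_by_aa(merge_samples(reps))
    return out


def public_sequences(
    cohort: Cohort, compartment: str, min_share: int = 2
) -> PublicityResult:
    """Share counts over patient-merged biopsies of ``compartment``."""
    if min_share < 2:
        raise ValueError("min_share must be >= 2")
    merged = _patient_merged_aa(cohort, compartment)
    if len(merged) < 2:
        raise ValueError(
            f"compartment {compartment!r}: publicity needs >= 2 biopsies, "
            f"found {len(merged)}"
        )
    share: dict[str, int] = {}
    for aa_rep in merged.values():
        for e in aa_rep.entries:
            share[e.cdr3_aa] = share.get(e.cdr3_aa, 0) + 1
    public = {aa for aa, k in share.items() if k >= min_share}
    pct = 100.0 * len(public) / len(share) if share else 0.0
    return PublicityResult(
        share=share,
        public=public,
        min_share=min_share,
        n_biopsies=len(merged),
        percent_public=pct,
    )


def crosstab_from_flags(public_flags: dict, convergent_flags: dict) -> CrossTab:
    """Build the 2x2 publicity x convergence table from per-sequence flags
    computed over the same aa universe."""
    if set(public_flags) != set(convergent_flags):
        raise ValueError("publicity and convergence flags cover different aa universes")
    cells = [0, 0, 0, 0]  # pc, pn, rc, rn
    for aa, is_public in public_flags.items():
        is_conv = convergent_flags[aa]
        idx = (0 if is_public else 2) + (0 if is_conv else 1)
        cells[idx] += 1
    return CrossTab(*cells)


def publicity_convergence_crosstab(
    cohort: Cohort, compartment: str, min_share: int = 2
) -> CrossTab:
    """Publicity x convergence cross-tabulation for one compartment.

    The universe is the union of patient-merged CDR3aa sequences; a
    sequence is convergent when some patient's merged repertoire carries
    at least two nucleotide variants of it.
    """
    merged = _patient_merged_aa(cohort, compartment)
    pub = public_sequences(cohort, compartment, min_share=min_share)
    convergent: dict[str, bool] = {aa: False for aa in pub.share}
    for aa_rep in merged.values():
        for e in aa_rep.entries:
            if e.nt_variant_count >= 2:
                convergent[e.cdr3_aa] = True
    public_flags = {aa: (aa in pub.public) for aa in pub.share}
    return crosstab_from_flags(public_flags, convergent)
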