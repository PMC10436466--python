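"""CDR3 length statistics and physicochemical profiles.

Two families of descriptors:

* Lengths — CDR3nt length and N(D)Nnt length (nucleotides between the end
  of the V-germline and the start of the J-germline contribution, i.e.
  N + D + N), summarized per sample both unweighted over distinct
  clonotypes and weighted by clonotype frequency.
* Physicochemistry — the mean value of a residue property scale over the
  central 5-mer of the CDR3aa sequence, frequency-weighted over the
  amino-acid-collapsed repertoire and normalized to the 5-residue window.

Registered property scales: ``charge`` (K/R = +1, D/E = -1 at
physiological pH, H treated as neutral), ``hydropathy`` (Kyte-Doolittle),
and ``polarity`` (binary indicator of polar residues).  All are swappable
via :func:`register_scale`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from types import MappingProxyType
from typing import Optional

import numpy as np

from .germline import AA_ALPHABET
from .model import AARepertoire, Clonotype, Repertoire

__all__ = [
    "PropertyScale",
    "SCALES",
    "register_scale",
    "get_scale",
    "LengthSummary",
    "ndn_length",
    "central_kmer",
    "property_score",
    "repertoire_property_profile",
    "length_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyScale:
    """An immutable residue -> value map over the 20-aa alphabet."""

    name: str
    values: MappingProxyType

    def __post_init__(self) -> None:
        missing = [a for a in AA_ALPHABET if a not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {missing}")

    def __getitem__(self, residue: str) -> float:
        try:
            return self.values[residue]
        except KeyError:
            raise KeyError(f"scale {self.name!r}: unknown residue {residue!r}") from None


def _scale(name: str, values: dict) -> PropertyScale:
    return PropertyScale(name=name, values=MappingProxyType(dict(values)))


_CHARGE = {a: 0.0 for a in AA_ALPHABET}
_CHARGE.update({"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.0})

# Kyte & Doolittle hydropathy index
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_POLAR_SET = set("NQSTYCHKRDE")
_POLARITY = {a: (1.0 if a in _POLAR_SET else 0.0) for a in AA_ALPHABET}

SCALES: dict[str, PropertyScale] = {
    "charge": _scale("charge", _CHARGE),
    "hydropathy": _scale("hydropathy", _HYDROPATHY),
    "polarity": _scale("polarity", _POLARITY),
}


def register_scale(scale: PropertyScale) -> None:
    if scale.name in SCALES:
        raise ValueError(f"scale {scale.name!r} already registered (scales are immutable)")
    SCALES[scale.name] = scale


def get_scale(scale) -> PropertyScale:
    if isinstance(scale, PropertyScale):
        return scale
    return SCALES[scale]


def ndn_length(clonotype: Clonotype) -> Optional[int]:
    """N(D)N length in nt: ``j_start - v_end``; None when the reference
    points are missing (never coerced to 0)."""
    if clonotype.v_end is None or clonotype.j_start is None:
        return None
    if clonotype.v_end > clonotype.j_start:
        raise ValueError(
            f"clonotype {clonotype.cdr3_nt!r}: v_end {clonotype.v_end} > "
            f"j_start {clonotype.j_start}"
        )
    return clonotype.j_start - clonotype.v_end


def central_kmer(cdr3_aa: str, k: int = 5) -> Optional[str]:
    """The central ``k`` residues of a CDR3aa sequence.

    The window starts at ``floor((L-k)/2)`` so even-length ties shift
    toward the N-terminus.  Sequences shorter than ``k`` return None (skip
    signal for callers).
    """
    if len(cdr3_aa) < k:
        return None
    start = (len(cdr3_aa) - k) // 2
    return cdr3_aa[start : start + k]


def property_score(peptide: str, scale) -> float:
    """Mean property value over the peptide (normalized to its length)."""
    if not peptide:
        raise ValueError("empty peptide")
    sc = get_scale(scale)
    return sum(sc[a] for a in peptide) / len(peptide)


def repertoire_property_profile(aa_rep: AARepertoire, scale, k: int = 5) -> float:
    """Frequency-weighted mean central-``k``-mer property of a repertoire.

    Sequences shorter than ``k`` are skipped (with a logged warning) and
    the frequencies of the retained set are renormalized.
    """
    if len(aa_rep) == 0:
        raise ValueError(f"sample {aa_rep.sample_id}: empty repertoire")
    sc = get_scale(scale)
    weights = []
    scores = []
    skipped = 0
    for entry in aa_rep.entries:
        kmer = central_kmer(entry.cdr3_aa, k)
        if kmer is None:
            skipped += 1
            continue
        weights.append(entry.freq)
        scores.append(property_score(kmer, sc))
    if not weights:
        raise ValueError(
            f"sample {aa_rep.sample_id}: no CDR3aa sequence of length >= {k}"
        )
    if skipped:
        log.warning(
            "sample %s: skipped %d CDR3aa sequences shorter than %d residues",
            aa_rep.sample_id,
            skipped,
            k,
        )
    w = np.asarray(weights, dtype=float)
    s = np.asarray(scores, dtype=float)
    return float((w * s).sum() / w.sum())


@dataclass(frozen=True)
class LengthSummary:
    """Per-sample CDR3nt and N(D)Nnt length statistics.

    Unweighted statistics treat each distinct clonotype once; weighted
    means use clonotype frequencies.  N(D)N fields are NaN when no
    clonotype carries reference points.
    """

    sample_id: str
    compartment: str
    n: int
    n_ndn: int
    cdr3nt_mean: float
    cdr3nt_sd: float
    cdr3nt_wmean: float
    ndn_mean: float
    ndn_sd: float
    ndn_wmean: float


def _mean_sd_wmean(values: list[float], weights: list[float]) -> tuple[float, float, float]:
    if not values:
        return (math.nan, math.nan, math.nan)
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    wmean = float((v * w).sum() / w.sum()) if w.sum() > 0 else math.nan
    return mean, sd, wmean


def length_summary(rep: Repertoire) -> LengthSummary:
    """CDR3nt and N(D)Nnt length summary of one repertoire; N(D)N uses only
    clonotypes with reference points present."""
    if len(rep) == 0:
        raise ValueError(f"sample {rep.sample_id}: empty repertoire")
    cdr3_lens = [float(len(c.cdr3_nt)) for c in rep.clonotypes]
    cdr3_w = [c.freq for c in rep.clonotypes]
    ndn_lens: list[float] = []
    ndn_w: list[float] = []
    for c in rep.clonotypes:
        nl = ndn_length(c)
        if nl is not None:
            ndn_lens.append(float(nl))
            ndn_w.append(c.freq)
    c_mean, c_sd, c_wmean = _mean_sd_wmean(cdr3_lens, cdr3_w)
    n_mean, n_sd, n_wmean = _mean_sd_wmean(ndn_lens, ndn_w)
    return LengthSummary(
        sample_id=rep.sample_id,
        compartment=rep.compartment,
        n=len(rep),
        n_ndn=len(ndn_lens),
        cdr3nt_mean=c_mean,
        cdr3nt_sd=c_sd,
        cdr3nt_wmean=c_wmean,
        ndn_mean=n_mean,
        ndn_sd=n_sd,
        ndn_wmean=n_wmean,
    )
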