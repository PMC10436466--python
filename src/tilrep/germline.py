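"""Toy germline segment set and codon utilities.

The simulator does not aim at realistic human gene-usage frequencies; it
only needs V- and J-derived CDR3 flanks so that generated rearrangements
have the canonical ``C...F`` CDR3 structure, gene calls, and well-defined
boundaries for the N(D)N region.  The flanks below mimic the conserved
amino-acid prefixes/suffixes of common human TRBV/TRBJ segments, encoded
with a fixed codon choice so that generation is deterministic.

Codon tables come from the standard genetic code (NCBI table 1).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "AA_ALPHABET",
    "CODON_TO_AA",
    "AA_TO_CODONS",
    "PREFERRED_CODON",
    "TRB_V_FLANKS",
    "TRB_J_FLANKS",
    "TRB_D_NAME",
    "translate",
    "reverse_translate",
    "synonymous_codon",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_table = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

#: deterministic codon used by :func:`reverse_translate`
PREFERRED_CODON: dict[str, str] = {aa: codons[0] for aa, codons in AA_TO_CODONS.items()}


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide string; trailing partial codons are
    marked with ``_`` (frameshift marker, VDJTools convention)."""
    n = len(nt) - len(nt) % 3
    aa = "".join(CODON_TO_AA[nt[i : i + 3]] for i in range(0, n, 3))
    if len(nt) % 3:
        aa += "_"
    return aa


def reverse_translate(aa: str, rng: Optional[np.random.Generator] = None) -> str:
    """Encode a peptide as DNA, with the fixed preferred codon per residue
    or, if ``rng`` is given, a random synonymous codon per position."""
    if rng is None:
        return "".join(PREFERRED_CODON[a] for a in aa)
    out = []
    for a in aa:
        codons = AA_TO_CODONS[a]
        out.append(codons[int(rng.integers(len(codons)))])
    return "".join(out)


def synonymous_codon(codon: str, rng: np.random.Generator) -> Optional[str]:
    """A codon encoding the same residue but differing from ``codon``,
    or None if the residue has a single codon."""
    options = [c for c in AA_TO_CODONS[CODON_TO_AA[codon]] if c != codon]
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _enc(aa: str) -> str:
    return "".join(PREFERRED_CODON[a] for a in aa)


# (gene call, nt flank) pairs.  V flanks are the 5' CDR3 contribution
# (starting at the conserved cysteine); J flanks the 3' contribution
# (ending at the conserved phenylalanine).
TRB_V_FLANKS: list[tuple[str, str]] = [
    ("TRBV4-1", _enc("CASSQ")),
    ("TRBV5-1", _enc("CASSL")),
    ("TRBV6-5", _enc("CASSY")),
    ("TRBV7-2", _enc("CASSS")),
    ("TRBV9", _enc("CASSV")),
    ("TRBV19", _enc("CASSI")),
    ("TRBV20-1", _enc("CSARD")),
    ("TRBV28", _enc("CASSF")),
]

TRB_J_FLANKS: list[tuple[str, str]] = [
    ("TRBJ1-1", _enc("NTEAFF")),
    ("TRBJ1-2", _enc("NYGYTF")),
    ("TRBJ2-1", _enc("YNEQFF")),
    ("TRBJ2-3", _enc("STDTQYF")),
    ("TRBJ2-5", _enc("QETQYF")),
    ("TRBJ2-7", _enc("SYEQYF")),
]

TRB_D_NAME = "TRBD1"
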