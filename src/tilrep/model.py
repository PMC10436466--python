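"""Core in-memory containers for clonotype repertoires.

The unit of observation is the clonotype: a unique V(D)J rearrangement keyed
by its CDR3 nucleotide sequence plus V/J gene calls, carried with a read
count and its within-sample frequency.  A ``Repertoire`` is one sample's
clonotype list plus metadata (patient, compartment, chain); an
``AARepertoire`` is its amino-acid-collapsed view; a ``Cohort`` groups
repertoires by patient/biopsy and compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "Clonotype",
    "Repertoire",
    "AAEntry",
    "AARepertoire",
    "Cohort",
    "FREQ_TOL",
]

#: tolerance on |sum of frequencies - 1| after normalization
FREQ_TOL = 1e-6


@dataclass(frozen=True)
class Clonotype:
    """One nucleotide-level rearrangement.

    ``v_end``/``d_start``/``d_end``/``j_start`` are 0-based, half-open
    offsets *within* ``cdr3_nt`` marking the germline contribution
    boundaries; ``None`` means the aligner did not report the point.  The
    N(D)N region (non-templated plus D-derived nucleotides) spans
    ``[v_end, j_start)``.
    """

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    d_call: Optional[str] = None
    count: int = 1
    freq: float = 0.0
    v_end: Optional[int] = None
    d_start: Optional[int] = None
    d_end: Optional[int] = None
    j_start: Optional[int] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative count for clonotype {self.cdr3_nt!r}")
        if not (0.0 <= self.freq <= 1.0 + FREQ_TOL):
            raise ValueError(f"freq {self.freq} outside [0,1] for {self.cdr3_nt!r}")
        if self.v_end is not None and self.j_start is not None:
            if not (0 <= self.v_end <= len(self.cdr3_nt)) or not (
                0 <= self.j_start <= len(self.cdr3_nt)
            ):
                raise ValueError(
                    f"reference points outside CDR3 for {self.cdr3_nt!r}"
                )

    @property
    def key(self) -> tuple:
        """Identity key used for merging and decontamination: nt + V + J."""
        return (self.cdr3_nt, self.v_call, self.j_call)


@dataclass
class Repertoire:
    """A sample's clonotype list with its metadata."""

    sample_id: str
    clonotypes: list[Clonotype]
    patient_id: str = ""
    compartment: str = ""
    chain: str = "TRB"

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def freq_sum(self) -> float:
        return sum(c.freq for c in self.clonotypes)

    def normalized(self) -> "Repertoire":
        """Return a copy with frequencies recomputed from counts.

        If every count is zero the existing frequencies are rescaled to sum
        to one instead (frequency-only tables).
        """
        total = self.total_count
        if total > 0:
            clones = [replace(c, freq=c.count / total) for c in self.clonotypes]
        else:
            fsum = self.freq_sum()
            if fsum <= 0:
                raise ValueError(f"sample {self.sample_id}: no counts and no frequencies")
            clones = [replace(c, freq=c.freq / fsum) for c in self.clonotypes]
        return replace(self, clonotypes=clones)

    def sorted(self) -> "Repertoire":
        """Canonical order: descending count, ties by cdr3_nt lexicographic."""
        clones = sorted(self.clonotypes, key=lambda c: (-c.count, c.cdr3_nt))
        return replace(self, clonotypes=clones)


@dataclass(frozen=True)
class AAEntry:
    """One amino-acid clonotype after nucleotide collapse."""

    cdr3_aa: str
    count: int
    freq: float
    nt_variant_count: int

    def __post_init__(self) -> None:
        if self.nt_variant_count < 1:
            raise ValueError(f"nt_variant_count < 1 for {self.cdr3_aa!r}")


@dataclass
class AARepertoire:
    """Amino-acid-collapsed repertoire: entries keyed by CDR3aa."""

    sample_id: str
    entries: list[AAEntry]
    patient_id: str = ""
    compartment: str = ""
    chain: str = "TRB"

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[AAEntry]:
        return iter(self.entries)

    @property
    def richness(self) -> int:
        """S: number of distinct CDR3aa sequences."""
        return len(self.entries)

    @property
    def sequences(self) -> list[str]:
        return [e.cdr3_aa for e in self.entries]

    def freq_sum(self) -> float:
        return sum(e.freq for e in self.entries)


@dataclass
class Cohort:
    """A collection of repertoires with patient/compartment grouping.

    ``reference`` optionally carries a background repertoire used for motif
    enrichment scoring.
    """

    repertoires: list[Repertoire]
    reference: Optional[Repertoire] = None

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    @property
    def patients(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.repertoires:
            seen.setdefault(r.patient_id, None)
        return list(seen)

    @property
    def compartments(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.repertoires:
            seen.setdefault(r.compartment, None)
        return list(seen)

    def by_patient(self, patient_id: str) -> list[Repertoire]:
        return [r for r in self.repertoires if r.patient_id == patient_id]

    def by_compartment(self, compartment: str) -> list[Repertoire]:
        return [r for r in self.repertoires if r.compartment == compartment]

    def select(self, patient_id: str, compartment: str) -> list[Repertoire]:
        return [
            r
            for r in self.repertoires
            if r.patient_id == patient_id and r.compartment == compartment
        ]

    def validate(self) -> None:
        ids = [r.sample_id for r in self.repertoires]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id within cohort")
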