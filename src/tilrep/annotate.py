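"""Specificity-database matching and motif-based annotation propagation.

Candidate CDR3aa sequences (high-frequency, public, or motif-clustered)
are compared with a specificity database — a catalogue of CDR3aa
sequences with a reported pathological context (allergy, autoimmunity,
cancer, pathogens) — at Levenshtein distance <= 1.  Sequences whose
motif cluster contains a direct cancer match are then annotated as
putatively tumor-associated, propagating the database hit to every
member of the cluster.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import edlib
import pandas as pd

from .model import AARepertoire, Cohort
from .motifs import MotifCluster
from .stats import PublicityResult, public_sequences

__all__ = [
    "SpecificityRecord",
    "DbMatch",
    "CandidateSets",
    "levenshtein",
    "read_specificity_db",
    "write_specificity_db",
    "match_database",
    "candidate_sets",
    "annotate_clusters",
]

CATEGORIES = ("allergy", "autoimmunity", "cancer", "pathogens")


@dataclass(frozen=True)
class SpecificityRecord:
    """One database entry: a CDR3aa with its reported response category."""

    cdr3_aa: str
    category: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class DbMatch:
    query: str
    record: SpecificityRecord
    distance: int


@dataclass(frozen=True)
class CandidateSets:
    """The three (overlapping) candidate sequence subgroups."""

    high_freq: frozenset
    public: frozenset
    clustered: frozenset
    freq_threshold: float

    @property
    def sizes(self) -> dict:
        return {
            "high_freq": len(self.high_freq),
            "public": len(self.public),
            "clustered": len(self.clustered),
        }

    @property
    def union(self) -> frozenset:
        return self.high_freq | self.public | self.clustered


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    return int(edlib.align(a, b, task="distance")["editDistance"])


def read_specificity_db(path: Union[str, os.PathLike]) -> list[SpecificityRecord]:
    """Read a database CSV with header ``cdr3aa,category,source``."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"cdr3aa", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns {sorted(required)}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(
                    SpecificityRecord(
                        cdr3_aa=row["cdr3aa"],
                        category=row["category"],
                        source=row.get("source", "") or "",
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row {i}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: empty database")
    return records


def write_specificity_db(
    records: Sequence[SpecificityRecord], path: Union[str, os.PathLike]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cdr3aa", "category", "source"])
        for rec in records:
            writer.writerow([rec.cdr3_aa, rec.category, rec.source])


def match_database(
    queries: Iterable[str],
    db: Sequence[SpecificityRecord],
    max_dist: int = 1,
) -> dict[str, list[DbMatch]]:
    """All (query, record) pairs at Levenshtein distance <= ``max_dist``.

    A length pre-filter (|length difference| <= max_dist) is applied
    before computing distances.  Every query appears in the result, with
    an empty match list when nothing is close enough.
    """
    if not db:
        raise ValueError("empty specificity database")
    by_len: dict[int, list[SpecificityRecord]] = {}
    for rec in db:
        by_len.setdefault(len(rec.cdr3_aa), []).append(rec)

    out: dict[str, list[DbMatch]] = {}
    for q in queries:
        if q in out:
            continue
        hits: list[DbMatch] = []
        for length in range(len(q) - max_dist, len(q) + max_dist + 1):
            for rec in by_len.get(length, ()):
                d = levenshtein(q, rec.cdr3_aa)
                if d <= max_dist:
                    hits.append(DbMatch(query=q, record=rec, distance=d))
        hits.sort(key=lambda m: (m.distance, m.record.cdr3_aa, m.record.category))
        out[q] = hits
    return out


def candidate_sets(
    aa_rep: AARepertoire,
    cohort: Optional[Cohort],
    clusters: Sequence[MotifCluster],
    freq_threshold: float = 0.001,
    compartment: Optional[str] = None,
) -> CandidateSets:
    """The three candidate subgroups over one compartment's aa universe:
    sequences above ``freq_threshold``, public sequences, and members of
    passing motif clusters."""
    if not 0.0 < freq_threshold < 1.0:
        raise ValueError(f"freq_threshold must be in (0,1), got {freq_threshold}")
    high = frozenset(e.cdr3_aa for e in aa_rep.entries if e.freq > freq_threshold)
    if cohort is not None:
        comp = compartment if compartment is not None else aa_rep.compartment
        pub: frozenset = frozenset(public_sequences(cohort, comp).public)
    else:
        pub = frozenset()
    clustered = frozenset(s for cl in clusters for s, _f in cl.members)
    return CandidateSets(
        high_freq=high, public=pub, clustered=clustered, freq_threshold=freq_threshold
    )


def annotate_clusters(
    clusters: Sequence[MotifCluster],
    matches: dict[str, list[DbMatch]],
    propagate_categories: Sequence[str] = ("cancer",),
) -> pd.DataFrame:
    """Per-sequence annotation table with motif-based propagation.

    A cluster member with a direct match in a propagating category
    (cancer by default — the putatively tumor-associated call) marks every
    other member of its cluster as annotated in that category with the
    ``propagated`` flag; direct matches in other categories are recorded
    but not propagated.  Columns: ``cdr3aa, motif, biopsy, frequency,
    categories, direct, propagated, propagating_motif``.
    """
    for cat in propagate_categories:
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
    rows = []
    for cl in clusters:
        member_cats = {
            s: sorted({m.record.category for m in matches.get(s, [])})
            for s, _f in cl.members
        }
        propagate: set = set()
        for cats in member_cats.values():
            propagate.update(c for c in cats if c in propagate_categories)
        for s, f in cl.members:
            direct = member_cats[s]
            prop = sorted(propagate - set(direct))
            if not direct and not prop:
                continue
            rows.append(
                {
                    "cdr3aa": s,
                    "motif": cl.motif,
                    "biopsy": cl.biopsy,
                    "frequency": f,
                    "categories": ";".join(sorted(set(direct) | set(prop))),
                    "direct": ";".join(direct),
                    "propagated": ";".join(prop),
                    "propagating_motif": cl.motif if prop else "",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cdr3aa",
            "motif",
            "biopsy",
            "frequency",
            "categories",
            "direct",
            "propagated",
            "propagating_motif",
        ],
    )
    return df.sort_values(["motif", "cdr3aa"], kind="mergesort").reset_index(drop=True)


def category_counts(annotation: pd.DataFrame) -> pd.DataFrame:
    """Direct vs direct+propagated sequence counts per category, mirroring
    the clustered vs clustered-plus-annotation comparison."""
    counts = []
    for cat in CATEGORIES:
        direct = annotation[
            annotation["direct"].str.split(";").apply(lambda cs: cat in cs)
        ]["cdr3aa"].nunique()
        total = annotation[
            annotation["categories"].str.split(";").apply(lambda cs: cat in cs)
        ]["cdr3aa"].nunique()
        counts.append({"category": cat, "direct": direct, "direct_plus_propagated": total})
    return pd.DataFrame(counts)
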