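"""Clonotype table IO and preprocessing.

Two dialects are supported, matching the toolchain that produces such
tables in practice:

* ``vdjtools`` — TSV with columns (exact order)
  ``count freq cdr3nt cdr3aa v d j VEnd DStart DEnd JStart``; reference
  points are 0-based offsets within the CDR3, ``-1`` marks a missing point.
* ``airr`` — AIRR Rearrangement TSV with
  ``junction junction_aa v_call d_call j_call duplicate_count`` plus
  optional ``v_sequence_end d_sequence_start d_sequence_end
  j_sequence_start`` carrying the same CDR3-local offsets.

Preprocessing follows the conventional repertoire pipeline: exclusion of
non-productive clonotypes, cross-sample decontamination, collapse of
nucleotide variants onto amino-acid clonotypes, and merging of biopsy
slices per patient.
"""

from __future__ import annotations

import math
import os
from dataclasses import replace
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .model import AAEntry, AARepertoire, Clonotype, Cohort, Repertoire

__all__ = [
    "VDJTOOLS_COLUMNS",
    "AIRR_COLUMNS",
    "read_clonotype_table",
    "write_clonotype_table",
    "filter_productive",
    "decontaminate",
    "collapse_by_aa",
    "merge_samples",
]

VDJTOOLS_COLUMNS = [
    "count",
    "freq",
    "cdr3nt",
    "cdr3aa",
    "v",
    "d",
    "j",
    "VEnd",
    "DStart",
    "DEnd",
    "JStart",
]

AIRR_COLUMNS = [
    "junction",
    "junction_aa",
    "v_call",
    "d_call",
    "j_call",
    "duplicate_count",
]
AIRR_OPTIONAL = [
    "v_sequence_end",
    "d_sequence_start",
    "d_sequence_end",
    "j_sequence_start",
]

_MISSING_POINT = -1


def _point_out(v: Optional[int]) -> int:
    return _MISSING_POINT if v is None else int(v)


def _point_in(v) -> Optional[int]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() in ("", "."):
        return None
    iv = int(v)
    return None if iv < 0 else iv


def _parse_count(value, row: int, path: str) -> int:
    try:
        c = int(value)
    except (TypeError, ValueError):
        raise ValueError(f"{path}: non-numeric count {value!r} at data row {row}")
    if c < 0:
        raise ValueError(f"{path}: negative count {value!r} at data row {row}")
    return c


def read_clonotype_table(
    path: Union[str, os.PathLike],
    dialect: str = "vdjtools",
    sample_id: Optional[str] = None,
    patient_id: str = "",
    compartment: str = "",
    chain: str = "TRB",
) -> Repertoire:
    """Read one clonotype table.

    Metadata defaults: ``sample_id`` falls back to the file name stem;
    patient/compartment/chain come from the keyword arguments (typically a
    sample sheet).  Frequencies are recomputed from counts.
    """
    path = os.fspath(path)
    if dialect not in ("vdjtools", "airr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = VDJTOOLS_COLUMNS if dialect == "vdjtools" else AIRR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing {dialect} columns {missing}")
    unknown = [c for c in df.columns if c not in required + AIRR_OPTIONAL]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    if len(df) == 0:
        raise ValueError(f"{path}: empty clonotype table")

    clones: list[Clonotype] = []
    if dialect == "vdjtools":
        for row, rec in enumerate(df.itertuples(index=False), start=1):
            clones.append(
                Clonotype(
                    cdr3_nt=rec.cdr3nt,
                    cdr3_aa=rec.cdr3aa,
                    v_call=rec.v,
                    d_call=None if pd.isna(rec.d) or rec.d in (".", "") else rec.d,
                    j_call=rec.j,
                    count=_parse_count(rec.count, row, path),
                    v_end=_point_in(rec.VEnd),
                    d_start=_point_in(rec.DStart),
                    d_end=_point_in(rec.DEnd),
                    j_start=_point_in(rec.JStart),
                )
            )
    else:
        has_points = all(c in df.columns for c in AIRR_OPTIONAL)
        for row, rec in enumerate(df.itertuples(index=False), start=1):
            points = {}
            if has_points:
                points = dict(
                    v_end=_point_in(rec.v_sequence_end),
                    d_start=_point_in(rec.d_sequence_start),
                    d_end=_point_in(rec.d_sequence_end),
                    j_start=_point_in(rec.j_sequence_start),
                )
            d_call = rec.d_call
            if pd.isna(d_call) or d_call in ("", "."):
                d_call = None
            clones.append(
                Clonotype(
                    cdr3_nt=rec.junction,
                    cdr3_aa=rec.junction_aa,
                    v_call=rec.v_call,
                    d_call=d_call,
                    j_call=rec.j_call,
                    count=_parse_count(rec.duplicate_count, row, path),
                    **points,
                )
            )
    sid = sample_id if sample_id is not None else os.path.splitext(os.path.basename(path))[0]
    rep = Repertoire(
        sample_id=sid,
        clonotypes=clones,
        patient_id=patient_id,
        compartment=compartment,
        chain=chain,
    )
    return rep.normalized()


def write_clonotype_table(
    rep: Repertoire, path: Union[str, os.PathLike], dialect: str = "vdjtools"
) -> None:
    """Write a repertoire in the requested dialect.

    Rows are sorted by descending count with ties broken by ``cdr3_nt``
    lexicographic order; frequencies use a fixed 10-significant-digit
    representation so files are diff-stable.
    """
    if dialect not in ("vdjtools", "airr"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if len(rep) == 0:
        raise ValueError(f"refusing to write empty repertoire {rep.sample_id!r}")
    rep = rep.sorted()
    rows = []
    if dialect == "vdjtools":
        for c in rep.clonotypes:
            rows.append(
                {
                    "count": c.count,
                    "freq": f"{c.freq:.10g}",
                    "cdr3nt": c.cdr3_nt,
                    "cdr3aa": c.cdr3_aa,
                    "v": c.v_call,
                    "d": c.d_call if c.d_call is not None else ".",
                    "j": c.j_call,
                    "VEnd": _point_out(c.v_end),
                    "DStart": _point_out(c.d_start),
                    "DEnd": _point_out(c.d_end),
                    "JStart": _point_out(c.j_start),
                }
            )
        df = pd.DataFrame(rows, columns=VDJTOOLS_COLUMNS)
    else:
        for c in rep.clonotypes:
            rows.append(
                {
                    "junction": c.cdr3_nt,
                    "junction_aa": c.cdr3_aa,
                    "v_call": c.v_call,
                    "d_call": c.d_call if c.d_call is not None else "",
                    "j_call": c.j_call,
                    "duplicate_count": c.count,
                    "v_sequence_end": _point_out(c.v_end),
                    "d_sequence_start": _point_out(c.d_start),
                    "d_sequence_end": _point_out(c.d_end),
                    "j_sequence_start": _point_out(c.j_start),
                }
            )
        df = pd.DataFrame(rows, columns=AIRR_COLUMNS + AIRR_OPTIONAL)
    df.to_csv(path, sep="\t", index=False)


def is_productive(c: Clonotype) -> bool:
    """Productivity proxy: no stop ('*') or frameshift ('_') marker in the
    amino-acid sequence and an in-frame (length % 3 == 0) CDR3nt."""
    return "*" not in c.cdr3_aa and "_" not in c.cdr3_aa and len(c.cdr3_nt) % 3 == 0


def filter_productive(rep: Repertoire) -> Repertoire:
    """Exclude non-productive clonotypes and renormalize frequencies."""
    kept = [c for c in rep.clonotypes if is_productive(c)]
    if not kept:
        raise ValueError(f"sample {rep.sample_id}: no productive clonotypes remain")
    return replace(rep, clonotypes=kept).normalized()


def decontaminate(
    cohort: Union[Cohort, Sequence[Repertoire]], ratio: float = 20.0
) -> Union[Cohort, list[Repertoire]]:
    """Cross-sample decontamination.

    A clonotype (matched on cdr3_nt + V + J) is removed from sample A when
    any other sample carries the same clonotype at a frequency at least
    ``ratio`` times higher — the signature of carry-over contamination.
    Frequencies are renormalized afterwards.  Single-sample input is
    returned unchanged.
    """
    if ratio <= 1:
        raise ValueError("decontamination ratio must be > 1")
    reps = list(cohort.repertoires) if isinstance(cohort, Cohort) else list(cohort)
    if len(reps) < 2:
        return cohort

    # per-key top-2 frequencies across samples
    best: dict[tuple, tuple[float, int, float]] = {}  # key -> (max, argmax, second)
    for i, rep in enumerate(reps):
        for c in rep.clonotypes:
            m1, a1, m2 = best.get(c.key, (0.0, -1, 0.0))
            if c.freq > m1:
                best[c.key] = (c.freq, i, m1)
            elif c.freq > m2:
                best[c.key] = (m1, a1, c.freq)

    cleaned = []
    for i, rep in enumerate(reps):
        kept = []
        for c in rep.clonotypes:
            m1, a1, m2 = best[c.key]
            other = m2 if a1 == i else m1
            if other >= ratio * c.freq:
                continue
            kept.append(c)
        if not kept:
            raise ValueError(
                f"sample {rep.sample_id}: decontamination removed every clonotype"
            )
        cleaned.append(replace(rep, clonotypes=kept).normalized())
    if isinstance(cohort, Cohort):
        return Cohort(cleaned, reference=cohort.reference)
    return cleaned


def collapse_by_aa(rep: Repertoire) -> AARepertoire:
    """Sum nucleotide variants of the same CDR3aa and recompute frequencies.

    ``nt_variant_count`` records how many distinct CDR3nt sequences were
    merged per amino-acid clonotype (the convergent-recombination signal).
    """
    if len(rep) == 0:
        raise ValueError(f"sample {rep.sample_id}: empty repertoire")
    counts: dict[str, int] = {}
    variants: dict[str, set] = {}
    for c in rep.clonotypes:
        counts[c.cdr3_aa] = counts.get(c.cdr3_aa, 0) + c.count
        variants.setdefault(c.cdr3_aa, set()).add(c.cdr3_nt)
    total = sum(counts.values())
    entries = [
        AAEntry(
            cdr3_aa=aa,
            count=cnt,
            freq=cnt / total if total else 0.0,
            nt_variant_count=len(variants[aa]),
        )
        for aa, cnt in counts.items()
    ]
    entries.sort(key=lambda e: (-e.count, e.cdr3_aa))
    return AARepertoire(
        sample_id=rep.sample_id,
        entries=entries,
        patient_id=rep.patient_id,
        compartment=rep.compartment,
        chain=rep.chain,
    )


def merge_samples(reps: Sequence[Repertoire]) -> Repertoire:
    """Merge biopsy-slice repertoires of one patient.

    Counts are summed per (cdr3_nt, V, J) and frequencies renormalized.
    All inputs must share patient and chain; the compartment label is kept
    when common, otherwise set to ``"merged"``.
    """
    if not reps:
        raise ValueError("nothing to merge")
    patients = {r.patient_id for r in reps}
    chains = {r.chain for r in reps}
    if len(patients) > 1:
        raise ValueError(f"cannot merge mixed patients {sorted(patients)}")
    if len(chains) > 1:
        raise ValueError(f"cannot merge mixed chains {sorted(chains)}")
    if len(reps) == 1:
        return reps[0].normalized().sorted()

    merged: dict[tuple, Clonotype] = {}
    for rep in reps:
        for c in rep.clonotypes:
            if c.key in merged:
                prev = merged[c.key]
                merged[c.key] = replace(prev, count=prev.count + c.count)
            else:
                merged[c.key] = replace(c, freq=0.0)
    compartments = {r.compartment for r in reps}
    compartment = compartments.pop() if len(compartments) == 1 else "merged"
    patient = patients.pop()
    out = Repertoire(
        sample_id=f"{patient}_merged_{compartment}",
        clonotypes=list(merged.values()),
        patient_id=patient,
        compartment=compartment,
        chain=chains.pop(),
    )
    return out.normalized().sorted()
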