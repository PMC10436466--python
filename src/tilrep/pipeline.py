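"""End-to-end orchestration of the repertoire comparison from a YAML config.

Stage order: ingest -> preprocess -> features -> stats -> motifs ->
annotate -> compare.  Every stage reads its inputs from, and writes its
tables to, the configured output directory, so individual stages can be
re-run from cached upstream outputs.  In synthetic mode everything is a
pure function of (config, master seed): re-running yields byte-identical
tables.  A run manifest records the config hash, seed, per-stage row
counts and final status; on failure the manifest carries a FAILED marker
naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_clusters,
    candidate_sets,
    category_counts,
    match_database,
    read_specificity_db,
    write_specificity_db,
)
from .compare import compare_groups, correlate_diversity_composition
from .features import length_summary, repertoire_property_profile
from .io import (
    collapse_by_aa,
    decontaminate,
    filter_productive,
    merge_samples,
    read_clonotype_table,
    write_clonotype_table,
)
from .model import Cohort, Repertoire
from .motifs import MotifCluster, MotifScore, cluster_by_motifs, motif_sharing
from .stats import (
    convergence,
    normalized_shannon_wiener,
    public_sequences,
    publicity_convergence_crosstab,
)
from .synthetic import (
    CohortSpec,
    DbSpec,
    cd4_til_spec,
    cd8_til_spec,
    generate_cohort,
    generate_repertoire,
    generate_specificity_db,
    mixed_initial_repertoire,
    reference_spec,
    til_initial_spec,
)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline", "STAGES"]

STAGES = ("ingest", "preprocess", "features", "stats", "motifs", "annotate", "compare")

_PRESETS = {"cd4": cd4_til_spec, "cd8": cd8_til_spec, "initial": til_initial_spec}

_FLOAT_FMT = "%.8g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    mode: str  # "synthetic" | "tables"
    seed: int
    output_dir: str
    dialect: str = "vdjtools"
    cohort: dict = field(default_factory=dict)  # synthetic mode
    sample_sheet: Optional[str] = None  # table mode
    db_path: Optional[str] = None  # table mode
    db_synthetic: dict = field(default_factory=dict)
    decontamination_ratio: float = 20.0
    diversity_level: str = "nt"
    scales: tuple = ("charge", "hydropathy", "polarity")
    motif_params: dict = field(default_factory=dict)
    freq_threshold: float = 0.001
    motif_compartments: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        mode = raw.get("mode", "synthetic")
        if mode not in ("synthetic", "tables"):
            raise ValueError(f"unknown mode {mode!r}")
        if mode == "synthetic" and "seed" not in raw:
            raise ValueError("synthetic mode requires an explicit seed")
        db = raw.get("db", {}) or {}
        cfg = cls(
            mode=mode,
            seed=int(raw.get("seed", 0)),
            output_dir=raw["output_dir"],
            dialect=raw.get("dialect", "vdjtools"),
            cohort=raw.get("cohort", {}) or {},
            sample_sheet=raw.get("sample_sheet"),
            db_path=db.get("path"),
            db_synthetic=db.get("synthetic", {}) or {},
            decontamination_ratio=float(raw.get("decontamination_ratio", 20.0)),
            diversity_level=raw.get("diversity_level", "nt"),
            scales=tuple(raw.get("scales", ("charge", "hydropathy", "polarity"))),
            motif_params=raw.get("motifs", {}) or {},
            freq_threshold=float(raw.get("freq_threshold", 0.001)),
            motif_compartments=tuple(raw.get("motif_compartments", ())),
        )
        if cfg.mode == "tables":
            if not cfg.sample_sheet:
                raise ValueError("table mode requires sample_sheet")
            if not os.path.exists(cfg.sample_sheet):
                raise ValueError(f"sample sheet not found: {cfg.sample_sheet}")
        return cfg

    def hash(self) -> str:
        blob = json.dumps(
            {
                k: (sorted(v.items()) if isinstance(v, dict) else v)
                for k, v in sorted(self.__dict__.items())
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    outputs: dict  # logical name -> path
    manifest_path: str


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.output_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _write_df(df: pd.DataFrame, path: Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# ingest

def _compartment_entries(cfg: PipelineConfig) -> list[dict]:
    entries = []
    for item in cfg.cohort.get("compartments", []):
        if isinstance(item, str):
            item = {"label": item}
        entry = dict(item)
        entry.setdefault("preset", entry["label"].lower())
        entry.setdefault("mixture", False)
        entries.append(entry)
    if not entries:
        raise ValueError("synthetic cohort config has no compartments")
    return entries


def _preset_for(entry: dict, n_clonotypes: int) -> "object":
    name = entry["preset"]
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    planted = tuple((m, int(k)) for m, k in entry.get("planted_motifs", ()))
    return _PRESETS[name](
        n_clonotypes=n_clonotypes, planted_motifs=planted
    )


def stage_ingest(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    sdir = out / "ingest" / "samples"
    sdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    sheet_rows = []

    if cfg.mode == "synthetic":
        cc = cfg.cohort
        n_patients = int(cc.get("n_patients", 3))
        slices = int(cc.get("slices_per_patient", 2))
        n_clonotypes = int(cc.get("n_clonotypes", 500))
        entries = _compartment_entries(cfg)
        fixed = [e for e in entries if not e.get("mixture")]
        spec = CohortSpec(
            n_patients=n_patients,
            slices_per_patient=slices,
            compartments=tuple(
                (e["label"], _preset_for(e, n_clonotypes)) for e in fixed
            ),
            public_injection=tuple(
                (aa, int(k)) for aa, k in cc.get("public_injection", ())
            ),
            reference_size=int(cc.get("reference_size", 2000)),
            seed=int(rng.integers(2**31)),
        )
        cohort = generate_cohort(spec)
        reps = list(cohort.repertoires)

        pct_cd4 = {
            f"P{p:02d}": float(rng.uniform(20, 80)) for p in range(1, n_patients + 1)
        }
        for e in entries:
            if not e.get("mixture"):
                continue
            for p in range(1, n_patients + 1):
                pid = f"P{p:02d}"
                for s in range(1, slices + 1):
                    reps.append(
                        mixed_initial_repertoire(
                            pct_cd4[pid],
                            n_clonotypes=n_clonotypes,
                            seed=int(rng.integers(2**31)),
                            sample_id=f"{pid}_S{s}_{e['label']}",
                            patient_id=pid,
                            compartment=e["label"],
                        )
                    )

        for rep in reps:
            path = sdir / f"{rep.sample_id}.tsv"
            write_clonotype_table(rep, path, cfg.dialect)
            comp = rep.compartment
            is_mix = any(e.get("mixture") and e["label"] == comp for e in entries)
            if is_mix:
                p4 = pct_cd4[rep.patient_id]
            elif "cd4" in comp.lower():
                p4 = 100.0
            elif "cd8" in comp.lower():
                p4 = 0.0
            else:
                p4 = float("nan")
            sheet_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": rep.patient_id,
                    "compartment": comp,
                    "chain": rep.chain,
                    "path": str(path.relative_to(out)),
                    "pct_cd4": p4,
                    "pct_cd8": 100.0 - p4 if p4 == p4 else float("nan"),
                }
            )
        write_clonotype_table(cohort.reference, out / "ingest" / "reference.tsv", cfg.dialect)

        # synthetic specificity database seeded with a few cohort sequences
        overlap = []
        cats = ("cancer", "pathogens", "autoimmunity")
        for e in fixed:
            rep = next(r for r in reps if r.compartment == e["label"])
            top = [c.cdr3_aa for c in rep.sorted().clonotypes[:3]]
            for i, aa in enumerate(top):
                overlap.append((aa, cats[i % len(cats)], i % 2))
        db_counts = cfg.db_synthetic or {"allergy": 10, "autoimmunity": 10, "cancer": 15, "pathogens": 20}
        db = generate_specificity_db(
            DbSpec(
                n_records=tuple(sorted(db_counts.items())),
                overlap_with_cohort=tuple(overlap),
                seed=int(rng.integers(2**31)),
            )
        )
        write_specificity_db(db, out / "ingest" / "db.csv")
    else:
        sheet = pd.read_csv(cfg.sample_sheet)
        for rec in sheet.itertuples(index=False):
            rep = read_clonotype_table(
                rec.path,
                cfg.dialect,
                sample_id=rec.sample_id,
                patient_id=str(rec.patient_id),
                compartment=rec.compartment,
                chain=getattr(rec, "chain", "TRB"),
            )
            path = sdir / f"{rep.sample_id}.tsv"
            write_clonotype_table(rep, path, "vdjtools")
            sheet_rows.append(
                {
                    "sample_id": rep.sample_id,
                    "patient_id": rep.patient_id,
                    "compartment": rep.compartment,
                    "chain": rep.chain,
                    "path": str(path.relative_to(out)),
                    "pct_cd4": getattr(rec, "pct_cd4", float("nan")),
                    "pct_cd8": getattr(rec, "pct_cd8", float("nan")),
                }
            )
        ref_path = cfg.cohort.get("reference_path")
        if ref_path:
            ref = read_clonotype_table(ref_path, cfg.dialect, sample_id="reference")
        else:
            ref = generate_repertoire(
                reference_spec(n_clonotypes=2000, seed=cfg.seed), "reference"
            )
        write_clonotype_table(ref, out / "ingest" / "reference.tsv", "vdjtools")

    sheet_df = pd.DataFrame(sheet_rows).sort_values("sample_id", kind="mergesort")
    _write_df(sheet_df, out / "ingest" / "sample_sheet.csv", sep=",")
    return {"n_samples": len(sheet_rows)}


# ---------------------------------------------------------------------------
# shared readers

def _read_sheet(cfg: PipelineConfig) -> pd.DataFrame:
    path = _out(cfg) / "ingest" / "sample_sheet.csv"
    if not path.exists():
        raise PipelineError("preprocess", f"missing ingest output {path}; run ingest first")
    return pd.read_csv(path)


def _read_cohort(cfg: PipelineConfig, subdir: str) -> Cohort:
    out = _out(cfg)
    sheet = _read_sheet(cfg)
    reps = []
    meta = {}
    for rec in sheet.itertuples(index=False):
        meta[rec.sample_id] = rec
    dialect = cfg.dialect if subdir == "ingest/samples" else "vdjtools"
    for path in sorted((out / subdir).glob("*.tsv")):
        sid = path.stem
        rec = meta.get(sid)
        reps.append(
            read_clonotype_table(
                path,
                dialect,
                sample_id=sid,
                patient_id=str(rec.patient_id) if rec else "",
                compartment=rec.compartment if rec else "",
                chain=rec.chain if rec else "TRB",
            )
        )
    ref_path = out / "ingest" / "reference.tsv"
    ref = (
        read_clonotype_table(ref_path, cfg.dialect, sample_id="reference")
        if ref_path.exists()
        else None
    )
    return Cohort(reps, reference=ref)


def _read_merged(cfg: PipelineConfig) -> Cohort:
    out = _out(cfg)
    mdir = out / "preprocess" / "merged"
    if not mdir.exists():
        raise PipelineError("features", "missing preprocess outputs; run preprocess first")
    sheet = _read_sheet(cfg)
    comp_of = {}
    for rec in sheet.itertuples(index=False):
        comp_of[(str(rec.patient_id), rec.compartment)] = rec.compartment
    reps = []
    for path in sorted(mdir.glob("*.tsv")):
        pid, comp = path.stem.split("__", 1)
        reps.append(
            read_clonotype_table(
                path, "vdjtools", sample_id=path.stem, patient_id=pid, compartment=comp
            )
        )
    ref_path = out / "ingest" / "reference.tsv"
    ref = (
        read_clonotype_table(ref_path, cfg.dialect, sample_id="reference")
        if ref_path.exists()
        else None
    )
    return Cohort(reps, reference=ref)


# ---------------------------------------------------------------------------
# preprocess

def stage_preprocess(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    cohort = _read_cohort(cfg, "ingest/samples")
    log_rows = []
    filtered = []
    for rep in cohort.repertoires:
        before = len(rep)
        rep2 = filter_productive(rep)
        log_rows.append(
            {"sample_id": rep.sample_id, "step": "filter_productive", "before": before, "after": len(rep2)}
        )
        filtered.append(rep2)
    cleaned = decontaminate(filtered, ratio=cfg.decontamination_ratio)
    for rep_before, rep_after in zip(filtered, cleaned):
        log_rows.append(
            {
                "sample_id": rep_after.sample_id,
                "step": "decontaminate",
                "before": len(rep_before),
                "after": len(rep_after),
            }
        )

    mdir = out / "preprocess" / "merged"
    adir = out / "preprocess" / "aa"
    mdir.mkdir(parents=True, exist_ok=True)
    adir.mkdir(parents=True, exist_ok=True)
    groups: dict[tuple, list[Repertoire]] = {}
    for rep in cleaned:
        groups.setdefault((rep.patient_id, rep.compartment), []).append(rep)
    n_merged = 0
    for (pid, comp), reps in sorted(groups.items()):
        merged = merge_samples(reps)
        stem = f"{pid}__{comp}"
        merged = replace(merged, sample_id=stem)
        write_clonotype_table(merged, mdir / f"{stem}.tsv", "vdjtools")
        aa = collapse_by_aa(merged)
        aa_df = pd.DataFrame(
            {
                "cdr3aa": [e.cdr3_aa for e in aa.entries],
                "count": [e.count for e in aa.entries],
                "freq": [e.freq for e in aa.entries],
                "nt_variants": [e.nt_variant_count for e in aa.entries],
            }
        )
        _write_df(aa_df, adir / f"{stem}.tsv")
        log_rows.append(
            {"sample_id": stem, "step": "merge+collapse", "before": sum(len(r) for r in reps), "after": len(aa)}
        )
        n_merged += 1
    _write_df(pd.DataFrame(log_rows), out / "preprocess" / "log.tsv")
    return {"n_merged_samples": n_merged}


# ---------------------------------------------------------------------------
# features

def stage_features(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    cohort = _read_merged(cfg)
    rows = []
    for rep in cohort.repertoires:
        ls = length_summary(rep)
        aa = collapse_by_aa(rep)
        row = {
            "sample_id": rep.sample_id,
            "compartment": rep.compartment,
            "cdr3nt_mean": ls.cdr3nt_mean,
            "cdr3nt_sd": ls.cdr3nt_sd,
            "ndn_mean": ls.ndn_mean,
            "ndn_sd": ls.ndn_sd,
        }
        for scale in cfg.scales:
            row[scale] = repertoire_property_profile(aa, scale)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("sample_id", kind="mergesort")
    _write_df(df, out / "features.tsv")
    return {"n_rows": len(df)}


# ---------------------------------------------------------------------------
# stats

def stage_stats(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    cohort = _read_merged(cfg)
    rows = []
    for rep in cohort.repertoires:
        aa = collapse_by_aa(rep)
        div = normalized_shannon_wiener(
            rep if cfg.diversity_level == "nt" else aa, level=cfg.diversity_level
        )
        conv = convergence(aa)
        rows.append(
            {
                "sample_id": rep.sample_id,
                "compartment": rep.compartment,
                "level": cfg.diversity_level,
                "S": div.S,
                "H": div.H,
                "nsw": div.nsw,
                "cr_level": conv.cr_level,
            }
        )
    df = pd.DataFrame(rows).sort_values("sample_id", kind="mergesort")
    _write_df(df, out / "stats.tsv")

    pub_rows = []
    for comp in sorted(cohort.compartments):
        if len({r.patient_id for r in cohort.by_compartment(comp)}) < 2:
            continue
        pub = public_sequences(cohort, comp)
        ct = publicity_convergence_crosstab(cohort, comp)
        pub_rows.append(
            {
                "compartment": comp,
                "n_biopsies": pub.n_biopsies,
                "n_public": len(pub.public),
                "percent_public": pub.percent_public,
                "public_convergent": ct.public_convergent,
                "public_nonconvergent": ct.public_nonconvergent,
                "private_convergent": ct.private_convergent,
                "private_nonconvergent": ct.private_nonconvergent,
                "pct_public_given_convergent": ct.pct_public_given_convergent,
                "pct_public_given_nonconvergent": ct.pct_public_given_nonconvergent,
            }
        )
    _write_df(pd.DataFrame(pub_rows), out / "publicity.tsv")
    return {"n_rows": len(df)}


# ---------------------------------------------------------------------------
# motifs

def _motif_compartments(cfg: PipelineConfig, cohort: Cohort) -> list[str]:
    if cfg.motif_compartments:
        return list(cfg.motif_compartments)
    return [c for c in sorted(cohort.compartments) if c.lower() != "initial"]


def stage_motifs(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    cohort = _read_merged(cfg)
    if cohort.reference is None:
        raise PipelineError("motifs", "no reference repertoire available")
    ref_aa = collapse_by_aa(filter_productive(cohort.reference))
    mp = cfg.motif_params
    mdir = out / "motifs"
    mdir.mkdir(parents=True, exist_ok=True)
    n_clusters = 0
    for comp in _motif_compartments(cfg, cohort):
        clusters_by_biopsy = {}
        rows = []
        for rep in sorted(cohort.by_compartment(comp), key=lambda r: r.sample_id):
            aa = collapse_by_aa(rep)
            clusters = cluster_by_motifs(
                aa,
                ref_aa,
                fisher_max=float(mp.get("fisher_max", 0.5)),
                expansion_max=float(mp.get("expansion_max", 0.5)),
                k_exact=tuple(mp.get("k_exact", (3, 4, 5))),
                k_wild=tuple(mp.get("k_wild", (5, 6, 7))),
                min_carriers=int(mp.get("min_carriers", 2)),
                b=int(mp.get("b", 1000)),
                seed=cfg.seed,
            )
            clusters_by_biopsy[rep.patient_id] = clusters
            for cl in clusters:
                rows.append(
                    {
                        "motif": cl.motif,
                        "fisher_score": cl.score.fisher_score,
                        "expansion_score": cl.score.expansion_score,
                        "n_members": cl.n_members,
                        "biopsy": cl.biopsy,
                        "member_cdr3aa": ";".join(s for s, _ in cl.members),
                    }
                )
            n_clusters += len(clusters)
        _write_df(pd.DataFrame(rows, columns=["motif", "fisher_score", "expansion_score", "n_members", "biopsy", "member_cdr3aa"]), mdir / f"clusters_{comp}.tsv")
        sharing = motif_sharing(clusters_by_biopsy)
        sharing.reset_index().to_csv(
            mdir / f"sharing_{comp}.tsv", sep="\t", index=False
        )
    return {"n_clusters": n_clusters}


def _load_clusters(cfg: PipelineConfig, comp: str) -> list[MotifCluster]:
    path = _out(cfg) / "motifs" / f"clusters_{comp}.tsv"
    if not path.exists():
        raise PipelineError("annotate", f"missing motif output {path}; run motifs first")
    df = pd.read_csv(path, sep="\t")
    clusters = []
    for rec in df.itertuples(index=False):
        members = tuple((s, 0.0) for s in str(rec.member_cdr3aa).split(";"))
        clusters.append(
            MotifCluster(
                motif=rec.motif,
                members=members,
                biopsy=str(rec.biopsy),
                score=MotifScore(rec.fisher_score, rec.expansion_score, (rec.n_members, 0, 0, 0)),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# annotate

def stage_annotate(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    if cfg.mode == "tables" and cfg.db_path:
        db_file = Path(cfg.db_path)
    else:
        db_file = out / "ingest" / "db.csv"
    if not db_file.exists():
        raise PipelineError("annotate", f"specificity database not found: {db_file}")
    db = read_specificity_db(db_file)
    cohort = _read_merged(cfg)
    adir = out / "annotate"
    adir.mkdir(parents=True, exist_ok=True)
    n_annotated = 0
    for comp in _motif_compartments(cfg, cohort):
        reps = sorted(cohort.by_compartment(comp), key=lambda r: r.sample_id)
        if not reps:
            continue
        pooled = {}
        for rep in reps:
            for e in collapse_by_aa(rep).entries:
                pooled[e.cdr3_aa] = pooled.get(e.cdr3_aa, 0) + e.count
        total = sum(pooled.values())
        from .model import AAEntry, AARepertoire

        pooled_rep = AARepertoire(
            sample_id=f"pooled_{comp}",
            entries=sorted(
                (
                    AAEntry(aa, cnt, cnt / total, 1)
                    for aa, cnt in pooled.items()
                ),
                key=lambda e: (-e.count, e.cdr3_aa),
            ),
            compartment=comp,
        )
        clusters = _load_clusters(cfg, comp)
        n_patients = len({r.patient_id for r in reps})
        sets = candidate_sets(
            pooled_rep,
            cohort if n_patients >= 2 else None,
            clusters,
            freq_threshold=cfg.freq_threshold,
            compartment=comp,
        )
        set_df = pd.DataFrame(
            [
                {
                    "cdr3aa": aa,
                    "high_freq": int(aa in sets.high_freq),
                    "public": int(aa in sets.public),
                    "clustered": int(aa in sets.clustered),
                }
                for aa in sorted(sets.union)
            ],
            columns=["cdr3aa", "high_freq", "public", "clustered"],
        )
        _write_df(set_df, adir / f"candidates_{comp}.csv", sep=",")
        matches = match_database(sorted(sets.union), db)
        ann = annotate_clusters(clusters, matches)
        _write_df(ann, adir / f"annotation_{comp}.csv", sep=",")
        _write_df(category_counts(ann), adir / f"category_counts_{comp}.csv", sep=",")
        direct_rows = [
            {
                "cdr3aa": q,
                "matched": m.record.cdr3_aa,
                "category": m.record.category,
                "distance": m.distance,
            }
            for q in sorted(matches)
            for m in matches[q]
        ]
        _write_df(
            pd.DataFrame(direct_rows, columns=["cdr3aa", "matched", "category", "distance"]),
            adir / f"matches_{comp}.csv",
            sep=",",
        )
        n_annotated += len(ann)
    return {"n_annotated_rows": n_annotated}


# ---------------------------------------------------------------------------
# compare

def stage_compare(cfg: PipelineConfig) -> dict:
    out = _out(cfg)
    stats_path = out / "stats.tsv"
    feat_path = out / "features.tsv"
    if not stats_path.exists() or not feat_path.exists():
        raise PipelineError("compare", "missing stats/features outputs; run those stages first")
    stats_df = pd.read_csv(stats_path, sep="\t")
    feat_df = pd.read_csv(feat_path, sep="\t")
    sheet = _read_sheet(cfg)
    rows = []

    def record(panel: str, res) -> None:
        pw = ""
        if res.pairwise is not None:
            pw = ";".join(
                f"{c}={p:.4g}" for c, p in zip(res.pairwise["contrast"], res.pairwise["p_adj"])
            )
        rows.append(
            {
                "panel": panel,
                "method": res.method,
                "groups": ";".join(str(k) for k in res.group_sizes),
                "statistic": res.statistic,
                "p": res.pvalue,
                "pairwise_adjusted_p": pw,
            }
        )

    comps = sorted(stats_df["compartment"].unique())
    cd4 = next((c for c in comps if "cd4" in c.lower()), None)
    cd8 = next((c for c in comps if "cd8" in c.lower()), None)

    # paired diversity: CD4 vs CD8 per patient
    if cd4 and cd8:
        s4 = stats_df[stats_df["compartment"] == cd4].copy()
        s8 = stats_df[stats_df["compartment"] == cd8].copy()
        s4["patient"] = s4["sample_id"].str.split("__").str[0]
        s8["patient"] = s8["sample_id"].str.split("__").str[0]
        joined = s4.merge(s8, on="patient", suffixes=("_cd4", "_cd8"))
        if len(joined) >= 2:
            record(
                "diversity_paired",
                compare_groups((joined["nsw_cd4"], joined["nsw_cd8"]), "paired_t"),
            )

    # one-way ANOVA + Tukey across compartments for each scale
    for scale in cfg.scales:
        if scale not in feat_df.columns or len(comps) < 2:
            continue
        groups = {
            comp: feat_df[feat_df["compartment"] == comp][scale].to_numpy()
            for comp in comps
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            try:
                record(f"{scale}_anova", compare_groups(groups, "anova_tukey"))
            except ValueError:
                pass
    if len(comps) >= 2:
        groups = {
            comp: feat_df[feat_df["compartment"] == comp]["ndn_mean"].to_numpy()
            for comp in comps
        }
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            try:
                record("ndn_anova", compare_groups(groups, "anova_tukey"))
            except ValueError:
                pass

    # diversity vs composition over initial-culture samples
    init = next((c for c in comps if c.lower() == "initial"), None)
    if init is not None:
        si = stats_df[stats_df["compartment"] == init].copy()
        si["patient"] = si["sample_id"].str.split("__").str[0]
        pct = sheet[sheet["compartment"] == init].groupby("patient_id")[["pct_cd4", "pct_cd8"]].mean()
        si = si.merge(pct, left_on="patient", right_index=True, how="left")
        table = si.rename(columns={"nsw": "nsw"})[["nsw", "pct_cd4", "pct_cd8"]]
        if len(table.dropna()) >= 3:
            try:
                res = correlate_diversity_composition(table)
                record("diversity_vs_pct_cd4", res["cd4"])
                record("diversity_vs_pct_cd8", res["cd8"])
            except ValueError:
                pass

    df = pd.DataFrame(
        rows, columns=["panel", "method", "groups", "statistic", "p", "pairwise_adjusted_p"]
    )
    _write_df(df, out / "comparisons.csv", sep=",")
    return {"n_comparisons": len(df)}


# ---------------------------------------------------------------------------

_STAGE_FUNCS = {
    "ingest": stage_ingest,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "stats": stage_stats,
    "motifs": stage_motifs,
    "annotate": stage_annotate,
    "compare": stage_compare,
}


def run_pipeline(cfg: PipelineConfig, stages=STAGES) -> ReportBundle:
    """Execute the requested stages in order and write the run manifest."""
    out = _out(cfg)
    manifest = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "version": __version__,
        "stages": {},
        "status": "OK",
    }
    manifest_path = out / "manifest.json"
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise PipelineError(stage, "unknown stage")
            try:
                info = _STAGE_FUNCS[stage](cfg)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            manifest["stages"][stage] = info
    except PipelineError as exc:
        manifest["status"] = f"FAILED:{exc.stage}"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    outputs = {}
    for name in [
        "features.tsv",
        "stats.tsv",
        "publicity.tsv",
        "comparisons.csv",
    ]:
        p = out / name
        if p.exists():
            outputs[name] = str(p)
    for sub in ["motifs", "annotate"]:
        d = out / sub
        if d.exists():
            for p in sorted(d.iterdir()):
                outputs[f"{sub}/{p.name}"] = str(p)
    return ReportBundle(outputs=outputs, manifest_path=str(manifest_path))
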