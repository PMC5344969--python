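"""Readers and writers for the pipeline's tabular formats.

Conventions: BED intervals are 0-based half-open; missing values are
empty fields (an empty Ct field means no amplification, never zero);
floats are written with six significant digits; writers order rows
deterministically.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Amplicon, AmpliconPanel, DepthProfile
from .qpcr import QpcrRun, QpcrWell
from .variants import VariantRecord


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# -- panel BED --------------------------------------------------------------


def write_panel(panel: AmpliconPanel, path: str | Path) -> None:
    """BED4: chrom, start, end, name=``gene|exon|index``."""
    with open(path, "w") as fh:
        for a in panel:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\n")


def read_panel(path: str | Path) -> AmpliconPanel:
    """Read and validate a panel BED file.

    Malformed lines are reported with their line number; ``end <
    start`` (the signature of 1-based input) is an explicit error, and
    unsorted input is sorted with a warning.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 BED columns, got {len(fields)}")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end ({end}) < start ({start}); "
                    "input looks 1-based — convert to 0-based half-open"
                )
            parts = name.split("|")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: name {name!r} is not gene|exon|index"
                )
            records.append((chrom, start, end, parts[0], parts[1], lineno))
    if not records:
        raise ValueError(f"{path}: empty panel")
    ordered = sorted(records, key=lambda r: (r[0], r[1]))
    if ordered != records:
        warnings.warn(f"{path}: panel was not sorted; sorting by (chrom, start)")
    amplicons = [
        Amplicon(chrom, start, end, gene, exon, i)
        for i, (chrom, start, end, gene, exon, _) in enumerate(ordered)
    ]
    return AmpliconPanel(amplicons)


# -- depth tables -----------------------------------------------------------

DEPTH_COLUMNS = ["amplicon_id", "sample_id", "reads"]


def write_depths(profiles: list[DepthProfile], panel: AmpliconPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DEPTH_COLUMNS) + "\n")
        for profile in profiles:
            profile.check_panel(panel)
            for a, count in zip(panel, profile.counts):
                fh.write(f"{a.name}\t{profile.sample_id}\t{int(count)}\n")


def read_depths(path: str | Path, panel: AmpliconPanel) -> dict[str, DepthProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"amplicon_id": str, "sample_id": str})
    for col in DEPTH_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    name_to_idx = {a.name: a.index for a in panel}
    profiles: dict[str, DepthProfile] = {}
    for sample_id, sub in df.groupby("sample_id", sort=False):
        counts = np.zeros(len(panel), dtype=np.int64)
        seen = np.zeros(len(panel), dtype=bool)
        for row_no, row in enumerate(sub.itertuples(index=False), start=1):
            idx = name_to_idx.get(row.amplicon_id)
            if idx is None:
                raise ValueError(
                    f"{path}: sample {sample_id!r} references amplicon "
                    f"{row.amplicon_id!r} absent from the panel"
                )
            try:
                counts[idx] = int(row.reads)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: sample {sample_id!r} row {row_no}: "
                    f"non-integer read count {row.reads!r}"
                ) from None
            seen[idx] = True
        if not seen.all():
            missing = [a.name for a in panel if not seen[a.index]]
            raise ValueError(
                f"{path}: sample {sample_id!r} lacks counts for {missing[:3]}..."
            )
        profiles[str(sample_id)] = DepthProfile(str(sample_id), counts)
    if not profiles:
        raise ValueError(f"{path}: no depth rows")
    return profiles


# -- qPCR Ct tables ---------------------------------------------------------

CT_COLUMNS = ["well", "sample_id", "sample_type", "target", "replicate", "ct"]


def write_ct(run: QpcrRun, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(CT_COLUMNS) + "\n")
        for w in run.wells:
            ct = "" if w.ct is None else _fmt(w.ct)
            fh.write(f"{w.well},{w.sample_id},{w.sample_type},{w.target},{w.replicate},{ct}\n")


def read_ct(path: str | Path) -> QpcrRun:
    df = pd.read_csv(path, dtype={"well": str, "sample_id": str})
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    wells = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        ct = None if pd.isna(row.ct) else float(row.ct)  # empty field = no amplification
        try:
            wells.append(
                QpcrWell(row.well, row.sample_id, row.sample_type, row.target,
                         int(row.replicate), ct)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from None
    return QpcrRun(wells)


# -- cohort tables ----------------------------------------------------------

COHORT_COLUMNS_DOC = [
    "case_id",
    "aetiology",  # KIT | PDGFRA | NF1 | SDH | unknown
    "group",  # sporadic | nf1_syndromic | other_syndromic
    "site",  # gastric | non_gastric | unknown
    "risk_class",  # low | intermediate | high | metastatic | micro
    "genomic_max",  # mutant | wild_type | untested
    "immunoblot_expression",  # float normalized to GIST430; empty = untested
    "ihc_status",  # loss | retained | untested
]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    out = cohort.copy()
    out["immunoblot_expression"] = [
        "" if pd.isna(e) else _fmt(float(e)) for e in out["immunoblot_expression"]
    ]
    out.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str})
    for col in COHORT_COLUMNS_DOC:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    df["immunoblot_expression"] = pd.to_numeric(
        df["immunoblot_expression"], errors="coerce"
    )
    return df


# -- variant tables ---------------------------------------------------------

VARIANT_COLUMNS = ["case_id", "specimen_id", "hgvs_c", "vaf", "normal_genotype"]


def write_variants(records: list[VariantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(VARIANT_COLUMNS) + "\n")
        for r in records:
            vaf = "" if r.vaf is None else _fmt(r.vaf)
            fh.write(f"{r.case_id},{r.specimen_id},{r.hgvs_c},{vaf},{r.normal_genotype}\n")


def read_variants(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, dtype={"case_id": str, "specimen_id": str, "hgvs_c": str})
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    records = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vaf = None if pd.isna(row.vaf) else float(row.vaf)
        genotype = "unavailable" if pd.isna(row.normal_genotype) else str(row.normal_genotype)
        try:
            records.append(
                VariantRecord(row.hgvs_c, str(row.case_id), str(row.specimen_id), vaf, genotype)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {row_no}: {exc}") from None
    return records


# -- reports ----------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(_fmt(float(obj)))
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Machine-readable JSON report (floats at 6 significant digits)."""
    header = {
        "conventions": "BED coordinates 0-based half-open; HGVS transcript "
        "coordinates 1-based",
    }
    with open(path, "w") as fh:
        json.dump({"header": header, **_jsonify(report)}, fh, indent=2, sort_keys=True)
        fh.write("\n")
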