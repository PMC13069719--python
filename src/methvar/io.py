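"""Readers and writers for every file format the pipeline touches.

TSV for matrices and result tables, CSV for the probe manifest and sample
sheet, BED for TADs, BEDPE for loops. Output tables carry the configuration
snapshot used to produce them as a ``# methvar-config: {...}`` comment line;
all readers skip ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BetaMatrix,
    ExpressionMatrix,
    GenomeIntervals,
    MqtlTable,
    ProbeManifest,
    SampleSheet,
    ValidationError,
    normalize_chrom,
)


def _read_table(path, sep):
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no probes (empty file)")
    return df


def read_beta_matrix(path, validate_range: bool = True) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV (probe ids first column).

    ``validate_range=False`` admits cell-corrected matrices whose values may
    fall slightly outside [0, 1].
    """
    df = _read_table(path, "\t")
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: no probes")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return BetaMatrix(df.astype(float), validate_range)
    except ValidationError as err:
        raise ValidationError(f"{path}: {err}") from None


def write_beta_matrix(betas: BetaMatrix, path, config_snapshot: str | None = None) -> None:
    _write_with_snapshot(betas.values, path, "\t", config_snapshot, index_label="probe_id")


def read_expression_matrix(path) -> ExpressionMatrix:
    df = _read_table(path, "\t")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path, config_snapshot=None) -> None:
    _write_with_snapshot(expr.values, path, "\t", config_snapshot, index_label="gene_id")


def read_manifest(path) -> ProbeManifest:
    df = pd.read_csv(path, index_col=0, comment="#",
                     dtype={"features": str, "gene": str})
    df.index = df.index.astype(str)
    for col in ("imprinted", "non_cpg", "on_450k"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    df["features"] = df["features"].fillna("")
    return ProbeManifest(df)


def write_manifest(manifest: ProbeManifest, path, config_snapshot=None) -> None:
    _write_with_snapshot(manifest.table, path, ",", config_snapshot, index_label="probe_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, index_col=0, comment="#")
    df.index = df.index.astype(str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, config_snapshot=None) -> None:
    _write_with_snapshot(sheet.table, path, ",", config_snapshot, index_label="sample_id")


def read_mqtl_table(path) -> MqtlTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["snp_id"] = df["snp_id"].astype(str)
    df["cpg_id"] = df["cpg_id"].astype(str)
    return MqtlTable(df)


def write_mqtl_table(mqtl: MqtlTable, path, config_snapshot=None) -> None:
    _write_with_snapshot(mqtl.table, path, "\t", config_snapshot, index=False)


def read_intervals(path, kind: str) -> GenomeIntervals:
    """Read TADs (``kind='bed'``) or loops (``kind='bedpe'``).

    BED: >= 3 columns (chrom, start, end); BEDPE: >= 6 columns
    (chromA, startA, endA, chromB, startB, endB). Coordinates are 0-based
    half-open; chromosome names are normalised to the ``chr`` dialect.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((ln, line.split("\t") if "\t" in line else line.split()))
    if kind == "bed":
        tad_rows = []
        for ln, parts in rows:
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = normalize_chrom(parts[0]), int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end ({start} >= {end})")
            tad_rows.append((chrom, start, end))
        return GenomeIntervals(
            tads=pd.DataFrame(tad_rows, columns=["chrom", "start", "end"]))
    if kind == "bedpe":
        loop_rows = []
        for ln, parts in rows:
            if len(parts) < 6:
                raise ValidationError(f"{path}:{ln}: BEDPE needs >= 6 columns")
            ca, sa, ea = normalize_chrom(parts[0]), int(parts[1]), int(parts[2])
            cb, sb, eb = normalize_chrom(parts[3]), int(parts[4]), int(parts[5])
            if sa >= ea or sb >= eb:
                raise ValidationError(f"{path}:{ln}: anchor start >= end")
            if ca != cb:
                raise ValidationError(f"{path}:{ln}: loop anchors on different chromosomes")
            loop_rows.append((ca, sa, ea, sb, eb))
        return GenomeIntervals(
            tads=pd.DataFrame(columns=["chrom", "start", "end"]),
            loops=pd.DataFrame(loop_rows,
                               columns=["chrom", "startA", "endA", "startB", "endB"]),
        )
    raise ValueError(f"unknown interval kind {kind!r}, expected 'bed' or 'bedpe'")


def read_genome_intervals(tad_path, loop_path) -> GenomeIntervals:
    tads = read_intervals(tad_path, "bed")
    loops = read_intervals(loop_path, "bedpe")
    return GenomeIntervals(tads=tads.tads, loops=loops.loops)


def write_intervals(intervals: GenomeIntervals, tad_path=None, loop_path=None) -> None:
    if tad_path is not None:
        with open(tad_path, "w") as fh:
            for _, r in intervals.tads.iterrows():
                fh.write(f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\n")
    if loop_path is not None:
        with open(loop_path, "w") as fh:
            for _, r in intervals.loops.iterrows():
                fh.write(f"{r['chrom']}\t{int(r['startA'])}\t{int(r['endA'])}\t"
                         f"{r['chrom']}\t{int(r['startB'])}\t{int(r['endB'])}\n")


def write_result_table(df: pd.DataFrame, path, config_snapshot: str | None = None,
                       index: bool = True, index_label=None) -> None:
    """Write an analysis result table as TSV with the config snapshot."""
    _write_with_snapshot(df, path, "\t", config_snapshot, index=index,
                         index_label=index_label)


def read_result_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def _write_with_snapshot(df: pd.DataFrame, path, sep, config_snapshot,
                         index: bool = True, index_label=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if config_snapshot:
            fh.write(f"# methvar-config: {config_snapshot}\n")
        df.to_csv(fh, sep=sep, index=index, index_label=index_label)
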