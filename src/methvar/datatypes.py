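"""Core data containers for EPIC-array style methylation analyses.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`
so that downstream code can rely on a handful of invariants (unique ids,
beta values inside [0, 1], consistent coordinate conventions) without
re-checking them at every step.

Coordinate conventions
----------------------
Probe and SNP positions are 1-based (as in array manifests and mQTL tables);
TADs and chromatin loops use the 0-based half-open BED/BEDPE convention.
All conversions between the two happen here and in :mod:`methvar.mqtl`,
nowhere else. Chromosome names are normalised to the ``chr``-prefixed
dialect on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")
FEATURES = ("exon", "intron", "5UTR", "3UTR", "promoter", "enhancer", "intergenic", "TE")
CELL_TYPES = ("CD8T", "CD4T", "NK", "B", "Mono", "Gran")
COHORTS = ("discovery", "validation")


class ValidationError(ValueError):
    """Raised when an input file or container violates a documented invariant."""


def normalize_chrom(chrom: str) -> str:
    """Normalise chromosome names to the ``chr``-prefixed dialect."""
    c = str(chrom).strip()
    if not c.lower().startswith("chr"):
        c = "chr" + c
    return "chr" + c[3:]


def _check_unique(values, what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dups = s[s.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values in [0, 1].

    Missing values are NaN. ``values`` is indexed by probe id with sample ids
    as columns. Cell-composition corrected matrices may carry values
    slightly outside [0, 1] (they are deliberately not clipped); those are
    constructed with ``validate_range=False`` and keep that property through
    subsetting.
    """

    values: pd.DataFrame
    validate_range: bool = True

    def __post_init__(self):
        if self.values.shape[0] == 0:
            raise ValidationError("no probes")
        if self.values.shape[1] == 0:
            raise ValidationError("no samples")
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        if self.validate_range:
            arr = self.values.to_numpy(dtype=float)
            bad = (arr < 0) | (arr > 1)
            bad &= ~np.isnan(arr)
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise ValidationError(
                    f"beta value out of [0, 1] at probe {self.values.index[r]!r}, "
                    f"sample {self.values.columns[c]!r}: {arr[r, c]}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def drop_high_missing(self, max_missing_frac: float = 0.05) -> "BetaMatrix":
        """Drop probes whose fraction of missing samples exceeds the threshold."""
        frac = self.values.isna().mean(axis=1)
        keep = frac <= max_missing_frac
        if keep.all():
            return self
        return BetaMatrix(self.values.loc[keep], self.validate_range)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)], self.validate_range)


@dataclass
class ProbeManifest:
    """Per-probe genomic annotation.

    ``table`` is indexed by probe id with columns: chrom, pos (1-based),
    island_relation, features (semicolon-joined subset of FEATURES), gene
    (may be empty), imprinted, non_cpg, on_450k (booleans).
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "pos", "island_relation", "features", "gene",
                "imprinted", "non_cpg", "on_450k")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        _check_unique(self.table.index, "probe ids")
        self.table = self.table.copy()
        self.table["chrom"] = self.table["chrom"].map(normalize_chrom)
        pos = self.table["pos"].to_numpy()
        if (pos < 1).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")
        bad = ~self.table["island_relation"].isin(ISLAND_RELATIONS)
        if bad.any():
            raise ValidationError(
                f"unknown island relation: {self.table['island_relation'][bad].unique()[:5]}"
            )
        self.table["gene"] = self.table["gene"].fillna("")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def features_of(self, probe_id: str) -> list[str]:
        raw = self.table.at[probe_id, "features"]
        return [f for f in str(raw).split(";") if f]

    def feature_indicator(self, feature: str) -> pd.Series:
        """Boolean series: does each probe carry the given feature annotation."""
        pat = self.table["features"].fillna("").str.split(";")
        return pat.map(lambda fs: feature in fs)


@dataclass
class SampleSheet:
    """Per-sample metadata with six estimated blood cell-type proportions."""

    table: pd.DataFrame
    prop_tolerance: float = 0.02

    def __post_init__(self):
        _check_unique(self.table.index, "sample ids")
        missing = [c for c in ("cohort",) + CELL_TYPES if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        bad = ~self.table["cohort"].isin(COHORTS)
        if bad.any():
            raise ValidationError(
                f"unknown cohort labels: {self.table['cohort'][bad].unique()[:5]}"
            )
        props = self.table[list(CELL_TYPES)].to_numpy(dtype=float)
        if ((props < 0) | (props > 1)).any():
            raise ValidationError("cell proportions must lie in [0, 1]")
        total = props.sum(axis=1)
        off = np.abs(total - 1.0) > self.prop_tolerance
        if off.any():
            sid = self.table.index[off][0]
            raise ValidationError(
                f"cell proportions of sample {sid!r} sum to {total[off][0]:.4f}, "
                f"outside 1 +/- {self.prop_tolerance}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def cohort_samples(self, cohort: str) -> pd.Index:
        return self.table.index[self.table["cohort"] == cohort]

    def proportions(self) -> pd.DataFrame:
        return self.table[list(CELL_TYPES)].astype(float)


@dataclass
class MqtlTable:
    """SNP-CpG association records: snp_id, snp_chrom, snp_pos (1-based), cpg_id."""

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in ("snp_id", "snp_chrom", "snp_pos", "cpg_id")
                   if c not in self.table.columns]
        if missing:
            raise ValidationError(f"mQTL table missing columns: {missing}")
        self.table = self.table.copy()
        self.table["snp_chrom"] = self.table["snp_chrom"].map(normalize_chrom)
        if (self.table["snp_pos"].to_numpy() < 1).any():
            raise ValidationError("SNP positions must be >= 1 (1-based)")
        dup = self.table.duplicated(subset=["snp_id", "cpg_id"])
        if dup.any():
            raise ValidationError(
                f"duplicate (snp_id, cpg_id) pairs, e.g. "
                f"{self.table.loc[dup, ['snp_id', 'cpg_id']].iloc[0].tolist()}"
            )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenomeIntervals:
    """TADs (BED, 0-based half-open) and chromatin loops (BEDPE anchor pairs).

    ``tads``: columns chrom, start, end. ``loops``: columns chrom, startA,
    endA, startB, endB (anchors of one loop share a chromosome).
    """

    tads: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end"]))
    loops: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "startA", "endA", "startB", "endB"]))

    def __post_init__(self):
        self.tads = self.tads.copy()
        self.loops = self.loops.copy()
        if len(self.tads):
            self.tads["chrom"] = self.tads["chrom"].map(normalize_chrom)
            bad = self.tads["start"] >= self.tads["end"]
            if bad.any():
                row = self.tads[bad].iloc[0]
                raise ValidationError(
                    f"TAD with start >= end: {row['chrom']}:{row['start']}-{row['end']}"
                )
        if len(self.loops):
            self.loops["chrom"] = self.loops["chrom"].map(normalize_chrom)
            for s, e in (("startA", "endA"), ("startB", "endB")):
                bad = self.loops[s] >= self.loops[e]
                if bad.any():
                    row = self.loops[bad].iloc[0]
                    raise ValidationError(
                        f"loop anchor with start >= end: "
                        f"{row['chrom']}:{row[s]}-{row[e]}"
                    )

    def validate_tads_nonoverlapping(self) -> None:
        """TAD containment tests require disjoint TADs per chromosome."""
        for chrom, grp in self.tads.groupby("chrom"):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValidationError(f"overlapping TADs on {chrom}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression levels."""

    values: pd.DataFrame

    def __post_init__(self):
        if self.values.shape[0] == 0:
            raise ValidationError("no genes")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative expression at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns
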