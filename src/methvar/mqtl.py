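"""mQTL annotation: cis/trans classification and 3D-chromatin co-occupancy.

A SNP-CpG pair is *cis* when both sit on the same chromosome within
``cis_window_bp`` (default 500 bp -- a deliberately small, nucleosome-scale
window meant to capture effects of sequence variation in or immediately
flanking the probe) and *trans* otherwise, including all interchromosomal
pairs. CpGs annotated to several SNPs can be cis-and-trans. Trans pairs are
then tested for 3D proximity: occupying the same TAD, or being connected by
a chromatin loop (one position in each anchor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.stats import fisher_exact

from .datatypes import GenomeIntervals, MqtlTable, ProbeManifest


@dataclass
class PairRecord:
    snp_id: str
    cpg_id: str
    snp_chrom: str
    snp_pos: int
    cpg_chrom: str
    cpg_pos: int
    distance_bp: float          # NaN for interchromosomal pairs
    pair_class: str             # cis | trans
    same_tad: bool = False
    loop_connected: bool = False


def classify_pair(snp_chrom: str, snp_pos: int, cpg_chrom: str, cpg_pos: int,
                  window_bp: int = 500) -> tuple[str, float]:
    """(pair_class, distance) of one SNP-CpG pair; 1-based positions.

    cis iff same chromosome and |snp - cpg| <= window_bp; distance is NaN
    for interchromosomal pairs.
    """
    if snp_pos is None or cpg_pos is None or np.isnan(snp_pos) or np.isnan(cpg_pos):
        raise ValueError("missing position")
    if snp_chrom != cpg_chrom:
        return "trans", float("nan")
    d = abs(int(snp_pos) - int(cpg_pos))
    return ("cis" if d <= window_bp else "trans"), float(d)


def classify_pairs(mqtl: MqtlTable, manifest: ProbeManifest,
                   window_bp: int = 500) -> pd.DataFrame:
    """Pair table for every mQTL record whose CpG is in the manifest.

    Columns: snp_id, cpg_id, snp_chrom, snp_pos, cpg_chrom, cpg_pos,
    distance_bp, pair_class.
    """
    t = mqtl.table.merge(
        manifest.table[["chrom", "pos"]].rename(
            columns={"chrom": "cpg_chrom", "pos": "cpg_pos"}),
        left_on="cpg_id", right_index=True, how="inner",
    ).reset_index(drop=True)
    same = t["snp_chrom"] == t["cpg_chrom"]
    dist = (t["snp_pos"] - t["cpg_pos"]).abs().astype(float)
    dist[~same] = np.nan
    t["distance_bp"] = dist
    t["pair_class"] = np.where(same & (dist <= window_bp), "cis", "trans")
    return t


def summarize_cpg(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG partner counts and class: cis, trans, cis_and_trans or none."""
    grp = pairs.groupby("cpg_id")["pair_class"]
    n_cis = grp.apply(lambda s: int((s == "cis").sum()))
    n_trans = grp.apply(lambda s: int((s == "trans").sum()))
    out = pd.DataFrame({"n_cis_partners": n_cis, "n_trans_partners": n_trans})
    out["cpg_class"] = np.select(
        [
            (out["n_cis_partners"] > 0) & (out["n_trans_partners"] > 0),
            out["n_cis_partners"] > 0,
            out["n_trans_partners"] > 0,
        ],
        ["cis_and_trans", "cis", "trans"],
        default="none",
    )
    out.index.name = "cpg_id"
    return out


def _tad_index(pos_1based, chrom, tads_by_chrom) -> int:
    """Index of the TAD containing a 1-based position, or -1.

    Containment uses the 0-based half-open convention: a position at a TAD
    start is inside, at the end outside.
    """
    if chrom not in tads_by_chrom:
        return -1
    starts, ends, base = tads_by_chrom[chrom]
    p0 = int(pos_1based) - 1
    i = np.searchsorted(starts, p0, side="right") - 1
    if i >= 0 and p0 < ends[i]:
        return base + i
    return -1


def _build_tad_lookup(tads: pd.DataFrame):
    by = {}
    base = 0
    for chrom, grp in tads.groupby("chrom", sort=True):
        g = grp.sort_values("start")
        by[chrom] = (g["start"].to_numpy(), g["end"].to_numpy(), base)
        base += len(g)
    return by


def same_tad(snp_chrom, snp_pos, cpg_chrom, cpg_pos,
             intervals: GenomeIntervals) -> bool:
    """True iff one TAD contains both 1-based positions."""
    intervals.validate_tads_nonoverlapping()
    if snp_chrom != cpg_chrom:
        return False
    lookup = _build_tad_lookup(intervals.tads)
    a = _tad_index(snp_pos, snp_chrom, lookup)
    return a >= 0 and a == _tad_index(cpg_pos, cpg_chrom, lookup)


def loop_connected(snp_chrom, snp_pos, cpg_chrom, cpg_pos,
                   intervals: GenomeIntervals) -> bool:
    """True iff a loop has the SNP in one anchor and the CpG in the other.

    Both positions inside the *same single* anchor does not count.
    """
    if snp_chrom != cpg_chrom:
        return False
    loops = intervals.loops
    sub = loops[loops["chrom"] == snp_chrom]
    s0 = int(snp_pos) - 1
    c0 = int(cpg_pos) - 1
    for _, r in sub.iterrows():
        in_a = r["startA"] <= s0 < r["endA"]
        in_b = r["startB"] <= s0 < r["endB"]
        cin_a = r["startA"] <= c0 < r["endA"]
        cin_b = r["startB"] <= c0 < r["endB"]
        if (in_a and cin_b) or (in_b and cin_a):
            return True
    return False


def annotate_pairs_3d(pairs: pd.DataFrame, intervals: GenomeIntervals) -> pd.DataFrame:
    """Vectorised same-TAD and loop-connected flags for a pair table."""
    intervals.validate_tads_nonoverlapping()
    lookup = _build_tad_lookup(intervals.tads)
    out = pairs.copy()
    same_t = np.zeros(len(out), dtype=bool)
    loop_c = np.zeros(len(out), dtype=bool)
    loops_by_chrom = dict(tuple(intervals.loops.groupby("chrom")))
    for i, r in enumerate(out.itertuples(index=False)):
        if r.snp_chrom != r.cpg_chrom:
            continue
        a = _tad_index(r.snp_pos, r.snp_chrom, lookup)
        if a >= 0 and a == _tad_index(r.cpg_pos, r.cpg_chrom, lookup):
            same_t[i] = True
        sub = loops_by_chrom.get(r.snp_chrom)
        if sub is not None:
            s0 = int(r.snp_pos) - 1
            c0 = int(r.cpg_pos) - 1
            sa = sub["startA"].to_numpy(); ea = sub["endA"].to_numpy()
            sb = sub["startB"].to_numpy(); eb = sub["endB"].to_numpy()
            in_a = (sa <= s0) & (s0 < ea)
            in_b = (sb <= s0) & (s0 < eb)
            cin_a = (sa <= c0) & (c0 < ea)
            cin_b = (sb <= c0) & (c0 < eb)
            loop_c[i] = bool(((in_a & cin_b) | (in_b & cin_a)).any())
    out["same_tad"] = same_t
    out["loop_connected"] = loop_c
    return out


def co_occupancy_enrichment(pairs_set: pd.DataFrame,
                            pairs_background: pd.DataFrame) -> pd.DataFrame:
    """Same-TAD / loop-connected fractions of a pair set vs a background.

    One row per co-occupancy kind with both fractions, log2 ratio and the
    two-sided Fisher p from the 2x2 of (set vs background) x (co-occupying
    vs not). Pair collections must be non-empty and already annotated.
    """
    if len(pairs_set) == 0 or len(pairs_background) == 0:
        raise ValueError("empty pair collection")
    rows = []
    for kind in ("same_tad", "loop_connected"):
        a = int(pairs_set[kind].sum())
        n_a = len(pairs_set)
        b = int(pairs_background[kind].sum())
        n_b = len(pairs_background)
        table = np.array([[a, n_a - a], [b, n_b - b]])
        p = float(fisher_exact(table, alternative="two-sided")[1])
        fa, fb = a / n_a, b / n_b
        rows.append({
            "kind": kind, "n_set": n_a, "n_in_set": a, "set_fraction": fa,
            "n_background": n_b, "n_in_background": b, "background_fraction": fb,
            "log2_ratio": np.nan if (fa == 0 or fb == 0) else float(np.log2(fa / fb)),
            "fisher_p": p,
        })
    return pd.DataFrame(rows)
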