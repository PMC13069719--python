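"""Linking methylation variability and gene expression.

Two modes, mirroring the two kinds of data that are usually available:

* *variation vs variation* (unmatched cohorts): Pearson correlation, across
  probe-gene pairs, of the probe's methylation SD with the target gene's
  expression coefficient of variation (CV = SD / mean). The two matrices
  need not share samples.
* *level vs level* (matched samples): per probe-gene pair, Pearson
  correlation of methylation and expression across the shared samples;
  summarised per genomic feature group as the mean pair correlation.

Feature stratification uses the manifest's feature vocabulary; a probe
carrying several features contributes to each group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datatypes import FEATURES, BetaMatrix, ExpressionMatrix, ProbeManifest
from .variability import probe_sd


def expression_cv(expr: ExpressionMatrix) -> pd.Series:
    """Coefficient of variation (sample SD / mean) per gene.

    Genes with non-positive mean expression are excluded (counted in the
    series' attrs); an all-excluded matrix raises.
    """
    arr = expr.values.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    keep = mean > 0
    if not keep.any():
        raise ValueError("all genes excluded: non-positive mean expression")
    sd = arr[keep].std(axis=1, ddof=1)
    cv = pd.Series(sd / mean[keep], index=expr.gene_ids[keep], name="cv")
    cv.attrs["n_excluded"] = int((~keep).sum())
    return cv


def map_probe_to_gene(probe_ids, manifest: ProbeManifest) -> pd.DataFrame:
    """(probe, gene, features) triples from the manifest gene link.

    Probes with several listed genes (separated by ``;``) take the first;
    probes without a gene are dropped (count in attrs).
    """
    rows = []
    dropped = 0
    for p in probe_ids:
        gene = str(manifest.table.at[p, "gene"]) if p in manifest.table.index else ""
        gene = gene.split(";")[0] if gene else ""
        if not gene:
            dropped += 1
            continue
        rows.append({"probe_id": p, "gene": gene,
                     "features": manifest.table.at[p, "features"]})
    out = pd.DataFrame(rows, columns=["probe_id", "gene", "features"])
    out.attrs["n_dropped"] = dropped
    return out


def _feature_groups(triples: pd.DataFrame):
    split = triples["features"].fillna("").str.split(";")
    for feat in FEATURES:
        mask = split.map(lambda fs: feat in fs)
        if mask.any():
            yield feat, triples[mask]
    yield "all", triples


def correlate_variation(probe_ids, betas: BetaMatrix, expr: ExpressionMatrix,
                        manifest: ProbeManifest) -> pd.DataFrame:
    """Pearson r of methylation SD vs expression CV per feature group.

    Cohorts need not share samples. Groups with fewer than 3 pairs, or a
    degenerate (zero-variance) axis, are reported with r undefined.
    """
    triples = map_probe_to_gene(probe_ids, manifest)
    sd = probe_sd(betas)
    cv = expression_cv(expr)
    triples = triples[triples["probe_id"].isin(sd.index)
                      & triples["gene"].isin(cv.index)]
    rows = []
    for feat, grp in _feature_groups(triples):
        x = sd[grp["probe_id"]].to_numpy()
        y = cv[grp["gene"]].to_numpy()
        rows.append(_corr_row(feat, x, y, mode="variation_vs_variation"))
    return pd.DataFrame(rows)


def correlate_levels(probe_ids, betas: BetaMatrix, expr: ExpressionMatrix,
                     manifest: ProbeManifest) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched-sample level-vs-level correlations.

    Returns (per feature-group summary with the mean pair r, per-pair
    records). Requires >= 3 shared samples between the matrices.
    """
    shared = [s for s in betas.sample_ids if s in set(expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    triples = map_probe_to_gene(probe_ids, manifest)
    triples = triples[triples["gene"].isin(expr.gene_ids)]
    b = betas.values.loc[:, shared]
    e = expr.values.loc[:, shared]
    pair_rows = []
    for t in triples.itertuples(index=False):
        x = b.loc[t.probe_id].to_numpy(dtype=float)
        y = e.loc[t.gene].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = pearsonr(x[ok], y[ok])
        pair_rows.append({"probe_id": t.probe_id, "gene": t.gene,
                          "features": t.features, "n": int(ok.sum()),
                          "pearson_r": r, "r_p_value": p})
    pairs = pd.DataFrame(pair_rows)
    rows = []
    for feat, _ in _feature_groups(triples):
        if feat == "all":
            sub = pairs
        else:
            sub = pairs[pairs["features"].fillna("").str.split(";")
                        .map(lambda fs: feat in fs)]
        sub = sub.dropna(subset=["pearson_r"])
        rows.append({
            "feature": feat, "mode": "level_vs_level", "n": len(sub),
            "mean_r": sub["pearson_r"].mean() if len(sub) else np.nan,
        })
    return pd.DataFrame(rows), pairs


def _corr_row(feat: str, x: np.ndarray, y: np.ndarray, mode: str) -> dict:
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        r, p = np.nan, np.nan
    else:
        r, p = pearsonr(x, y)
    return {"feature": feat, "mode": mode, "n": n, "pearson_r": r,
            "r_p_value": p, "significance": _stars(p)}


def _stars(p) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."
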