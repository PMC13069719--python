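"""Screening variably methylated probes for putative epialleles.

A putative epiallele is a VMP whose pooled mean beta is intermediate
(inside ``epiallele_mean_window``, inclusive at both ends) and whose
distribution of betas across individuals is bimodal by Hartigan's dip test
(Monte-Carlo p-value below ``dip_alpha``) -- the signature of two
population subgroups in distinct epigenetic states at one locus.

Non-candidate VMPs are reported with ``is_epiallele=False`` and no dip
computed; degenerate (constant) candidates are reported with the minimal
dip for their sample size rather than crashing the screen. A
Benjamini-Hochberg adjusted column is emitted alongside the raw dip
p-values for users who want multiplicity control; the epiallele flag
itself uses the raw p-value threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import BetaMatrix
from .dip import dip_statistic, dip_pvalue
from .variability import VariabilityCatalog


def screen_epialleles(betas: BetaMatrix, catalog: VariabilityCatalog,
                      config: PipelineConfig,
                      validation_betas: BetaMatrix | None = None) -> pd.DataFrame:
    """Dip-test screen of VMPs with intermediate pooled mean methylation.

    Parameters
    ----------
    betas : BetaMatrix
        Discovery betas; if ``validation_betas`` is given, means and dip
        tests are computed on the samples of both cohorts pooled.
    catalog : VariabilityCatalog
        Output of :func:`methvar.variability.call_catalog` on the same probes.
    config : PipelineConfig
        Supplies the mean window, alpha, Monte-Carlo replicates and seed.

    Returns
    -------
    DataFrame indexed by probe id with columns mean_beta, dip_stat, dip_p,
    dip_p_bh, is_epiallele, is_candidate, degenerate.
    """
    missing = set(catalog.table.index) - set(betas.probe_ids)
    if missing:
        raise ValueError(f"catalog covers probes absent from betas: "
                         f"{sorted(missing)[:5]}")
    if validation_betas is not None:
        pooled = pd.concat([betas.values, validation_betas.values], axis=1)
    else:
        pooled = betas.values

    lo, hi = config.epiallele_mean_window
    vmps = catalog.vmps
    mean = pooled.mean(axis=1, skipna=True)

    out = pd.DataFrame(index=pooled.index.copy())
    out.index.name = "probe_id"
    out["mean_beta"] = mean
    out["is_vmp"] = [p in vmps for p in out.index]
    out["is_candidate"] = out["is_vmp"] & (mean >= lo) & (mean <= hi)
    out["dip_stat"] = np.nan
    out["dip_p"] = np.nan
    out["degenerate"] = False

    arr = pooled.to_numpy(dtype=float)
    idx_positions = {p: i for i, p in enumerate(pooled.index)}
    for probe in out.index[out["is_candidate"]]:
        x = arr[idx_positions[probe]]
        x = x[~np.isnan(x)]
        n = x.size
        if np.min(x) == np.max(x):
            out.at[probe, "dip_stat"] = 1.0 / (2 * n)
            out.at[probe, "degenerate"] = True
            out.at[probe, "dip_p"] = 1.0
            continue
        d = dip_statistic(x)
        out.at[probe, "dip_stat"] = d
        out.at[probe, "dip_p"] = dip_pvalue(d, n, B=config.dip_mc_reps,
                                            rng_seed=config.rng_seed)

    cand = out["is_candidate"] & ~out["degenerate"]
    out["dip_p_bh"] = np.nan
    if cand.any():
        out.loc[cand, "dip_p_bh"] = multipletests(
            out.loc[cand, "dip_p"].to_numpy(), method="fdr_bh")[1]
    out["is_epiallele"] = cand & (out["dip_p"] < config.dip_alpha)
    return out
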