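"""End-to-end orchestration of the variability pipeline.

Stages run in order: variability calling, cell-composition correction and
re-calling, genomic-context enrichment, mQTL cis/trans + 3D co-occupancy,
epiallele screening, expression correlation. Each stage writes its result
tables (TSV with the config snapshot) into the output directory; any stage
failure aborts the run with the stage name and cause. Identical inputs,
config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import io as mio
from .cells import (cell_sensitivity_report, corrected_betas, fit_cell_model,
                    sensitivity_table)
from .config import PipelineConfig
from .datatypes import BetaMatrix
from .enrichment import enrichment_table
from .epialleles import screen_epialleles
from .expression import correlate_levels, correlate_variation
from .mqtl import annotate_pairs_3d, classify_pairs, co_occupancy_enrichment, summarize_cpg
from .variability import call_catalog

log = logging.getLogger("methvar")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, inputs: dict, out_dir) -> dict:
    """Run every stage on the given input paths; returns result objects.

    ``inputs`` maps names (betas_discovery, betas_validation, manifest,
    sample_sheet, mqtl, tads, loops, expression) to file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snap = config.snapshot()
    results: dict = {}

    def _stage(name):
        log.info("stage: %s", name)
        def deco(fn):
            try:
                results[name] = fn()
            except Exception as err:  # noqa: BLE001 - reported with stage name
                raise StageError(name, err) from err
            return results[name]
        return deco

    @_stage("load")
    def _load():
        betas_d = mio.read_beta_matrix(inputs["betas_discovery"])
        betas_v = mio.read_beta_matrix(inputs["betas_validation"])
        betas_d = betas_d.drop_high_missing(config.max_missing_frac)
        betas_v = betas_v.drop_high_missing(config.max_missing_frac)
        common = betas_d.probe_ids.intersection(betas_v.probe_ids)
        betas_d = BetaMatrix(betas_d.values.loc[common])
        betas_v = BetaMatrix(betas_v.values.loc[common])
        return {
            "betas_discovery": betas_d,
            "betas_validation": betas_v,
            "manifest": mio.read_manifest(inputs["manifest"]),
            "sheet": mio.read_sample_sheet(inputs["sample_sheet"]),
            "mqtl": mio.read_mqtl_table(inputs["mqtl"]),
            "intervals": mio.read_genome_intervals(inputs["tads"], inputs["loops"]),
            "expression": mio.read_expression_matrix(inputs["expression"]),
        }

    data = results["load"]
    betas_d, betas_v = data["betas_discovery"], data["betas_validation"]
    manifest, sheet = data["manifest"], data["sheet"]

    @_stage("call_variability")
    def _call():
        catalog = call_catalog(betas_d, betas_v, config)
        mio.write_result_table(catalog.table, out / "variability_catalog.tsv", snap)
        return catalog

    catalog = results["call_variability"]

    @_stage("adjust_cells")
    def _cells():
        fit_d = fit_cell_model(betas_d, sheet)
        fit_v = fit_cell_model(betas_v, sheet)
        corr_d = corrected_betas(fit_d)
        corr_v = corrected_betas(fit_v)
        mio.write_beta_matrix(corr_d, out / "betas_discovery_cellcorrected.tsv", snap)
        mio.write_beta_matrix(corr_v, out / "betas_validation_cellcorrected.tsv", snap)
        # same seeds as the raw catalogue so differences reflect correction
        catalog_adj = call_catalog(corr_d, corr_v, config)
        mio.write_result_table(catalog_adj.table,
                               out / "variability_catalog_cellcorrected.tsv", snap)
        report = cell_sensitivity_report(catalog, catalog_adj)
        mio.write_result_table(sensitivity_table(report),
                               out / "cell_sensitivity.tsv", snap, index=False)
        log.info("corrected betas out of [0,1]: %.3f%% / %.3f%%",
                 100 * fit_d.out_of_range_rate(), 100 * fit_v.out_of_range_rate())
        return {"catalog_adjusted": catalog_adj, "report": report}

    @_stage("enrichment")
    def _enrich():
        tables = []
        for name, ids in (("VMP", catalog.vmps), ("SMP", catalog.smps)):
            if ids:
                tables.append(enrichment_table(
                    ids, manifest, set_name=name, imprinted_perm=True,
                    n_reps=config.permutation_reps, rng_seed=config.rng_seed))
        tab = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        mio.write_result_table(tab, out / "enrichment.tsv", snap, index=False)
        return tab

    @_stage("mqtl_chromatin")
    def _mqtl():
        pairs = classify_pairs(data["mqtl"], manifest, config.cis_window_bp)
        pairs = annotate_pairs_3d(pairs, data["intervals"])
        summary = summarize_cpg(pairs)
        mio.write_result_table(pairs, out / "mqtl_pairs.tsv", snap, index=False)
        mio.write_result_table(summary, out / "mqtl_cpg_summary.tsv", snap)
        co = []
        trans = pairs[pairs["pair_class"] == "trans"]
        for name, ids in (("VMP", catalog.vmps), ("SMP", catalog.smps)):
            sub = trans[trans["cpg_id"].isin(ids)]
            if len(sub) and len(trans):
                c = co_occupancy_enrichment(sub, trans)
                c.insert(0, "set", name)
                co.append(c)
        co_tab = pd.concat(co, ignore_index=True) if co else pd.DataFrame()
        mio.write_result_table(co_tab, out / "co_occupancy.tsv", snap, index=False)
        return {"pairs": pairs, "summary": summary, "co_occupancy": co_tab}

    @_stage("epialleles")
    def _epi():
        records = screen_epialleles(betas_d, catalog, config,
                                    validation_betas=betas_v)
        mio.write_result_table(records, out / "epialleles.tsv", snap)
        return records

    epialleles = results["epialleles"]

    @_stage("expression_link")
    def _expr():
        epi_ids = list(epialleles.index[epialleles["is_epiallele"]])
        target = epi_ids if epi_ids else sorted(catalog.vmps)
        var_tab = correlate_variation(target, betas_d, data["expression"], manifest)
        mio.write_result_table(var_tab, out / "correlation_variation.tsv", snap,
                               index=False)
        shared = set(betas_d.sample_ids) & set(data["expression"].sample_ids)
        if len(shared) >= 3:
            lvl_tab, lvl_pairs = correlate_levels(target, betas_d,
                                                  data["expression"], manifest)
            mio.write_result_table(lvl_tab, out / "correlation_levels.tsv", snap,
                                   index=False)
            mio.write_result_table(lvl_pairs, out / "correlation_level_pairs.tsv",
                                   snap, index=False)
        else:
            lvl_tab, lvl_pairs = None, None
        return {"variation": var_tab, "levels": lvl_tab, "level_pairs": lvl_pairs}

    run_log = {
        "config": config.to_dict(),
        "inputs": {k: str(v) for k, v in inputs.items()},
        "n_probes": int(betas_d.n_probes),
        "n_samples_discovery": int(betas_d.n_samples),
        "n_samples_validation": int(betas_v.n_samples),
        "n_vmp": len(catalog.vmps),
        "n_smp": len(catalog.smps),
        "n_epialleles": int(epialleles["is_epiallele"].sum()),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return results
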