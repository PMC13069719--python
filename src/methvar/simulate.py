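"""Synthetic EPIC-array-like data with planted structure.

The generator emulates the features of population whole-blood methylation
data that the pipeline is designed to detect, with known ground truth:

* *stable* probes near full (un)methylation drawn from high-concentration
  beta distributions (tight low/high beta values across individuals);
* *variable unimodal* probes with intermediate means and low concentration;
* *epiallele-like bimodal* probes: two-component beta mixtures with
  per-sample component assignment (two subpopulations of epigenetic state);
* *cell-driven* probes whose mean tracks one blood cell-type proportion;
* *mQTL-driven* probes whose mean shifts additively with a biallelic
  Hardy-Weinberg genotype;
* a probe manifest whose island/feature annotations are class-dependent
  (variable probes preferentially at shores/enhancers, stable probes at
  islands/promoters), with TADs tiling each chromosome, long-range loops,
  and SNP placement controlling the cis share and the same-TAD / loop
  co-occupancy of mQTL pairs;
* a gene-expression matrix over the discovery samples whose per-gene
  coefficient of variation is coupled to the methylation SD of the gene's
  probe through a Gaussian copula on ranks, plus a planted *negative*
  level-coupling for genes of bimodal probes annotated to 5'UTRs.

Two cohorts (discovery/validation) are independent draws from the same
design. All randomness derives from ``design.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CELL_TYPES,
    BetaMatrix,
    ExpressionMatrix,
    GenomeIntervals,
    MqtlTable,
    ProbeManifest,
    SampleSheet,
)
from . import io as mio

PROBE_CLASSES = (
    "stable_low",
    "stable_high",
    "variable_unimodal",
    "epiallele_bimodal",
    "cell_driven",
    "mqtl_driven",
)

# Mean blood cell-type fractions used for the Dirichlet prior
_CELL_MEANS = {"CD8T": 0.10, "CD4T": 0.16, "NK": 0.04, "B": 0.08,
               "Mono": 0.07, "Gran": 0.55}
# cell-driven probes track one of the five proportions retained in the
# correction model, so that correcting for composition can remove them
_DRIVABLE_CELLS = ("CD8T", "CD4T", "B", "Mono", "Gran")


@dataclass
class SimulationDesign:
    """Knobs of the synthetic bundle; defaults are the study conditions."""

    n_probes: int = 2000
    n_samples_discovery: int = 400
    n_samples_validation: int = 400
    class_mix: dict = field(default_factory=lambda: {
        "stable_low": 0.15,
        "stable_high": 0.15,
        "variable_unimodal": 0.50,
        "epiallele_bimodal": 0.02,
        "cell_driven": 0.10,
        "mqtl_driven": 0.08,
    })
    # beta-family concentration (a+b) per class (central value; see
    # concentration_spread for per-probe heterogeneity)
    concentration: dict = field(default_factory=lambda: {
        "stable_low": 200.0,
        "stable_high": 200.0,
        "variable_unimodal": 40.0,
        "epiallele_bimodal": 50.0,
        "cell_driven": 300.0,
        "mqtl_driven": 150.0,
    })
    # per-probe multiplicative concentration range (lo, hi) per class; probes
    # draw log-uniform factors so stable probes differ in how stable they are
    # (a realistic long tail of ultra-stable probes) and variable probes in
    # how variable; classes not listed use a fixed concentration
    concentration_spread: dict = field(default_factory=lambda: {
        "stable_low": (0.75, 8.0),
        "stable_high": (0.75, 8.0),
        "variable_unimodal": (1.5, 8.0),
    })
    stable_low_mean: float = 0.05
    stable_high_mean: float = 0.95
    variable_mean_range: tuple[float, float] = (0.40, 0.60)
    bimodal_modes: tuple[float, float] = (0.25, 0.75)
    bimodal_weight: float = 0.5
    cell_baseline: float = 0.05
    cell_effect: float = 0.80
    cell_effect_range: tuple[float, float] = (0.5, 1.2)
    mqtl_baseline: float = 0.25
    mqtl_effect: float = 0.10
    mqtl_effect_range: tuple[float, float] = (0.4, 1.6)
    maf: float = 0.30
    cell_dirichlet_scale: float = 60.0
    # mQTL geometry
    cis_fraction: float = 0.25
    same_tad_share: float = 0.90
    loop_share: float = 0.05
    second_snp_fraction: float = 0.15
    # expression
    gene_fraction: float = 0.60
    n_expression_samples: int | None = None  # defaults to discovery samples
    expr_coupling_rho: float = 0.60
    expr_cv_mean: float = 0.30
    expr_cv_sd: float = 0.08
    utr5_coupling_strength: float = 0.9
    rng_seed: int = 0

    def __post_init__(self):
        total = sum(self.class_mix.get(c, 0.0) for c in PROBE_CLASSES)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        unknown = set(self.class_mix) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes in class_mix: {sorted(unknown)}")
        lo, hi = self.bimodal_modes
        m = self.bimodal_weight * lo + (1 - self.bimodal_weight) * hi
        if not 0 < m < 1 or not (0 < lo < 1 and 0 < hi < 1):
            raise ValueError("infeasible bimodal modes/weight")


@dataclass
class GroundTruth:
    """Planted per-probe class labels, drivers and per-gene CV targets."""

    table: pd.DataFrame  # index probe_id: class, driver, gene, cv_target

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["class"] == cls]


@dataclass
class SimulatedBundle:
    betas_discovery: BetaMatrix
    betas_validation: BetaMatrix
    manifest: ProbeManifest
    sheet: SampleSheet
    mqtl: MqtlTable
    intervals: GenomeIntervals
    expression: ExpressionMatrix
    truth: GroundTruth
    clip_rate: float = 0.0


def _beta_from_mean(rng, mean, conc, size=None):
    mean = np.clip(mean, 1e-4, 1 - 1e-4)
    return rng.beta(mean * conc, (1 - mean) * conc, size=size)


_ISLAND_BASE = {"island": 0.30, "shore": 0.25, "shelf": 0.10, "open_sea": 0.35}
_ISLAND_VARIABLE = {"island": 0.10, "shore": 0.50, "shelf": 0.10, "open_sea": 0.30}
_ISLAND_STABLE = {"island": 0.55, "shore": 0.15, "shelf": 0.10, "open_sea": 0.20}

_PRIMARY_BASE = {"promoter": 0.20, "exon": 0.10, "intron": 0.30, "5UTR": 0.07,
                 "3UTR": 0.05, "intergenic": 0.20, "TE": 0.08}
_PRIMARY_VARIABLE = {"promoter": 0.08, "exon": 0.07, "intron": 0.33, "5UTR": 0.12,
                     "3UTR": 0.04, "intergenic": 0.28, "TE": 0.08}
_PRIMARY_STABLE = {"promoter": 0.38, "exon": 0.12, "intron": 0.18, "5UTR": 0.12,
                   "3UTR": 0.04, "intergenic": 0.10, "TE": 0.06}


def _choice_from(rng, table):
    keys = list(table)
    p = np.asarray([table[k] for k in keys], float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def simulate_bundle(design: SimulationDesign) -> SimulatedBundle:
    """Generate the full synthetic input bundle with ground truth."""
    ss = np.random.SeedSequence(design.rng_seed)
    (ss_class, ss_disc, ss_valid, ss_sheet, ss_manifest, ss_geno, ss_expr) = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]

    P = design.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(P)])

    classes = np.concatenate([
        np.full(int(round(design.class_mix.get(c, 0.0) * P)), c, dtype=object)
        for c in PROBE_CLASSES
    ])
    # rounding may leave a few probes unassigned; fill with the largest class
    if classes.size < P:
        filler = max(design.class_mix, key=design.class_mix.get)
        classes = np.concatenate([classes, np.full(P - classes.size, filler, dtype=object)])
    classes = classes[:P]
    ss_class.shuffle(classes)

    # --- sample sheet (both cohorts share the Dirichlet prior) -------------
    n_d, n_v = design.n_samples_discovery, design.n_samples_validation
    sample_ids = (
        [f"D{i:05d}" for i in range(n_d)] + [f"V{i:05d}" for i in range(n_v)]
    )
    alpha = np.array([_CELL_MEANS[c] for c in CELL_TYPES]) * design.cell_dirichlet_scale
    props = ss_sheet.dirichlet(alpha, size=n_d + n_v)
    sheet_df = pd.DataFrame(props, columns=list(CELL_TYPES),
                            index=pd.Index(sample_ids, name="sample_id"))
    sheet_df.insert(0, "cohort", ["discovery"] * n_d + ["validation"] * n_v)
    sheet_df["sex"] = ss_sheet.choice(["F", "M"], size=n_d + n_v)
    sheet_df["age"] = ss_sheet.integers(20, 80, size=n_d + n_v)
    sheet_df["smoking"] = ss_sheet.choice(["never", "former", "current"],
                                          p=[0.55, 0.25, 0.20], size=n_d + n_v)
    sheet = SampleSheet(sheet_df)

    # --- per-probe static parameters --------------------------------------
    var_lo, var_hi = design.variable_mean_range
    base_mean = np.empty(P)
    driver = np.full(P, "", dtype=object)
    conc_factor = np.ones(P)
    effect_size = np.zeros(P)
    for i, cls in enumerate(classes):
        lo_f, hi_f = design.concentration_spread.get(cls, (1.0, 1.0))
        if hi_f != lo_f:
            conc_factor[i] = np.exp(ss_class.uniform(np.log(lo_f), np.log(hi_f)))
        if cls == "cell_driven":
            effect_size[i] = design.cell_effect * ss_class.uniform(
                *design.cell_effect_range)
        elif cls == "mqtl_driven":
            effect_size[i] = design.mqtl_effect * ss_class.uniform(
                *design.mqtl_effect_range)
        if cls == "stable_low":
            base_mean[i] = design.stable_low_mean
        elif cls == "stable_high":
            base_mean[i] = design.stable_high_mean
        elif cls == "variable_unimodal":
            base_mean[i] = ss_class.uniform(var_lo, var_hi)
        elif cls == "epiallele_bimodal":
            base_mean[i] = np.nan  # mixture, no single mean
        elif cls == "cell_driven":
            base_mean[i] = design.cell_baseline
            driver[i] = _DRIVABLE_CELLS[ss_class.integers(len(_DRIVABLE_CELLS))]
        else:  # mqtl_driven
            base_mean[i] = design.mqtl_baseline
            driver[i] = f"rs{i:08d}"

    # --- betas per cohort ---------------------------------------------------
    n_clipped = 0
    n_total = 0

    def _cohort(rng, samp_ids):
        nonlocal n_clipped, n_total
        n = len(samp_ids)
        prop = sheet.proportions().loc[samp_ids]
        out = np.empty((P, n))
        genotypes = {}
        for i, cls in enumerate(classes):
            conc = design.concentration[cls] * conc_factor[i]
            if cls == "epiallele_bimodal":
                lo_m, hi_m = design.bimodal_modes
                comp = rng.random(n) < design.bimodal_weight
                means = np.where(comp, lo_m, hi_m)
                out[i] = _beta_from_mean(rng, means, conc)
            elif cls == "cell_driven":
                mean = base_mean[i] + effect_size[i] * prop[driver[i]].to_numpy()
                clipped = np.clip(mean, 1e-4, 1 - 1e-4)
                n_clipped += int(np.sum(mean != clipped))
                n_total += n
                out[i] = _beta_from_mean(rng, clipped, conc)
            elif cls == "mqtl_driven":
                g = rng.binomial(2, design.maf, size=n).astype(float)
                genotypes[probe_ids[i]] = g
                mean = base_mean[i] + effect_size[i] * g
                clipped = np.clip(mean, 1e-4, 1 - 1e-4)
                n_clipped += int(np.sum(mean != clipped))
                n_total += n
                out[i] = _beta_from_mean(rng, clipped, conc)
            else:
                out[i] = _beta_from_mean(rng, base_mean[i], conc, size=n)
        df = pd.DataFrame(out, index=pd.Index(probe_ids, name="probe_id"),
                          columns=list(samp_ids))
        return BetaMatrix(df), genotypes

    betas_d, _ = _cohort(ss_disc, sample_ids[:n_d])
    betas_v, _ = _cohort(ss_valid, sample_ids[n_d:])

    # --- manifest, TADs, loops, mQTL geometry -------------------------------
    manifest_df, mqtl_df, intervals = _simulate_genome(
        design, ss_manifest, ss_geno, probe_ids, classes, driver)
    manifest = ProbeManifest(manifest_df)
    mqtl = MqtlTable(mqtl_df)

    # --- expression ----------------------------------------------------------
    expr, cv_target = _simulate_expression(
        design, ss_expr, manifest_df, classes, betas_d, probe_ids)

    truth_df = pd.DataFrame(
        {
            "class": classes,
            "driver": driver,
            "gene": manifest_df["gene"].to_numpy(),
            "cv_target": cv_target,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = GroundTruth(truth_df)
    clip_rate = n_clipped / n_total if n_total else 0.0

    return SimulatedBundle(
        betas_discovery=betas_d, betas_validation=betas_v, manifest=manifest,
        sheet=sheet, mqtl=mqtl, intervals=intervals, expression=expr,
        truth=truth, clip_rate=clip_rate,
    )


def _simulate_genome(design, rng, rng_geno, probe_ids, classes, driver):
    """Manifest positions/annotations plus TADs, loops and SNP placement."""
    P = len(probe_ids)
    chroms = [f"chr{c}" for c in range(1, 23)]
    tad_len, tad_gap, n_tads = 500_000, 100_000, 20
    anchor_len = 10_000

    tad_rows = []
    for ch in chroms:
        for t in range(n_tads):
            s = t * (tad_len + tad_gap)
            tad_rows.append((ch, s, s + tad_len))
    tads = pd.DataFrame(tad_rows, columns=["chrom", "start", "end"])

    loop_rows = []
    for ch in chroms:
        for t in range(0, n_tads - 4, 2):
            a = t * (tad_len + tad_gap) + 50_000
            b = (t + 3) * (tad_len + tad_gap) + 50_000
            loop_rows.append((ch, a, a + anchor_len, b, b + anchor_len))
    loops = pd.DataFrame(loop_rows,
                         columns=["chrom", "startA", "endA", "startB", "endB"])

    chrom_arr = np.empty(P, dtype=object)
    pos_arr = np.empty(P, dtype=int)
    island_arr = np.empty(P, dtype=object)
    features_arr = np.empty(P, dtype=object)
    mqtl_rows = []

    def _rand_tad_pos(ch_idx, margin=5_000):
        t = rng.integers(n_tads)
        s = t * (tad_len + tad_gap)
        return int(rng.integers(s + margin, s + tad_len - margin))

    for i, cls in enumerate(classes):
        ch_idx = int(rng.integers(len(chroms)))
        ch = chroms[ch_idx]
        chrom_arr[i] = ch
        variable = cls in ("variable_unimodal", "epiallele_bimodal")
        stable = cls in ("stable_low", "stable_high")
        island_arr[i] = _choice_from(
            rng, _ISLAND_VARIABLE if variable else _ISLAND_STABLE if stable
            else _ISLAND_BASE)
        primary = _choice_from(
            rng, _PRIMARY_VARIABLE if variable else _PRIMARY_STABLE if stable
            else _PRIMARY_BASE)
        feats = [primary]
        p_enh = 0.45 if variable else 0.12 if stable else 0.20
        if primary not in ("promoter",) and rng.random() < p_enh:
            feats.append("enhancer")
        features_arr[i] = ";".join(feats)

        if cls != "mqtl_driven":
            pos_arr[i] = _rand_tad_pos(ch_idx) if rng.random() < 0.85 else int(
                rng.integers(1, n_tads * (tad_len + tad_gap)))
            pos_arr[i] = max(1, pos_arr[i])
            continue

        # mQTL-driven probe: place CpG and its SNP with planted 3D geometry
        u = rng.random()
        if u < design.cis_fraction:
            cpg = _rand_tad_pos(ch_idx)
            d = int(rng.integers(1, 501))
            snp = cpg + (d if rng.random() < 0.5 else -d)
        elif u < design.cis_fraction + (1 - design.cis_fraction) * design.loop_share:
            ch_loops = loops[loops["chrom"] == ch]
            row = ch_loops.iloc[int(rng.integers(len(ch_loops)))]
            cpg = int(rng.integers(row["startA"] + 1, row["endA"] - 1))
            snp = int(rng.integers(row["startB"] + 1, row["endB"] - 1))
        elif rng.random() < design.same_tad_share:
            t = rng.integers(n_tads)
            s = t * (tad_len + tad_gap)
            cpg = int(rng.integers(s + 1_000, s + tad_len - 302_000))
            snp = cpg + int(rng.integers(1_000, 300_000))
        else:
            t = rng.integers(n_tads - 1)
            s = t * (tad_len + tad_gap)
            cpg = int(rng.integers(s + 1_000, s + tad_len - 1_000))
            s2 = (t + 1) * (tad_len + tad_gap)
            snp = int(rng.integers(s2 + 1_000, s2 + tad_len - 1_000))
        cpg = max(1, cpg)
        snp = max(1, snp)
        pos_arr[i] = cpg
        mqtl_rows.append((driver[i], ch, snp, probe_ids[i]))
        if rng.random() < design.second_snp_fraction:
            # a second, clearly distal SNP -> cis-and-trans CpGs exist
            snp2 = cpg + int(rng.integers(400_000, 2_000_000))
            mqtl_rows.append((driver[i] + "b", ch, snp2, probe_ids[i]))

    # gene links: a fraction of probes get a dedicated gene symbol
    gene_arr = np.full(P, "", dtype=object)
    has_gene = rng.random(P) < design.gene_fraction
    gidx = 0
    for i in range(P):
        if has_gene[i]:
            gene_arr[i] = f"G{gidx:05d}"
            gidx += 1

    imprint_p = np.where(np.isin(classes, ("variable_unimodal", "epiallele_bimodal")),
                         0.06, 0.01)
    noncpg_p = np.where(np.isin(classes, ("stable_low", "stable_high")), 0.06, 0.015)
    manifest_df = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "island_relation": island_arr,
            "features": features_arr,
            "gene": gene_arr,
            "imprinted": rng.random(P) < imprint_p,
            "non_cpg": rng.random(P) < noncpg_p,
            "on_450k": rng.random(P) < 0.45,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    mqtl_df = pd.DataFrame(mqtl_rows,
                           columns=["snp_id", "snp_chrom", "snp_pos", "cpg_id"])
    return manifest_df, mqtl_df, GenomeIntervals(tads=tads, loops=loops)


def _simulate_expression(design, rng, manifest_df, classes, betas_d, probe_ids):
    """Expression over the discovery samples; per-gene CV coupled to the
    realized methylation SD of the gene's probe via a Gaussian copula."""
    genes = manifest_df["gene"]
    mapped = np.where(genes.to_numpy() != "")[0]
    cv_target = np.full(len(probe_ids), np.nan)
    if mapped.size == 0:
        raise ValueError("design produced no gene-linked probes")
    sample_ids = list(betas_d.sample_ids)
    n = len(sample_ids)

    sd = betas_d.values.to_numpy()[mapped].std(axis=1, ddof=1)
    # normal scores of the SD ranks
    order = np.argsort(np.argsort(sd))
    from scipy.stats import norm
    u = norm.ppf((order + 1) / (mapped.size + 1))
    rho = design.expr_coupling_rho
    z = rho * u + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(mapped.size)
    cvs = np.maximum(0.05, design.expr_cv_mean + design.expr_cv_sd * z)

    utr5 = manifest_df["features"].str.split(";").map(lambda f: "5UTR" in f).to_numpy()
    values = np.empty((mapped.size, n))
    gene_ids = []
    for gi, pi in enumerate(mapped):
        gene_ids.append(genes.iloc[pi])
        mean = float(np.exp(rng.normal(np.log(100.0), 0.5)))
        if classes[pi] == "epiallele_bimodal" and utr5[pi]:
            # planted negative level-coupling at 5'UTR epialleles
            b = betas_d.values.to_numpy()[pi]
            base = mean * (1.5 - design.utr5_coupling_strength * b)
            noise = rng.normal(0, 0.05 * mean, size=n)
            values[gi] = np.maximum(0.0, base + noise)
            cv_target[pi] = np.nan
        else:
            cv = cvs[gi]
            shape = 1.0 / cv ** 2
            values[gi] = rng.gamma(shape, mean / shape, size=n)
            cv_target[pi] = cv
    expr = ExpressionMatrix(pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids))
    return expr, cv_target


def plant_phenotype_cpg_lists(truth: GroundTruth, fractions: dict,
                              rng_seed: int = 0) -> dict[str, list[str]]:
    """Labelled CpG lists sampled from designated true classes.

    ``fractions`` maps a list label to ``(probe_class, fraction)``; each list
    is a uniform sample of that fraction of the class's probes. These stand
    in for external phenotype-associated CpG catalogues (age, sex, smoking,
    cell type) in overlap reporting.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[str, list[str]] = {}
    for label, (cls, frac) in fractions.items():
        if not 0 <= frac <= 1:
            raise ValueError(f"fraction for {label!r} must be in [0, 1], got {frac}")
        pool = list(truth.probes_of_class(cls))
        n = int(round(frac * len(pool)))
        if n > len(pool):
            raise ValueError(f"fraction for {label!r} exceeds available probes")
        pick = sorted(rng.choice(len(pool), size=n, replace=False)) if n else []
        out[label] = [pool[i] for i in pick]
    return out


def write_bundle(bundle: SimulatedBundle, outdir, config_snapshot=None) -> dict[str, Path]:
    """Write the bundle in the exact formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas_discovery": outdir / "betas_discovery.tsv",
        "betas_validation": outdir / "betas_validation.tsv",
        "manifest": outdir / "manifest.csv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "mqtl": outdir / "mqtl.tsv",
        "tads": outdir / "tads.bed",
        "loops": outdir / "loops.bedpe",
        "expression": outdir / "expression.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    mio.write_beta_matrix(bundle.betas_discovery, paths["betas_discovery"], config_snapshot)
    mio.write_beta_matrix(bundle.betas_validation, paths["betas_validation"], config_snapshot)
    mio.write_manifest(bundle.manifest, paths["manifest"], config_snapshot)
    mio.write_sample_sheet(bundle.sheet, paths["sample_sheet"], config_snapshot)
    mio.write_mqtl_table(bundle.mqtl, paths["mqtl"], config_snapshot)
    mio.write_intervals(bundle.intervals, paths["tads"], paths["loops"])
    mio.write_expression_matrix(bundle.expression, paths["expression"], config_snapshot)
    mio.write_result_table(bundle.truth.table, paths["ground_truth"], config_snapshot,
                           index_label="probe_id")
    return paths
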