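"""Genomic-context enrichment of probe sets against the array background.

For a probe set (e.g. the VMPs) and an annotation (island relation class,
genomic feature, imprinted flag, housekeeping/tissue-specific gene label),
enrichment is summarised as ``log2(observed/expected)`` -- the set fraction
over the background fraction -- with a two-sided Fisher exact test on the
2x2 contingency (the background column excludes the test set to avoid
double counting) and, where a null of random probe draws is more faithful
(imprinted-region overlap), an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .datatypes import ISLAND_RELATIONS, FEATURES, ProbeManifest


@dataclass
class EnrichmentRecord:
    annotation: str
    n_in_set: int
    n_set: int
    n_in_background: int
    n_background: int
    log2_ratio: float      # NaN when observed or expected fraction is 0
    fisher_p: float
    perm_p: float | None = None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.log2_ratio)


def log2_obs_exp(set_ids, background_ids, annotated_ids,
                 annotation: str = "") -> EnrichmentRecord:
    """log2 of (set fraction / background fraction) for one annotation.

    ``set_ids`` must be a subset of ``background_ids``; ``annotated_ids`` are
    the probes carrying the annotation. An undefined ratio (zero fraction on
    either side) is reported as NaN rather than +/-inf.
    """
    s = set(set_ids)
    bg = set(background_ids)
    if not s or not bg:
        raise ValueError("empty set or background")
    if not s <= bg:
        raise ValueError("set_ids must be a subset of background_ids")
    ann = set(annotated_ids)
    n_in_set = len(s & ann)
    n_in_bg = len(bg & ann)
    obs = n_in_set / len(s)
    exp = n_in_bg / len(bg)
    ratio = np.nan if (obs == 0 or exp == 0) else float(np.log2(obs / exp))
    p = fisher_enrichment(n_in_set, len(s), n_in_bg, len(bg))
    return EnrichmentRecord(annotation=annotation, n_in_set=n_in_set, n_set=len(s),
                            n_in_background=n_in_bg, n_background=len(bg),
                            log2_ratio=ratio, fisher_p=p)


def fisher_enrichment(n_in_set: int, n_set: int, n_in_background: int,
                      n_background: int) -> float:
    """Two-sided Fisher exact p for set vs rest-of-background membership.

    The contrast column is the background *excluding* the set, so the two
    columns of the 2x2 table are disjoint probe collections.
    """
    rest = n_background - n_set
    rest_in = n_in_background - n_in_set
    table = np.array([
        [n_in_set, n_set - n_in_set],
        [rest_in, rest - rest_in],
    ])
    if (table < 0).any():
        raise ValueError(f"negative cell in contingency table: {table.tolist()}")
    return float(fisher_exact(table, alternative="two-sided")[1])


def permutation_enrichment(set_ids, background_ids, annotated_ids,
                           n_reps: int = 1000, rng_seed: int = 0) -> float:
    """Permutation p for the overlap of a set with annotated probes.

    Draws ``n_reps`` random sets of the same size from the background
    (without replacement) and reports the add-one upper-tail p-value
    ``(1 + #{draws with overlap >= observed}) / (n_reps + 1)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    s = set(set_ids)
    bg = np.asarray(sorted(background_ids), dtype=object)
    if len(s) > bg.size:
        raise ValueError("set larger than background")
    ann = set(annotated_ids)
    observed = len(s & ann)
    is_ann = np.fromiter((b in ann for b in bg), dtype=bool, count=bg.size)
    rng = np.random.default_rng(rng_seed)
    m = len(s)
    count = 0
    for _ in range(n_reps):
        idx = rng.choice(bg.size, size=m, replace=False)
        if int(is_ann[idx].sum()) >= observed:
            count += 1
    return (1 + count) / (n_reps + 1)


def enrichment_table(set_ids, manifest: ProbeManifest, set_name: str = "set",
                     background_ids=None, imprinted_perm: bool = False,
                     n_reps: int = 1000, rng_seed: int = 0,
                     gene_labels: pd.Series | None = None) -> pd.DataFrame:
    """Enrichment of one probe set across all standard annotations.

    Background defaults to all probes in the manifest (the analyzable array
    background). Island-relation classes are exclusive; feature annotations
    may overlap (a probe counts once in every feature it carries). With
    ``imprinted_perm``, the imprinted-region overlap also gets a permutation
    p-value. ``gene_labels`` (probe id -> {housekeeping, tissue_specific})
    adds gene-class rows.
    """
    bg = list(background_ids) if background_ids is not None else list(manifest.probe_ids)
    records = []
    tab = manifest.table
    for rel in ISLAND_RELATIONS:
        ann = tab.index[tab["island_relation"] == rel]
        records.append(log2_obs_exp(set_ids, bg, ann, annotation=f"island:{rel}"))
    split = tab["features"].fillna("").str.split(";")
    for feat in FEATURES:
        ann = tab.index[split.map(lambda fs: feat in fs)]
        records.append(log2_obs_exp(set_ids, bg, ann, annotation=f"feature:{feat}"))
    for flag in ("imprinted", "non_cpg", "on_450k"):
        ann = tab.index[tab[flag]]
        rec = log2_obs_exp(set_ids, bg, ann, annotation=f"flag:{flag}")
        if flag == "imprinted" and imprinted_perm:
            rec.perm_p = permutation_enrichment(set_ids, bg, ann, n_reps=n_reps,
                                                rng_seed=rng_seed)
        records.append(rec)
    if gene_labels is not None:
        for lab in ("housekeeping", "tissue_specific"):
            ann = gene_labels.index[gene_labels == lab]
            records.append(log2_obs_exp(set_ids, bg, ann, annotation=f"gene:{lab}"))
    rows = [{
        "set": set_name, "annotation": r.annotation, "n_in_set": r.n_in_set,
        "n_set": r.n_set, "n_in_background": r.n_in_background,
        "n_background": r.n_background, "log2_ratio": r.log2_ratio,
        "fisher_p": r.fisher_p, "perm_p": r.perm_p,
    } for r in records]
    return pd.DataFrame(rows)


def label_housekeeping(expr_by_tissue: pd.DataFrame,
                       top_fraction: float = 0.40) -> pd.Series:
    """Housekeeping vs tissue-specific gene labels from a genes x tissues matrix.

    A gene is *housekeeping* iff its within-tissue percentile rank (average
    ranks for ties) is in the top ``top_fraction`` in **every** tissue;
    all other genes are *tissue_specific*. In a constant tissue column all
    genes tie at the average rank and all pass for that tissue.
    """
    if expr_by_tissue.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    n = expr_by_tissue.shape[0]
    ok = np.ones(n, dtype=bool)
    cutoff = 1.0 - top_fraction
    for col in expr_by_tissue.columns:
        pct = rankdata(expr_by_tissue[col].to_numpy(), method="average") / n
        ok &= pct >= cutoff
    return pd.Series(np.where(ok, "housekeeping", "tissue_specific"),
                     index=expr_by_tissue.index, name="gene_label")
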