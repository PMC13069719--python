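"""Robust identification of variably (VMP) and stably (SMP) methylated probes.

The caller screens for probes whose cross-individual standard deviation is
consistently in the top (VMP) or bottom (SMP) decile of the array: in each
of ``n_repeats`` runs per cohort, a random 10% of samples is removed, the
per-probe SD recomputed, and the top/bottom ``floor(q*P)`` probes selected;
only probes selected in *every* run of *both* cohorts are called. The
repeated downsampling protects the catalogue against outlier individuals.

Conventions the procedure fixes deliberately: ``floor()`` for both the drop
count and the decile size; ties at the decile boundary broken by
lexicographic probe id; downsampling draws keyed to *sorted sample ids*
(so that column order never affects results); per-repeat seeds equal to
``rng_seed + repeat_index``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import BetaMatrix


def probe_sd(betas: BetaMatrix) -> pd.Series:
    """Sample standard deviation (ddof=1) per probe over non-missing values.

    Raises
    ------
    ValueError
        If any probe has fewer than 2 non-missing samples.
    """
    arr = betas.values.to_numpy(dtype=float)
    n_ok = np.sum(~np.isnan(arr), axis=1)
    if (n_ok < 2).any():
        probe = betas.probe_ids[np.argmax(n_ok < 2)]
        raise ValueError(
            f"probe {probe!r} has fewer than 2 non-missing samples ({n_ok.min()})"
        )
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(arr, axis=1, ddof=1)
    return pd.Series(sd, index=betas.probe_ids, name="sd")


def _select_extremes(sd: pd.Series, q: float) -> tuple[set, set]:
    """Top/bottom floor(q*P) probes by SD; boundary ties resolved by probe id
    (the lexicographically smaller id enters the set)."""
    P = len(sd)
    m = int(np.floor(q * P))
    if m == 0:
        raise ValueError(f"too few probes: floor(q*P) = 0 with q={q}, P={P}")
    df = pd.DataFrame({"sd": sd})
    df["pid"] = df.index
    top = df.sort_values(["sd", "pid"], ascending=[False, True]).head(m)
    vmp = set(top.index)
    # stable probes drawn from the non-variable remainder so the two sets are
    # disjoint by construction even in degenerate tie cases near q = 0.5
    rest = df.drop(index=list(vmp))
    bottom = rest.sort_values(["sd", "pid"], ascending=[True, True]).head(m)
    return vmp, set(bottom.index)


def call_single_run(betas: BetaMatrix, drop_fraction: float, q: float,
                    rng_seed: int) -> dict[str, set]:
    """One downsampled VMP/SMP selection.

    Removes ``floor(drop_fraction * n_samples)`` samples uniformly without
    replacement (drawn over sorted sample ids), computes per-probe SD on the
    remainder and selects the extreme deciles.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError(f"drop_fraction must be in [0, 1), got {drop_fraction}")
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    sorted_ids = sorted(betas.sample_ids)
    n_drop = int(np.floor(drop_fraction * len(sorted_ids)))
    if n_drop:
        rng = np.random.default_rng(rng_seed)
        dropped = set(
            np.asarray(sorted_ids, dtype=object)[
                rng.choice(len(sorted_ids), size=n_drop, replace=False)
            ]
        )
        keep = [s for s in sorted_ids if s not in dropped]
    else:
        keep = sorted_ids
    sd = probe_sd(betas.subset_samples(keep))
    vmp, smp = _select_extremes(sd, q)
    return {"vmp_set": vmp, "smp_set": smp}


@dataclass
class VariabilityCatalog:
    """Per-probe SDs, per-run selection counts and final calls.

    ``table`` columns: sd_discovery, sd_validation, runs_as_vmp_discovery,
    runs_as_vmp_validation, runs_as_smp_discovery, runs_as_smp_validation,
    call_discovery, call_validation, call (combined).
    """

    table: pd.DataFrame
    n_repeats: int

    @property
    def vmps(self) -> set:
        return set(self.table.index[self.table["call"] == "VMP"])

    @property
    def smps(self) -> set:
        return set(self.table.index[self.table["call"] == "SMP"])

    def cohort_set(self, cohort: str, which: str) -> set:
        col = f"call_{cohort}"
        return set(self.table.index[self.table[col] == which])


def call_catalog(discovery: BetaMatrix, validation: BetaMatrix,
                 config: PipelineConfig) -> VariabilityCatalog:
    """Full two-cohort, repeated-downsampling VMP/SMP catalogue."""
    d_probes = set(discovery.probe_ids)
    v_probes = set(validation.probe_ids)
    if d_probes != v_probes:
        diff = len(d_probes ^ v_probes)
        raise ValueError(
            f"discovery and validation probe sets differ ({diff} probes in the "
            "symmetric difference)"
        )
    probes = discovery.probe_ids
    table = pd.DataFrame(index=probes.copy())
    table.index.name = "probe_id"

    cohort_sets = {}
    for cohort, betas in (("discovery", discovery), ("validation", validation)):
        vmp_counts = pd.Series(0, index=probes)
        smp_counts = pd.Series(0, index=probes)
        vmp_inter: set | None = None
        smp_inter: set | None = None
        for rep in range(config.n_repeats):
            run = call_single_run(betas, config.drop_fraction,
                                  config.decile_fraction,
                                  config.rng_seed + rep)
            vmp_counts[list(run["vmp_set"])] += 1
            smp_counts[list(run["smp_set"])] += 1
            vmp_inter = run["vmp_set"] if vmp_inter is None else vmp_inter & run["vmp_set"]
            smp_inter = run["smp_set"] if smp_inter is None else smp_inter & run["smp_set"]
        cohort_sets[cohort] = (vmp_inter or set(), smp_inter or set())
        table[f"sd_{cohort}"] = probe_sd(betas)
        table[f"runs_as_vmp_{cohort}"] = vmp_counts
        table[f"runs_as_smp_{cohort}"] = smp_counts
        call = pd.Series("neither", index=probes)
        call[list(vmp_inter or set())] = "VMP"
        call[list(smp_inter or set())] = "SMP"
        table[f"call_{cohort}"] = call

    vmp_final = cohort_sets["discovery"][0] & cohort_sets["validation"][0]
    smp_final = cohort_sets["discovery"][1] & cohort_sets["validation"][1]
    call = pd.Series("neither", index=probes)
    call[list(vmp_final)] = "VMP"
    call[list(smp_final)] = "SMP"
    table["call"] = call
    return VariabilityCatalog(table=table, n_repeats=config.n_repeats)


def overlap_report(catalog_or_ids, cpg_lists: dict[str, list[str]]) -> dict:
    """Overlap of a probe set with labelled CpG lists.

    Returns ``{"exclusive": DataFrame, "pairwise": DataFrame, "unknown_ids": int}``:
    upset-style counts of set members per exclusive combination of list
    memberships, and pairwise list intersection counts (within the set).
    Ids in the lists that are not part of the reporting universe are counted
    as non-members.
    """
    if isinstance(catalog_or_ids, VariabilityCatalog):
        base = catalog_or_ids.vmps
    else:
        base = set(catalog_or_ids)
    labels = list(cpg_lists)
    sets = {lab: set(cpg_lists[lab]) for lab in labels}
    unknown = sum(len(s - base) for s in sets.values())

    combo_counts = {}
    for probe in base:
        combo = tuple(lab for lab in labels if probe in sets[lab])
        combo_counts[combo] = combo_counts.get(combo, 0) + 1
    rows = []
    for r in range(len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            rows.append({"combination": "+".join(combo) if combo else "(none)",
                         "n": combo_counts.get(combo, 0)})
    exclusive = pd.DataFrame(rows)

    pair_rows = []
    for a, b in itertools.combinations(labels, 2):
        pair_rows.append({"list_a": a, "list_b": b,
                          "n": len(sets[a] & sets[b] & base)})
    for lab in labels:
        pair_rows.append({"list_a": lab, "list_b": lab, "n": len(sets[lab] & base)})
    pairwise = pd.DataFrame(pair_rows)
    return {"exclusive": exclusive, "pairwise": pairwise, "unknown_ids": unknown}
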