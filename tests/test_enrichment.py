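"""Enrichment statistics: exact Fisher oracle, permutation calibration,
log2 obs/exp conventions, housekeeping labelling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from methvar import (
    fisher_enrichment,
    label_housekeeping,
    log2_obs_exp,
    permutation_enrichment,
)
from methvar.enrichment import enrichment_table


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration (exact integers)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(p for x in range(lo, hi + 1)
               if (p := pmf(x)) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_balanced_table_is_one(self):
        assert fisher_enrichment(1, 2, 2, 4) == pytest.approx(1.0)

    def test_perfect_separation_matches_enumeration(self):
        # table [[5,0],[0,5]]: p = 2/252
        p = fisher_enrichment(5, 5, 5, 10)
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert p == pytest.approx(fisher_two_sided_oracle(5, 0, 0, 5), abs=1e-12)

    def test_random_small_tables_match_enumeration(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            p = fisher_enrichment(a, a + b, a + c, a + b + c + d)
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                      abs=1e-12, rel=1e-9)

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            from scipy.stats import fisher_exact
            p1 = fisher_exact([[a, b], [c, d]])[1]
            p2 = fisher_exact([[a, c], [b, d]])[1]
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_negative_derived_cell_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fisher_enrichment(5, 4, 5, 20)


class TestLog2ObsExp:
    def test_equal_fractions_give_zero(self):
        bg = [f"p{i}" for i in range(100)]
        ann = bg[:10]                      # 10% of background
        s = bg[:2] + bg[50:68]             # 2/20 = 10% of set
        rec = log2_obs_exp(s, bg, ann)
        assert rec.log2_ratio == pytest.approx(0.0, abs=1e-12)

    def test_doubled_fraction_gives_one(self):
        bg = [f"p{i}" for i in range(100)]
        ann = bg[:10]
        s = bg[:4] + bg[50:66]             # 4/20 = 20% vs 10%
        rec = log2_obs_exp(s, bg, ann)
        assert rec.log2_ratio == pytest.approx(1.0, abs=1e-12)

    def test_zero_observed_marked_undefined(self):
        bg = [f"p{i}" for i in range(50)]
        rec = log2_obs_exp(bg[40:], bg, bg[:5])
        assert np.isnan(rec.log2_ratio) and not rec.defined

    def test_set_must_be_subset_of_background(self):
        with pytest.raises(ValueError, match="subset"):
            log2_obs_exp(["x"], ["a", "b"], ["a"])


class TestPermutation:
    def test_zero_observed_overlap_gives_p_one(self):
        bg = [f"p{i}" for i in range(40)]
        p = permutation_enrichment(bg[:5], bg, annotated_ids=[], n_reps=99, rng_seed=0)
        assert p == 1.0

    def test_set_equal_to_rare_annotation_gives_minimal_p(self):
        bg = [f"p{i}" for i in range(200)]
        ann = bg[:5]
        p = permutation_enrichment(ann, bg, ann, n_reps=199, rng_seed=1)
        assert p == pytest.approx(1 / 200)

    def test_p_bounds(self, rng):
        bg = [f"p{i}" for i in range(60)]
        ann = bg[:20]
        for seed in range(5):
            s = rng.choice(bg, size=10, replace=False)
            p = permutation_enrichment(s, bg, ann, n_reps=49, rng_seed=seed)
            assert 1 / 50 <= p <= 1.0

    def test_null_pvalues_approximately_uniform(self):
        """Random 'observed' sets from the background give near-uniform
        p-values (up to the mild discreteness of the overlap statistic)."""
        rng = np.random.default_rng(7)
        bg = [f"p{i}" for i in range(1500)]
        ann = set(np.random.default_rng(1).choice(bg, size=375, replace=False))
        ps = []
        for rep in range(150):
            s = rng.choice(bg, size=200, replace=False)
            ps.append(permutation_enrichment(s, bg, ann, n_reps=99, rng_seed=rep))
        assert kstest(ps, "uniform").pvalue > 0.01


class TestHousekeeping:
    def test_top_gene_everywhere_is_housekeeping(self, rng):
        vals = rng.random((50, 4))
        vals[0] = 10.0                      # top in every tissue
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(50)],
                          columns=list("ABCD"))
        labels = label_housekeeping(df)
        assert labels["g0"] == "housekeeping"

    def test_single_weak_tissue_disqualifies(self, rng):
        vals = np.tile(np.linspace(1, 50, 50)[:, None], (1, 3)).astype(float)
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(50)],
                          columns=list("ABC"))
        df.loc["g49", "C"] = 0.0            # top everywhere except bottom in C
        labels = label_housekeeping(df)
        assert labels["g49"] == "tissue_specific"

    def test_matches_bruteforce_percentile_check(self, rng):
        vals = rng.random((10, 3))
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                          columns=list("XYZ"))
        labels = label_housekeeping(df)
        for g in df.index:
            ok = True
            for t in df.columns:
                rank = (np.sum(df[t] < df.at[g, t])
                        + (np.sum(df[t] == df.at[g, t]) + 1) / 2)
                ok &= rank / 10 >= 0.6
            assert (labels[g] == "housekeeping") == ok

    def test_constant_tissue_column_passes_everyone(self):
        df = pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0, 5.0],
                           "B": [7.0] * 5},
                          index=[f"g{i}" for i in range(5)])
        labels = label_housekeeping(df)
        # B ties everyone at average rank (60th pct), so A alone decides:
        # A percentile ranks are .2 .4 .6 .8 1.0, three reach the top 40%
        assert (labels == "housekeeping").sum() == 3

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            label_housekeeping(pd.DataFrame({"A": [1.0, 2.0]}))


def test_partitioning_annotation_counts_are_conserved(small_bundle):
    """Island-relation categories partition the manifest, so their per-category
    counts must sum to the set and background sizes."""
    manifest = small_bundle.manifest
    ids = list(manifest.probe_ids[:60])
    tab = enrichment_table(ids, manifest, set_name="test")
    isl = tab[tab["annotation"].str.startswith("island:")]
    assert isl["n_in_set"].sum() == 60
    assert isl["n_in_background"].sum() == len(manifest.probe_ids)


def test_planted_variable_probes_enrich_at_shores_and_enhancers(small_bundle):
    truth = small_bundle.truth
    var_ids = list(truth.probes_of_class("variable_unimodal")) + \
        list(truth.probes_of_class("epiallele_bimodal"))
    tab = enrichment_table(var_ids, small_bundle.manifest, set_name="variable")
    tab = tab.dropna(subset=["log2_ratio"]).set_index("annotation")
    isl = tab.loc[[a for a in tab.index if a.startswith("island:")], "log2_ratio"]
    assert isl.idxmax() == "island:shore"
    feats = tab.loc[[a for a in tab.index if a.startswith("feature:")], "log2_ratio"]
    assert feats.loc["feature:enhancer"] > 0
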