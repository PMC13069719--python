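"""The downsampling VMP/SMP caller and overlap reporting."""

import numpy as np
import pandas as pd
import pytest

from methvar import (
    BetaMatrix,
    PipelineConfig,
    call_catalog,
    call_single_run,
    overlap_report,
    probe_sd,
)
from conftest import make_beta


class TestProbeSd:
    def test_constant_probe_has_zero_sd(self):
        sd = probe_sd(make_beta([[0.5, 0.5, 0.5]]))
        assert sd.iloc[0] == 0.0

    def test_two_point_closed_form(self):
        sd = probe_sd(make_beta([[0.0, 1.0]]))
        assert sd.iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-6)

    def test_matches_two_pass_oracle(self, rng):
        arr = rng.random((100, 50))
        sd = probe_sd(make_beta(arr))
        # independent two-pass oracle
        for i in (0, 17, 99):
            m = sum(arr[i]) / 50
            var = sum((x - m) ** 2 for x in arr[i]) / 49
            assert sd.iloc[i] == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_skips_missing_and_requires_two_values(self):
        vals = np.array([[0.2, np.nan, 0.4], [0.5, np.nan, np.nan]])
        bm = BetaMatrix(pd.DataFrame(vals, index=["a", "b"], columns=list("xyz")))
        with pytest.raises(ValueError, match="'b'"):
            probe_sd(bm)


class TestSingleRun:
    def test_highest_sd_probes_selected_by_full_sort_oracle(self, rng):
        arr = 0.3 + 0.1 * rng.random((100, 40))
        bm = make_beta(arr)
        run = call_single_run(bm, drop_fraction=0.0, q=0.10, rng_seed=0)
        sd = probe_sd(bm).sort_values(ascending=False)
        assert run["vmp_set"] == set(sd.index[:10])
        assert run["smp_set"] == set(sd.index[-10:])
        assert len(run["vmp_set"]) == len(run["smp_set"]) == 10

    def test_boundary_ties_resolved_lexicographically(self):
        # 4 probes; q=0.5 -> 2 slots; probes b and c tie at the boundary SD
        vals = {
            "a": [0.1, 0.9],     # sd ~ .566 highest
            "c": [0.3, 0.7],     # tie
            "b": [0.3, 0.7],     # tie (same sd as c)
            "d": [0.5, 0.5],     # sd 0
        }
        bm = make_beta(list(vals.values()), probe_ids=list(vals))
        run = call_single_run(bm, 0.0, 0.5, rng_seed=0)
        assert run["vmp_set"] == {"a", "b"}          # b < c lexicographically
        assert run["smp_set"] == {"d", "c"}          # disjoint from the VMP side

    def test_too_few_probes_error(self):
        bm = make_beta([[0.2, 0.4], [0.3, 0.5]])
        with pytest.raises(ValueError, match="too few probes"):
            call_single_run(bm, 0.0, 0.1, rng_seed=0)

    def test_drop_count_is_floor_of_fraction(self, rng):
        bm = make_beta(rng.random((30, 25)))
        # identical seed must give identical result; 10% of 25 -> 2 dropped
        r1 = call_single_run(bm, 0.10, 0.2, rng_seed=3)
        r2 = call_single_run(bm, 0.10, 0.2, rng_seed=3)
        assert r1 == r2


class TestCatalog:
    def test_reduces_to_single_run_without_downsampling(self, rng):
        arr = 0.2 + 0.6 * rng.random((60, 30))
        d = make_beta(arr)
        v = make_beta(0.2 + 0.6 * rng.random((60, 30)))
        cfg = PipelineConfig(drop_fraction=0.0, n_repeats=1, rng_seed=1)
        cat = call_catalog(d, v, cfg)
        run_d = call_single_run(d, 0.0, cfg.decile_fraction, cfg.rng_seed)
        run_v = call_single_run(v, 0.0, cfg.decile_fraction, cfg.rng_seed)
        assert cat.vmps == run_d["vmp_set"] & run_v["vmp_set"]
        assert cat.smps == run_d["smp_set"] & run_v["smp_set"]

    def test_final_sets_subset_of_every_repeat_and_disjoint(self, small_bundle,
                                                            fast_config):
        cat = call_catalog(small_bundle.betas_discovery,
                           small_bundle.betas_validation, fast_config)
        assert not (cat.vmps & cat.smps)
        for cohort, betas in (("discovery", small_bundle.betas_discovery),
                              ("validation", small_bundle.betas_validation)):
            for rep in range(fast_config.n_repeats):
                run = call_single_run(betas, fast_config.drop_fraction,
                                      fast_config.decile_fraction,
                                      fast_config.rng_seed + rep)
                assert cat.cohort_set(cohort, "VMP") <= run["vmp_set"]
                assert cat.cohort_set(cohort, "SMP") <= run["smp_set"]

    def test_sample_order_invariance(self, rng):
        arr = rng.random((50, 24)) * 0.8 + 0.1
        d = make_beta(arr)
        shuffled = d.values.iloc[:, rng.permutation(24)]
        d2 = BetaMatrix(shuffled)
        cfg = PipelineConfig(n_repeats=3, rng_seed=9)
        c1 = call_catalog(d, d, cfg)
        c2 = call_catalog(d2, d2, cfg)
        assert c1.vmps == c2.vmps and c1.smps == c2.smps

    def test_probe_mismatch_reports_symmetric_difference(self, rng):
        d = make_beta(rng.random((20, 10)))
        v = make_beta(rng.random((22, 10)))
        with pytest.raises(ValueError, match="2 probes"):
            call_catalog(d, v, PipelineConfig())

    def test_half_split_partitions_probes(self, rng):
        """q=0.5 assigns every probe to VMP or SMP in each run; after
        repeats/intersection the sets stay disjoint."""
        arr = 0.2 + 0.6 * rng.random((40, 30))
        d = make_beta(arr)
        cfg = PipelineConfig(decile_fraction=0.5, n_repeats=3, rng_seed=4)
        run = call_single_run(d, 0.0, 0.5, 0)
        assert len(run["vmp_set"] | run["smp_set"]) == 40
        cat = call_catalog(d, d, cfg)
        assert not (cat.vmps & cat.smps)


class TestOverlapReport:
    def test_disjoint_lists_counts_sum_to_set_size(self):
        vmps = [f"p{i}" for i in range(20)]
        lists = {"a": vmps[:7], "b": vmps[7:12]}
        rep = overlap_report(vmps, lists)
        assert rep["exclusive"]["n"].sum() == 20

    def test_single_list_equal_to_set(self):
        vmps = ["x", "y", "z"]
        rep = overlap_report(vmps, {"all": vmps})
        tab = rep["exclusive"].set_index("combination")["n"]
        assert tab["all"] == 3 and tab["(none)"] == 0

    def test_counts_match_bruteforce_enumeration(self, rng):
        vmps = [f"p{i}" for i in range(50)]
        lists = {k: list(rng.choice(vmps, size=rng.integers(5, 30), replace=False))
                 for k in "abc"}
        rep = overlap_report(vmps, lists)
        # brute force membership enumeration
        for _, row in rep["exclusive"].iterrows():
            combo = set(row["combination"].split("+")) if row["combination"] != "(none)" else set()
            n = sum(
                1 for p in vmps
                if {k for k in lists if p in lists[k]} == combo
            )
            assert row["n"] == n

    def test_unknown_ids_counted_not_fatal(self):
        rep = overlap_report(["a", "b"], {"l": ["a", "zzz"]})
        assert rep["unknown_ids"] == 1
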