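"""cis/trans classification and TAD/loop co-occupancy."""

import numpy as np
import pandas as pd
import pytest

from methvar import (
    GenomeIntervals,
    MqtlTable,
    PipelineConfig,
    SimulationDesign,
    ValidationError,
    classify_pair,
    classify_pairs,
    co_occupancy_enrichment,
    loop_connected,
    same_tad,
    simulate_bundle,
    summarize_cpg,
)
from methvar.mqtl import annotate_pairs_3d
from tests_stat_helpers import binom_ci


@pytest.mark.parametrize("snp_chrom,snp_pos,cpg_chrom,cpg_pos,expect_class,expect_dist", [
    ("chr1", 1000, "chr1", 1500, "cis", 500),     # distance exactly at the window
    ("chr1", 1000, "chr1", 1501, "trans", 501),   # one bp beyond
    ("chr1", 1000, "chr2", 1000, "trans", None),  # interchromosomal
    ("chr3", 500, "chr3", 500, "cis", 0),
])
def test_cis_trans_boundaries(snp_chrom, snp_pos, cpg_chrom, cpg_pos,
                              expect_class, expect_dist):
    cls, dist = classify_pair(snp_chrom, snp_pos, cpg_chrom, cpg_pos, window_bp=500)
    assert cls == expect_class
    if expect_dist is None:
        assert np.isnan(dist)
    else:
        assert dist == expect_dist


def test_missing_position_rejected():
    with pytest.raises(ValueError, match="missing"):
        classify_pair("chr1", float("nan"), "chr1", 100)


def test_window_monotonicity(rng):
    """Enlarging the window never moves a pair from cis to trans."""
    for _ in range(100):
        d = int(rng.integers(0, 2000))
        small = classify_pair("chr1", 10_000, "chr1", 10_000 + d, window_bp=400)[0]
        large = classify_pair("chr1", 10_000, "chr1", 10_000 + d, window_bp=900)[0]
        assert not (small == "cis" and large == "trans")


class TestCpgSummary:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["cpg_id", "pair_class"])

    def test_mixed_partners_are_cis_and_trans(self):
        out = summarize_cpg(self._pairs([("c1", "cis"), ("c1", "trans")]))
        assert out.loc["c1", "cpg_class"] == "cis_and_trans"

    def test_pure_trans_counts(self):
        out = summarize_cpg(self._pairs([("c1", "trans")] * 3))
        assert out.loc["c1", "cpg_class"] == "trans"
        assert out.loc["c1", "n_trans_partners"] == 3

    def test_no_pairs_yields_empty_summary(self):
        out = summarize_cpg(self._pairs([]))
        assert len(out) == 0


@pytest.fixture()
def toy_intervals():
    tads = pd.DataFrame([("chr1", 100, 200), ("chr1", 300, 400)],
                        columns=["chrom", "start", "end"])
    loops = pd.DataFrame([("chr1", 100, 150, 1000, 1050)],
                         columns=["chrom", "startA", "endA", "startB", "endB"])
    return GenomeIntervals(tads=tads, loops=loops)


class TestSameTad:
    def test_both_inside_one_tad(self, toy_intervals):
        assert same_tad("chr1", 150, "chr1", 180, toy_intervals)

    def test_half_open_end_is_outside(self, toy_intervals):
        # 1-based 201 -> 0-based 200, the excluded TAD end
        assert not same_tad("chr1", 150, "chr1", 201, toy_intervals)
        # 1-based 101 -> 0-based 100, the included TAD start
        assert same_tad("chr1", 101, "chr1", 150, toy_intervals)

    def test_two_different_tads(self, toy_intervals):
        assert not same_tad("chr1", 150, "chr1", 350, toy_intervals)

    def test_interchromosomal_always_false(self, toy_intervals):
        assert not same_tad("chr1", 150, "chr2", 150, toy_intervals)

    def test_overlapping_tads_rejected(self):
        tads = pd.DataFrame([("chr1", 100, 300), ("chr1", 200, 400)],
                            columns=["chrom", "start", "end"])
        iv = GenomeIntervals(tads=tads)
        with pytest.raises(ValidationError, match="overlapping"):
            same_tad("chr1", 150, "chr1", 250, iv)


class TestLoopConnected:
    def test_opposite_anchors_connect(self, toy_intervals):
        assert loop_connected("chr1", 120, "chr1", 1020, toy_intervals)
        assert loop_connected("chr1", 1020, "chr1", 120, toy_intervals)

    def test_same_single_anchor_does_not_connect(self, toy_intervals):
        assert not loop_connected("chr1", 110, "chr1", 140, toy_intervals)

    def test_outside_all_anchors(self, toy_intervals):
        assert not loop_connected("chr1", 500, "chr1", 600, toy_intervals)


def test_pair_classification_table_and_partition(small_bundle, fast_config):
    pairs = classify_pairs(small_bundle.mqtl, small_bundle.manifest,
                           fast_config.cis_window_bp)
    assert len(pairs) == len(small_bundle.mqtl.table)
    assert set(pairs["pair_class"]) <= {"cis", "trans"}
    n_cis = (pairs["pair_class"] == "cis").sum()
    n_trans = (pairs["pair_class"] == "trans").sum()
    assert n_cis + n_trans == len(pairs)
    ann = annotate_pairs_3d(pairs, small_bundle.intervals)
    inter = ann[ann["snp_chrom"] != ann["cpg_chrom"]]
    assert not inter["same_tad"].any()


def test_planted_same_tad_share_recovered_within_binomial_ci():
    design = SimulationDesign(
        n_probes=600, n_samples_discovery=30, n_samples_validation=30,
        class_mix={"stable_low": 0.0, "stable_high": 0.0,
                   "variable_unimodal": 0.5, "epiallele_bimodal": 0.0,
                   "cell_driven": 0.0, "mqtl_driven": 0.5},
        cis_fraction=0.0, loop_share=0.0, second_snp_fraction=0.0,
        same_tad_share=0.9, rng_seed=21)
    b = simulate_bundle(design)
    pairs = classify_pairs(b.mqtl, b.manifest, 500)
    pairs = annotate_pairs_3d(pairs, b.intervals)
    trans = pairs[pairs["pair_class"] == "trans"]
    assert len(trans) >= 200
    share = trans["same_tad"].mean()
    lo, hi = binom_ci(int(trans["same_tad"].sum()), len(trans))
    assert lo <= 0.9 <= hi, f"planted share 0.9 outside CI [{lo:.3f}, {hi:.3f}] (obs {share:.3f})"


def test_co_occupancy_equal_fractions_null(rng):
    base = pd.DataFrame({
        "same_tad": [True] * 50 + [False] * 50,
        "loop_connected": [True] * 5 + [False] * 95,
    })
    out = co_occupancy_enrichment(base, base)
    assert (out["log2_ratio"].abs() < 1e-12).all()
    assert (out["fisher_p"] > 0.99).all()


def test_co_occupancy_fisher_matches_enumeration_oracle():
    from test_enrichment import fisher_two_sided_oracle
    s = pd.DataFrame({"same_tad": [True] * 8 + [False] * 2,
                      "loop_connected": [False] * 10})
    bg = pd.DataFrame({"same_tad": [True] * 5 + [False] * 10,
                       "loop_connected": [False] * 15})
    out = co_occupancy_enrichment(s, bg).set_index("kind")
    assert out.loc["same_tad", "fisher_p"] == pytest.approx(
        fisher_two_sided_oracle(8, 2, 5, 10), abs=1e-12)
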