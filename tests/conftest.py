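import numpy as np
import pandas as pd
import pytest

from methvar import (
    BetaMatrix,
    PipelineConfig,
    SampleSheet,
    SimulationDesign,
    simulate_bundle,
)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact default-mix bundle shared by read-only tests."""
    design = SimulationDesign(n_probes=400, n_samples_discovery=80,
                              n_samples_validation=80, rng_seed=11)
    return simulate_bundle(design)


@pytest.fixture(scope="session")
def fast_config():
    return PipelineConfig(rng_seed=11, n_repeats=4, dip_mc_reps=200,
                          permutation_reps=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_beta(values, probe_ids=None, sample_ids=None) -> BetaMatrix:
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:03d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{i:03d}" for i in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probe_ids, columns=sample_ids))


def make_sheet(props: dict, cohort="discovery") -> SampleSheet:
    """Sample sheet from {sample_id: [CD8T, CD4T, NK, B, Mono, Gran]}."""
    df = pd.DataFrame.from_dict(props, orient="index",
                                columns=["CD8T", "CD4T", "NK", "B", "Mono", "Gran"])
    df.index.name = "sample_id"
    df.insert(0, "cohort", cohort)
    return SampleSheet(df)
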