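"""Pipeline configuration: the tuning constants of every analysis stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable constants of the variability pipeline.

    Attributes
    ----------
    drop_fraction : float
        Fraction of samples removed in each downsampling repeat (default 0.10).
    n_repeats : int
        Number of downsampling repeats per cohort (default 10).
    decile_fraction : float
        Fraction of probes called variable (highest SD) and stable (lowest
        SD) in each run (default 0.10, the top/bottom decile).
    cis_window_bp : int
        SNP-CpG distance (bp) at or below which an mQTL pair is *cis*; this
        is a deliberately small, nucleosome-scale window (default 500).
    epiallele_mean_window : tuple of float
        Inclusive pooled-mean-beta window for epiallele candidates
        (default (0.40, 0.60)).
    dip_alpha : float
        Significance level of the dip test of unimodality (default 0.05).
    dip_mc_reps : int
        Monte-Carlo replicates for the dip null distribution (default 2000).
    permutation_reps : int
        Draws for permutation enrichment tests (default 1000).
    max_missing_frac : float
        Probes with a larger fraction of missing betas are dropped (0.05).
    rng_seed : int
        Seed for every randomised stage.
    """

    drop_fraction: float = 0.10
    n_repeats: int = 10
    decile_fraction: float = 0.10
    cis_window_bp: int = 500
    epiallele_mean_window: tuple[float, float] = (0.40, 0.60)
    dip_alpha: float = 0.05
    dip_mc_reps: int = 2000
    permutation_reps: int = 1000
    max_missing_frac: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 <= self.drop_fraction < 1:
            raise ValueError(f"drop_fraction must be in [0, 1), got {self.drop_fraction}")
        if not 0 < self.decile_fraction < 1:
            raise ValueError(f"decile_fraction must be in (0, 1), got {self.decile_fraction}")
        if not 0 < self.dip_alpha < 1:
            raise ValueError(f"dip_alpha must be in (0, 1), got {self.dip_alpha}")
        if not 0 <= self.max_missing_frac < 1:
            raise ValueError(f"max_missing_frac must be in [0, 1), got {self.max_missing_frac}")
        for name in ("n_repeats", "dip_mc_reps", "permutation_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.cis_window_bp < 0:
            raise ValueError("cis_window_bp must be >= 0")
        lo, hi = self.epiallele_mean_window
        if not 0 <= lo <= hi <= 1:
            raise ValueError("epiallele_mean_window must satisfy 0 <= lo <= hi <= 1")
        self.epiallele_mean_window = (float(lo), float(hi))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epiallele_mean_window"] = list(self.epiallele_mean_window)
        return d

    def snapshot(self) -> str:
        """One-line JSON snapshot embedded in output tables."""
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "epiallele_mean_window" in d:
            d["epiallele_mean_window"] = tuple(d["epiallele_mean_window"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
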