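"""Cell-composition correction of beta values.

Blood is a mixture of cell types with distinctive methylation profiles, so
part of the apparent inter-individual variability at a probe can reflect
composition differences rather than within-cell-type epigenetic state. Each
probe is regressed (OLS) on five of the six estimated cell-type proportions
-- the six sum to ~1, so one (NK, the smallest fraction) is excluded as the
non-independent remainder -- and the corrected value is the intercept plus
the residual, which keeps corrected betas on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CELL_TYPES, BetaMatrix, SampleSheet


@dataclass
class CellModelFit:
    """Per-probe OLS fit of beta on intercept + five cell proportions."""

    intercept: pd.Series               # per probe
    coefficients: pd.DataFrame         # probes x included cell types
    residuals: pd.DataFrame            # probes x samples
    fitted: pd.DataFrame               # probes x samples
    included_cells: tuple[str, ...]

    def out_of_range_rate(self) -> float:
        """Fraction of corrected values outside [0, 1] (reported, not clipped)."""
        corr = self.intercept.to_numpy()[:, None] + self.residuals.to_numpy()
        return float(np.mean((corr < 0) | (corr > 1)))


def fit_cell_model(betas: BetaMatrix, sheet: SampleSheet,
                   exclude_cell: str = "NK") -> CellModelFit:
    """OLS of each probe's betas on intercept + five cell-type proportions.

    Parameters
    ----------
    exclude_cell : str
        The proportion left out as the dependent remainder (default NK).
    """
    if exclude_cell not in CELL_TYPES:
        raise ValueError(f"unknown cell type {exclude_cell!r}")
    included = tuple(c for c in CELL_TYPES if c != exclude_cell)
    samples = list(betas.sample_ids)
    missing = [s for s in samples if s not in sheet.sample_ids]
    if missing:
        raise ValueError(f"samples missing from sample sheet: {missing[:5]}")
    if len(samples) <= 6:
        raise ValueError("need more than 6 samples to fit the cell model")

    X = np.column_stack(
        [np.ones(len(samples))]
        + [sheet.table.loc[samples, c].to_numpy(dtype=float) for c in included]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column whose removal restores full rank
        for ci, cell in enumerate(("intercept",) + included):
            sub = np.delete(X, ci, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"collinear design: column {cell!r} is redundant")
        raise ValueError("collinear design matrix")

    B = betas.values.loc[:, samples].to_numpy(dtype=float)  # probes x samples
    coef, *_ = np.linalg.lstsq(X, B.T, rcond=None)          # 6 x probes
    fitted = (X @ coef).T                                   # probes x samples
    resid = B - fitted

    probes = betas.probe_ids
    return CellModelFit(
        intercept=pd.Series(coef[0], index=probes, name="intercept"),
        coefficients=pd.DataFrame(coef[1:].T, index=probes, columns=list(included)),
        residuals=pd.DataFrame(resid, index=probes, columns=samples),
        fitted=pd.DataFrame(fitted, index=probes, columns=samples),
        included_cells=included,
    )


def corrected_betas(fit: CellModelFit) -> BetaMatrix:
    """Cell-composition corrected matrix: intercept + residual per probe/sample.

    Values are deliberately *not* clipped to [0, 1]; the out-of-range rate is
    available from :meth:`CellModelFit.out_of_range_rate`, and downstream
    stages accept the slightly out-of-range corrected values.
    """
    corr = fit.residuals.add(fit.intercept, axis=0)
    return BetaMatrix(corr, validate_range=False)


def cell_sensitivity_report(catalog_raw, catalog_adjusted) -> dict:
    """Calls lost/gained by cell-composition correction.

    Returns sets of probes called VMP/SMP in the raw catalogue but not in the
    adjusted one (and vice versa), with fractions relative to the raw sets.
    """
    if set(catalog_raw.table.index) != set(catalog_adjusted.table.index):
        raise ValueError("catalogues cover different probe universes")
    out = {}
    for which in ("vmps", "smps"):
        raw = getattr(catalog_raw, which)
        adj = getattr(catalog_adjusted, which)
        lost = raw - adj
        gained = adj - raw
        out[which] = {
            "lost": lost,
            "gained": gained,
            "lost_fraction": len(lost) / len(raw) if raw else 0.0,
            "gained_fraction": len(gained) / len(raw) if raw else float("nan"),
            "n_raw": len(raw),
            "n_adjusted": len(adj),
        }
    return out


def sensitivity_table(report: dict) -> pd.DataFrame:
    rows = []
    for which, r in report.items():
        rows.append({
            "set": which.upper().rstrip("S") + "s",
            "n_raw": r["n_raw"],
            "n_adjusted": r["n_adjusted"],
            "n_lost": len(r["lost"]),
            "n_gained": len(r["gained"]),
            "lost_fraction": r["lost_fraction"],
        })
    return pd.DataFrame(rows)
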