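"""Reference-based leukocyte deconvolution from methylation.

Whole-blood methylation is a mixture of cell-type-specific profiles, so a
sample's beta values at discriminating probes are modelled as a
nonnegative combination of reference columns. Fractions are obtained by
nonnegative least squares per sample followed by renormalization onto the
simplex, and enter downstream models as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .preprocess import MethylationMatrix

__all__ = ["ReferencePanel", "estimate_cell_fractions"]


@dataclass
class ReferencePanel:
    """Probes x cell-types reference beta values at discriminating probes."""

    table: pd.DataFrame  # index: probe IDs, columns: cell-type names

    def __post_init__(self) -> None:
        if self.table.shape[1] < 2:
            raise ValueError("reference panel needs >= 2 cell types")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate probe IDs in reference panel")
        vals = self.table.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    @property
    def cell_types(self) -> pd.Index:
        return self.table.columns


def estimate_cell_fractions(
    matrix: MethylationMatrix | pd.DataFrame, panel: ReferencePanel | pd.DataFrame
) -> pd.DataFrame:
    """Estimate per-sample cell-type fractions against a reference panel.

    For each sample solves ``min || x - R w ||^2 s.t. w >= 0`` over the
    panel probes present in the matrix, then renormalizes ``w`` to sum to
    one. Returns a samples x cell-types DataFrame whose rows are on the
    simplex.
    """
    if isinstance(panel, pd.DataFrame):
        panel = ReferencePanel(panel)
    values = matrix.values if isinstance(matrix, MethylationMatrix) else matrix
    if isinstance(matrix, MethylationMatrix) and matrix.scale != "beta":
        raise ValueError("deconvolution expects beta-scale methylation")

    common = panel.probe_ids.intersection(values.columns)
    if len(common) < panel.table.shape[1]:
        raise ValueError(
            f"underdetermined: {len(common)} panel probes present for "
            f"{panel.table.shape[1]} cell types"
        )
    R = panel.table.loc[common].to_numpy(dtype=float)
    X = values[common].to_numpy(dtype=float)

    out = np.empty((X.shape[0], R.shape[1]))
    for i, x in enumerate(X):
        w, _ = nnls(R, x)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"all-zero deconvolution solution for sample {values.index[i]!r}"
            )
        out[i] = w / total
    return pd.DataFrame(out, index=values.index, columns=panel.cell_types)
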