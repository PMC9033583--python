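"""Matrix conditioning: detection filter, half-minimum imputation, quantile
normalization and log2 transform.

The pipeline order is filter -> impute -> quantile-normalize -> log2:
imputation needs per-protein minima on the linear scale, and quantile
normalization assumes a complete matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

__all__ = [
    "filter_by_detection",
    "impute_half_min",
    "quantile_normalize",
    "log2_transform",
    "preprocess_pipeline",
]


def filter_by_detection(m: AbundanceMatrix, min_frac: float = 0.5) -> AbundanceMatrix:
    """Drop proteins detected in fewer than ``min_frac`` of all samples.

    A protein detected in exactly the threshold fraction is retained
    (only those *below* the threshold are excluded).  Row order is preserved.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    detected = m.data.notna().sum(axis=1) / m.n_samples
    keep = detected >= min_frac - 1e-12
    if not keep.any():
        warnings.warn("detection filter removed every protein", stacklevel=2)
    return AbundanceMatrix(m.data.loc[keep], scale=m.scale)


def impute_half_min(m: AbundanceMatrix) -> AbundanceMatrix:
    """Replace each missing cell with half the protein's minimal observed value."""
    if m.scale != "linear":
        raise ValueError("half-minimum imputation operates on the linear scale")
    vals = m.values()
    if np.all(np.isnan(vals), axis=1).any():
        raise ValueError("all-missing protein row; apply the detection filter first")
    row_min = np.nanmin(vals, axis=1)
    fill = np.where(np.isnan(vals), (row_min / 2.0)[:, None], vals)
    return AbundanceMatrix(
        pd.DataFrame(fill, index=m.data.index, columns=m.data.columns), scale=m.scale
    )


def quantile_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Force every sample column onto the common distribution of mean order
    statistics; tied values within a column receive the mean of their target
    quantiles.  Within-column rank order is preserved."""
    vals = m.values()
    if np.isnan(vals).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n, k = vals.shape
    if k == 1:
        return AbundanceMatrix(m.data.copy(), scale=m.scale)
    target = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(k):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # tie blocks in sorted order -> mean of the spanned target quantiles
        starts = np.r_[0, np.nonzero(np.diff(sorted_col))[0] + 1]
        sizes = np.diff(np.r_[starts, n])
        block_means = np.add.reduceat(target, starts) / sizes
        out[order, j] = np.repeat(block_means, sizes)
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns), scale=m.scale
    )


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise log2 of a complete, strictly positive linear matrix."""
    if m.scale != "linear":
        raise ValueError("matrix is already log2-scaled")
    vals = m.values()
    if np.isnan(vals).any() or np.any(vals <= 0):
        raise ValueError("log2 transform requires complete, strictly positive values")
    return AbundanceMatrix(
        pd.DataFrame(np.log2(vals), index=m.data.index, columns=m.data.columns),
        scale="log2",
    )


def preprocess_pipeline(
    m: AbundanceMatrix,
    min_frac: float = 0.5,
    quantile: bool = True,
) -> AbundanceMatrix:
    """filter -> impute -> (quantile normalize) -> log2."""
    out = filter_by_detection(m, min_frac=min_frac)
    out = impute_half_min(out)
    if quantile:
        out = quantile_normalize(out)
    return log2_transform(out)
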