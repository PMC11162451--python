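"""Intensity-matrix normalization and spatial-variability filtering.

Matrices are pandas DataFrames: rows are protein accessions, columns are
retained voxel ids, entries are log2 intensities with NaN for missing.
The workflow mirrors label-free DIA downstream processing: keep the fully
quantified rows, quantile-normalize voxels onto a common intensity
distribution, then keep the proteins whose intensity varies most across the
slide (standard error above a cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    IncompleteMatrixError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)

__all__ = [
    "SEFilterResult",
    "quantile_normalize",
    "fully_quantified",
    "spatial_se",
    "se_filter",
    "voxel_correlation",
]

#: spatial-variability cutoff on the standard error of protein intensity
DEFAULT_SE_CUTOFF = 0.18


@dataclass
class SEFilterResult:
    """Outcome of the spatial-variability (standard error) filter."""

    se: pd.Series  # per-protein SE across voxels
    cutoff: float
    retained: list[str]  # accessions with SE strictly above cutoff


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every voxel (column) onto the common quantile distribution.

    Each column's sorted values are replaced by the row-wise means of the
    column-sorted matrix; labels are preserved. Idempotent, and requires a
    complete matrix.
    """
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise IncompleteMatrixError("quantile normalization requires a complete matrix")
    order = np.argsort(values, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(values)
    np.put_along_axis(out, order, target[:, None], axis=0)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def fully_quantified(m: pd.DataFrame) -> pd.DataFrame:
    """Rows quantified in every voxel (no missing entries), order preserved."""
    keep = m.notna().all(axis=1)
    out = m.loc[keep]
    if out.empty:
        raise EmptySelectionError("no fully quantified proteins")
    return out


def spatial_se(m: pd.DataFrame) -> pd.Series:
    """Standard error of each protein's intensity across voxels.

    SE = sample standard deviation (n-1 denominator) / sqrt(n_voxels).
    Requires >= 2 voxels and complete rows.
    """
    if m.shape[1] < 2:
        raise InvalidArgumentError("need >= 2 voxels for a standard error")
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise IncompleteMatrixError("spatial_se requires complete rows")
    sd = values.std(axis=1, ddof=1)
    return pd.Series(sd / np.sqrt(m.shape[1]), index=m.index)


def se_filter(m: pd.DataFrame, cutoff: float = DEFAULT_SE_CUTOFF) -> SEFilterResult:
    """Keep the most spatially changed proteins: SE strictly above ``cutoff``.

    The boundary is exclusive (SE == cutoff is dropped); an empty retained
    list is a legitimate outcome.
    """
    se = spatial_se(m)
    retained = [str(p) for p in se.index[se > cutoff]]
    return SEFilterResult(se=se, cutoff=float(cutoff), retained=retained)


def voxel_correlation(m: pd.DataFrame) -> pd.DataFrame:
    """Voxel-by-voxel Pearson correlation of protein intensity profiles.

    Symmetric with unit diagonal; a zero-variance voxel column makes the
    correlation undefined and raises naming the voxel.
    """
    if m.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 proteins")
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise IncompleteMatrixError("voxel_correlation requires a complete matrix")
    sd = values.std(axis=0)
    for voxel, s in zip(m.columns, sd):
        if s == 0:
            raise UndefinedCorrelationError(voxel, "voxel")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=m.columns, columns=m.columns)
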