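"""Filtering and normalisation chain for peak tables.

The stages, in pipeline order:

1. :func:`presence_filter` — keep species present (non-missing and > 0)
   in at least a given fraction of samples (default 90%).
2. :func:`relative_to_sample_median` — express each intensity relative to
   the median positive intensity of its own sample, removing differences
   in cell number / input amount between samples.
3. class/stratum aggregation happens on this ratio scale (see
   :mod:`lipidstress.aggregate`), then
4. :func:`log2_transform` and
5. :func:`relative_to_baseline` — subtract, on the log2 scale, the mean
   of the unstressed (``Nor``) replicates of the same cell line and group,
   so baseline group means map to 0.

"Present" means non-missing AND strictly positive: gap-filled zeros are
evidence of absence, not of a low value.  Medians are computed over
non-missing positive values only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import PeakTable

__all__ = [
    "presence_filter",
    "relative_to_sample_median",
    "log2_transform",
    "relative_to_baseline",
    "impute_half_min",
]


def presence_filter(
    table: PeakTable, min_fraction: float = 0.90
) -> tuple[PeakTable, int]:
    """Drop species present in fewer than ``min_fraction`` of samples.

    Returns the filtered table and the number of species removed.
    Presence is non-missing and strictly positive; the boundary is
    inclusive (9/10 samples passes at 0.90).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    vals = table.intensities
    present = vals.notna() & (vals > 0)
    frac = present.sum(axis=1) / vals.shape[1]
    keep = frac[frac >= min_fraction].index.tolist()
    removed = table.n_species - len(keep)
    return table.subset_species(keep), removed


def relative_to_sample_median(table: PeakTable) -> PeakTable:
    """Divide each sample column by its median positive intensity.

    Missing stays missing; the per-sample median of the transformed
    positive values is 1.  A sample without any positive intensity is an
    error (there is nothing to normalise against).
    """
    vals = table.intensities
    positive = vals.where(vals > 0)
    medians = positive.median(axis=0, skipna=True)
    bad = medians.index[medians.isna()].tolist()
    if bad:
        raise ValueError(f"samples with no positive intensities: {bad}")
    return table.with_intensities(vals.div(medians, axis=1))


def log2_transform(table: PeakTable, pseudo: float = 0.0) -> PeakTable:
    """``x -> log2(x + pseudo)``; missing stays missing.

    With the default ``pseudo=0`` any zero intensity is an error rather
    than a silent ``-inf``: an explicit offset must be chosen.
    """
    if pseudo < 0:
        raise ValueError(f"pseudo offset must be >= 0, got {pseudo}")
    vals = table.intensities
    if pseudo == 0 and (vals == 0).any().any():
        raise ValueError("zero intensities present; log2 requires a positive pseudo offset")
    return table.with_intensities(np.log2(vals + pseudo), log_scale=True)


def impute_half_min(table: PeakTable) -> PeakTable:
    """Replace missing/zero cells with half the sample's minimum positive value.

    Produces the complete, strictly positive matrix required by log-scale
    multivariate statistics; intended for use after :func:`presence_filter`
    so at most a small fraction of cells is affected.
    """
    vals = table.intensities
    positive = vals.where(vals > 0)
    fill = positive.min(axis=0, skipna=True) / 2.0
    bad = fill.index[fill.isna()].tolist()
    if bad:
        raise ValueError(f"samples with no positive intensities: {bad}")
    out = vals.copy()
    for col in out.columns:
        mask = out[col].isna() | (out[col] <= 0)
        out.loc[mask, col] = fill[col]
    return table.with_intensities(out)


def relative_to_baseline(
    df: pd.DataFrame,
    value_col: str,
    group_cols: list[str],
    baseline: str = "Nor",
    condition_col: str = "condition",
    cell_line_col: str = "cell_line",
    out_col: str | None = None,
) -> pd.DataFrame:
    """Subtract the per-(cell line, group) mean of baseline replicates.

    Operates on a long table of log2-scale values.  Every (cell line,
    group) combination occurring in ``df`` must have at least one
    baseline row; baseline group means map exactly to 0.
    """
    keys = [cell_line_col, *group_cols]
    base = df[df[condition_col] == baseline]
    if base.empty:
        raise ValueError(f"no rows with baseline condition {baseline!r}")
    base_means = base.groupby(keys, sort=False)[value_col].mean()
    idx = pd.MultiIndex.from_frame(df[keys])
    aligned = base_means.reindex(idx)
    if aligned.isna().any():
        missing = sorted(set(idx[aligned.isna().to_numpy()]))
        raise ValueError(f"groups without baseline replicates: {missing[:10]}")
    out = df.copy()
    out[out_col or value_col] = df[value_col].to_numpy() - aligned.to_numpy()
    return out
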