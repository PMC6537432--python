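"""Class-level, double-bond-stratified aggregates.

For each included lipid class, species are grouped by the largest number
of double bonds found in any single acyl chain (the "double-bond
stratum") and their median-scaled intensities are summed per sample.
The log2 of these stratum sums, expressed relative to the unstressed
baseline of the same cell line, is the per-class profile used to compare
culture conditions: a polyunsaturated-TG loss, for example, appears as a
negative trend of the baseline-relative value against the stratum index.

Class inclusion follows a species-count rule (strictly more than
``min_n`` species, default 6) applied to the post-filter inventory, with
an explicit exclude-list escape hatch.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .io import PeakTable
from .nomenclature import LipidSpecies, max_chain_double_bonds
from .preprocess import relative_to_baseline

__all__ = [
    "class_size_filter",
    "aggregate_double_bond_strata",
    "fig3_matrix",
]


def class_size_filter(
    species: list[LipidSpecies], min_n: int = 6
) -> tuple[set[str], dict[str, int]]:
    """Classes with strictly more than ``min_n`` species.

    Returns the included set and the per-class species counts.
    """
    counts = Counter(sp.lipid_class for sp in species)
    included = {cls for cls, n in counts.items() if n > min_n}
    return included, dict(counts)


def aggregate_double_bond_strata(
    table: PeakTable, classes: set[str] | list[str] | None = None
) -> pd.DataFrame:
    """Sum median-scaled intensities per (sample, class, double-bond stratum).

    Missing intensities contribute 0 to the sums (after the presence
    filter at most a small fraction of cells is affected).  Every species
    of an included class contributes to exactly one stratum per sample.
    Sum-composition species enter by the total-double-bond fallback; the
    per-class fraction of such species is reported as ``inferred_fraction``.
    """
    by_class = Counter(sp.lipid_class for sp in table.species)
    if classes is None:
        classes = set(by_class)
    else:
        classes = set(classes)
        empty = sorted(c for c in classes if by_class[c] == 0)
        if empty:
            raise ValueError(f"classes with zero species in table: {empty}")

    info = pd.DataFrame(
        {
            "raw_name": [sp.raw_name for sp in table.species],
            "lipid_class": [sp.lipid_class for sp in table.species],
            "db_stratum": [max_chain_double_bonds(sp) for sp in table.species],
            "inferred": [not sp.chain_resolved for sp in table.species],
        }
    )
    info = info[info["lipid_class"].isin(classes)]
    inferred_frac = info.groupby("lipid_class")["inferred"].mean()

    long = (
        table.intensities.loc[info["raw_name"]]
        .fillna(0.0)
        .reset_index(names="raw_name")
        .melt(id_vars="raw_name", var_name="sample_id", value_name="intensity")
        .merge(info, on="raw_name")
    )
    agg = (
        long.groupby(["sample_id", "lipid_class", "db_stratum"], as_index=False)["intensity"]
        .sum()
        .rename(columns={"intensity": "ratio_sum"})
    )
    agg["inferred_fraction"] = agg["lipid_class"].map(inferred_frac)

    if table.samples is not None:
        agg = table.sample_meta_frame().merge(agg, on="sample_id")
    return agg.sort_values(
        [c for c in ("cell_line", "condition", "replicate", "sample_id", "lipid_class", "db_stratum") if c in agg.columns],
        kind="mergesort",
        key=lambda s: s if s.name != "condition" else s.map(_cond_key),
    ).reset_index(drop=True)


def _cond_key(c: str) -> str:
    from .io import CONDITION_ORDER

    try:
        return f"{CONDITION_ORDER.index(c):02d}"
    except ValueError:
        return f"{len(CONDITION_ORDER):02d}{c}"


def fig3_matrix(
    aggregates: pd.DataFrame, baseline: str = "Nor", pseudo: float = 0.0
) -> pd.DataFrame:
    """Baseline-relative log2 stratum profile per cell line and condition.

    Takes the output of :func:`aggregate_double_bond_strata` (which must
    include the baseline condition), log2-transforms the ratio-scale sums
    and subtracts the baseline mean of the same (cell line, class,
    stratum).  Baseline group means map to 0.
    """
    required = {"cell_line", "condition", "lipid_class", "db_stratum", "ratio_sum"}
    missing = required - set(aggregates.columns)
    if missing:
        raise ValueError(f"aggregate table missing columns {sorted(missing)}")
    out = aggregates.copy()
    if pseudo < 0:
        raise ValueError(f"pseudo offset must be >= 0, got {pseudo}")
    if pseudo == 0 and (out["ratio_sum"] == 0).any():
        raise ValueError(
            "zero stratum sums present; use a positive pseudo offset for log2"
        )
    out["log2_rel_baseline"] = np.log2(out["ratio_sum"] + pseudo)
    out = relative_to_baseline(
        out,
        value_col="log2_rel_baseline",
        group_cols=["lipid_class", "db_stratum"],
        baseline=baseline,
    )
    return out
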