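"""Saturation index and SFA-count stratification.

The saturation index (SI) of a lipid class in a sample is the ratio of
the intensity-weighted saturated-chain total to the intensity-weighted
unsaturated-chain total:

    SI = sum_i I_i * n_sat(i)  /  sum_i I_i * n_unsat(i)

where the sums run over the class's species and ``n_sat``/``n_unsat``
count the species' saturated / unsaturated acyl chains.  Only acyl,
alkyl-ether and sphingoid chains are counted; backbones (glycerol,
sterol, carnitine) never are.  SI is invariant to rescaling all
intensities of a sample, so raw and median-scaled input give identical
values.  A zero denominator (no unsaturated material) leaves SI
undefined; it propagates as missing, never as an injected epsilon.

Triglycerides (3 chains) are additionally stratified by the number of
attached saturated fatty acids: buckets 0 SFA, 1 SFA and >=2 SFA, each
reported as its share of the class's total intensity in the sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import PeakTable
from .nomenclature import count_chain_saturation

__all__ = [
    "saturation_index",
    "tg_sfa_stratification",
    "baseline_si_profile",
    "SFA_BUCKETS",
]

logger = logging.getLogger(__name__)

SFA_BUCKETS = ("0 SFA", "1 SFA", ">=2 SFA")


def _chain_counts(table: PeakTable) -> pd.DataFrame:
    rows = []
    for sp in table.species:
        n_sat, n_unsat, inferred = count_chain_saturation(sp)
        rows.append((sp.raw_name, sp.lipid_class, n_sat, n_unsat, inferred))
    return pd.DataFrame(
        rows, columns=["raw_name", "lipid_class", "n_sat", "n_unsat", "inferred"]
    ).set_index("raw_name")


def saturation_index(
    table: PeakTable,
    classes: set[str] | list[str] | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(sample, class) weighted SFA/UFA totals and their ratio.

    Missing intensities contribute 0.  Returns a long DataFrame with
    columns ``sample_id, lipid_class, sfa_weighted_total,
    ufa_weighted_total, si, inferred_fraction`` (plus sample metadata when
    joined); ``si`` is NaN where the UFA total is 0.
    """
    info = _chain_counts(table)
    present = set(info["lipid_class"])
    if classes is None:
        classes = present
    else:
        classes = set(classes)
        absent = sorted(classes - present)
        if absent:
            raise ValueError(f"classes absent from table: {absent}")
    info = info[info["lipid_class"].isin(classes)]

    vals = table.intensities.loc[info.index].fillna(0.0)
    if samples is not None:
        vals = vals[samples]
    cls = info["lipid_class"]
    sfa = vals.mul(info["n_sat"], axis=0).groupby(cls).sum()
    ufa = vals.mul(info["n_unsat"], axis=0).groupby(cls).sum()
    inferred_frac = info.groupby("lipid_class")["inferred"].mean()

    with np.errstate(divide="ignore", invalid="ignore"):
        si = sfa / ufa.where(ufa > 0)

    def _melt(df: pd.DataFrame, name: str) -> pd.DataFrame:
        out = df.rename_axis(index="lipid_class", columns="sample_id")
        return out.stack(future_stack=True).rename(name).reset_index()

    long = (
        _melt(sfa, "sfa_weighted_total")
        .merge(_melt(ufa, "ufa_weighted_total"), on=["lipid_class", "sample_id"])
        .merge(_melt(si, "si"), on=["lipid_class", "sample_id"])
    )
    long["inferred_fraction"] = long["lipid_class"].map(inferred_frac)
    n_undef = long["si"].isna().sum()
    if n_undef:
        logger.warning("saturation index undefined (UFA total 0) for %d rows", n_undef)

    if table.samples is not None:
        meta = table.sample_meta_frame()
        long = meta.merge(long, on="sample_id")
    cols = [
        c
        for c in (
            "sample_id",
            "cell_line",
            "condition",
            "replicate",
            "lipid_class",
            "sfa_weighted_total",
            "ufa_weighted_total",
            "si",
            "inferred_fraction",
        )
        if c in long.columns
    ]
    return long[cols].sort_values(["sample_id", "lipid_class"], kind="mergesort").reset_index(drop=True)


def tg_sfa_stratification(
    table: PeakTable, lipid_class: str = "TG", ge_bucket: int = 2
) -> pd.DataFrame:
    """Share of a class's intensity in 0 / 1 / >=``ge_bucket`` SFA buckets.

    Each species is assigned to a bucket by its saturated-chain count;
    bucket proportion = bucket intensity sum / total class intensity of
    the sample.  A sample with zero total intensity gets NaN proportions.
    """
    info = _chain_counts(table)
    info = info[info["lipid_class"] == lipid_class]
    if info.empty:
        raise ValueError(f"no {lipid_class} species in table")
    labels = [f"{i} SFA" for i in range(ge_bucket)] + [f">={ge_bucket} SFA"]
    bucket = info["n_sat"].clip(upper=ge_bucket).map(
        lambda n: labels[n] if n < ge_bucket else labels[-1]
    )

    vals = table.intensities.loc[info.index].fillna(0.0)
    sums = vals.groupby(bucket.rename("bucket")).sum().reindex(labels, fill_value=0.0)
    totals = sums.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        props = sums / totals.where(totals > 0)
    if (totals == 0).any():
        logger.warning(
            "zero total %s intensity in %d samples; proportions undefined",
            lipid_class,
            int((totals == 0).sum()),
        )

    def _melt(df: pd.DataFrame, name: str) -> pd.DataFrame:
        out = df.rename_axis(index="bucket", columns="sample_id")
        return out.stack(future_stack=True).rename(name).reset_index()

    long = _melt(sums, "intensity_sum").merge(
        _melt(props, "proportion"), on=["bucket", "sample_id"]
    )
    long["lipid_class"] = lipid_class
    long["bucket"] = pd.Categorical(long["bucket"], categories=labels, ordered=True)
    if table.samples is not None:
        long = table.sample_meta_frame().merge(long, on="sample_id")
    return long.sort_values(["sample_id", "bucket"], kind="mergesort").reset_index(drop=True)


def baseline_si_profile(
    si_table: pd.DataFrame, baseline: str = "Nor"
) -> pd.DataFrame:
    """Mean baseline SI per (cell line, class), ranked within class.

    Takes the long output of :func:`saturation_index` with metadata
    columns; rank 1 is the most saturated cell line for that class.
    """
    for col in ("cell_line", "condition", "lipid_class", "si"):
        if col not in si_table.columns:
            raise ValueError(f"SI table missing column {col!r}")
    base = si_table[si_table["condition"] == baseline]
    if base.empty:
        raise ValueError(f"no rows with baseline condition {baseline!r}")
    prof = (
        base.groupby(["cell_line", "lipid_class"], as_index=False)["si"]
        .mean()
        .rename(columns={"si": "mean_si"})
    )
    # classes whose SI is undefined in every baseline sample keep a NaN rank
    prof["rank"] = prof.groupby("lipid_class")["mean_si"].rank(
        ascending=False, method="min"
    ).astype("Int64")
    return prof.sort_values(["lipid_class", "rank"], kind="mergesort").reset_index(drop=True)
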