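"""Simulation studies that characterise the pipeline's statistical behaviour.

These are the package's own verification experiments, run both by the
test suite and by ``scripts/acceptance.py``:

* inventory tallies of the default synthetic species set;
* the worked saturation-index example computed through the pipeline;
* the VIP mean-square identity on a real fit;
* the repeated-measures-ANOVA / paired-t equivalence for two conditions;
* null calibration of the per-class SI contrast and per-species ANOVA
  under the hypoxia-like scenario (species-level fluctuation with no
  coherent class-level shift);
* recovery of the injected low-serum double-bond slope on TG;
* power to detect a +0.5 TG saturation-index shift at its stated
  settings (noise SD 0.1, three replicates per condition).

Every function takes an explicit seed and is deterministic given it.
Problem sizes are chosen so the full set runs in a couple of minutes on
one core.
"""

from __future__ import annotations

import logging
from collections import Counter
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .aggregate import aggregate_double_bond_strata, class_size_filter, fig3_matrix
from .preprocess import log2_transform, relative_to_sample_median
from .saturation import saturation_index
from .simulate import (
    EffectSpec,
    ScenarioConfig,
    default_scenario,
    generate_inventory,
    generate_peak_table,
)
from .stats import contrast_si, per_species_rm_anova, plsda_vip

__all__ = [
    "inventory_tallies",
    "si_worked_example",
    "vip_mean_square",
    "rm_anova_identity_gap",
    "NullCalibration",
    "hypoxia_null_calibration",
    "ls_tg_db_slope_recovery",
    "tg_si_shift_power",
]


@contextmanager
def _quiet_si_warnings():
    logger = logging.getLogger("lipidstress.saturation")
    level = logger.level
    logger.setLevel(logging.ERROR)
    try:
        yield
    finally:
        logger.setLevel(level)


def inventory_tallies(seed: int = 0) -> dict[str, int]:
    """Species counts of the default synthetic inventory."""
    inv = generate_inventory(seed=seed)
    by_class = Counter(sp.lipid_class for sp in inv)
    by_category = Counter(sp.category for sp in inv)
    return {
        "total": len(inv),
        "phospholipid": by_category["phospholipid"],
        "neutral": by_category["neutral"],
        "PC": by_class["PC"],
        "TG": by_class["TG"],
        "CE": by_class["CE"],
    }


def si_worked_example() -> float:
    """SI of {TG(16:0/16:0/18:1): 10, TG(18:1/18:2/18:1): 5}.

    Weighted totals are SFA 2x10 = 20 and UFA 1x10 + 3x5 = 25, so the
    index is 0.8.
    """
    from .nomenclature import parse_lipid_name
    from .io import PeakTable

    names = ["TG(16:0/16:0/18:1)", "TG(18:1/18:2/18:1)"]
    table = PeakTable(
        [parse_lipid_name(n) for n in names],
        pd.DataFrame({"S1": [10.0, 5.0]}, index=names),
    )
    return float(saturation_index(table)["si"].item())


def vip_mean_square(seed: int = 0) -> float:
    """Mean squared VIP over species for a PLS-DA fit on simulated data."""
    sim = generate_peak_table(default_scenario(seed=seed))
    scaled = relative_to_sample_median(sim.table)
    log2_tab = log2_transform(scaled)
    labels = sim.table.sample_meta_frame()["cell_line"].to_numpy()
    res = plsda_vip(log2_tab.intensities, labels, n_components=2)
    return float((res.vip**2).mean())


def rm_anova_identity_gap(seed: int = 0, n_species: int = 50, n_reps: int = 4) -> float:
    """Max |F - t_paired^2| over species for a two-condition design."""
    from .io import PeakTable, SampleMeta
    from .nomenclature import parse_lipid_name

    rng = np.random.default_rng(seed)
    conditions = ("Nor", "Hyp")
    samples = [
        SampleMeta(f"A549_{c}_R{r}", "A549", c, r)
        for r in range(1, n_reps + 1)
        for c in conditions
    ]
    names = [f"PC {30 + i}:0" for i in range(n_species)]
    vals = rng.normal(size=(n_species, len(samples)))
    table = PeakTable(
        [parse_lipid_name(n) for n in names],
        pd.DataFrame(vals, index=names, columns=[s.sample_id for s in samples]),
        samples,
        log_scale=True,
    )
    res = per_species_rm_anova(table).set_index("species")
    gaps = []
    for i, name in enumerate(names):
        a = vals[i, 0::2]
        b = vals[i, 1::2]
        t = sps.ttest_rel(a, b).statistic
        gaps.append(abs(res.loc[name, "statistic"] - t**2))
    return float(max(gaps))


@dataclass
class NullCalibration:
    """False-positive rates under the hypoxia-like null scenario."""

    si_rate: float  # pooled over analyzed classes
    si_rate_by_class: dict[str, float]
    n_si_contrasts: int
    anova_rate: float
    n_anova_tests: int
    anova_alpha: float


def hypoxia_null_calibration(
    n_repeats: int = 200,
    seed: int = 101,
    species_random_sd: float = 0.3,
    alpha: float = 0.05,
    anova_alpha: float = 0.001,
) -> NullCalibration:
    """Type-I-error study for the hypoxia contrast.

    Each repeat simulates one cell line under baseline and hypoxia (three
    replicates each) with zero-mean per-species fluctuations under
    hypoxia, then applies the pipeline's paired SI contrast to every
    analyzed class and the per-species repeated-measures ANOVA to every
    species.  Both should reject at their nominal rates.
    """
    rng = np.random.default_rng(seed)
    inventory = generate_inventory(seed=int(rng.integers(2**31)))
    included, _ = class_size_filter(inventory)
    hits = {cls: 0 for cls in included}
    anova_hits = 0
    anova_total = 0
    with _quiet_si_warnings():
        for _ in range(n_repeats):
            cfg = ScenarioConfig(
                cell_lines=("A549",),
                conditions=("Nor", "Hyp"),
                replicates=3,
                effects=(EffectSpec("Hyp", "all", "species_random", species_random_sd),),
                seed=int(rng.integers(2**31)),
            )
            sim = generate_peak_table(cfg, inventory=inventory)
            si = saturation_index(sim.table)
            for cls in included:
                r = contrast_si(si, "A549", cls, ("Hyp", "Nor"), paired=True, alpha=alpha)
                hits[cls] += int(r.p_value <= alpha)
            anova = per_species_rm_anova(log2_transform(sim.table), alpha=anova_alpha)
            anova_hits += int(anova["significant"].sum())
            anova_total += len(anova)
    n_contrasts = n_repeats * len(included)
    return NullCalibration(
        si_rate=sum(hits.values()) / n_contrasts,
        si_rate_by_class={cls: hits[cls] / n_repeats for cls in sorted(hits)},
        n_si_contrasts=n_contrasts,
        anova_rate=anova_hits / anova_total,
        n_anova_tests=anova_total,
        anova_alpha=anova_alpha,
    )


def ls_tg_db_slope_recovery(n_repeats: int = 5, seed: int = 101) -> float:
    """Recover the injected low-serum TG double-bond slope (-0.5 log2/db).

    Runs the full preprocessing + aggregation + baseline-relative chain
    on default-scenario simulations and regresses the mean stratum value
    against the double-bond count; returns the mean fitted slope.
    """
    rng = np.random.default_rng(seed)
    slopes = []
    for _ in range(n_repeats):
        cfg = ScenarioConfig(seed=int(rng.integers(2**31)))
        sim = generate_peak_table(cfg)
        scaled = relative_to_sample_median(sim.table)
        agg = aggregate_double_bond_strata(scaled, {"TG"})
        out = fig3_matrix(agg)
        sub = out[(out.lipid_class == "TG") & (out.condition == "LS")]
        means = sub.groupby("db_stratum")["log2_rel_baseline"].mean()
        slopes.append(np.polyfit(means.index.to_numpy(float), means.to_numpy(), 1)[0])
    return float(np.mean(slopes))


def tg_si_shift_power(
    n_repeats: int = 200,
    seed: int = 101,
    shift: float = 0.5,
    noise_sd: float = 0.1,
    n_replicates: int = 3,
    alpha: float = 0.05,
) -> float:
    """Detection rate for a TG saturation-index shift between conditions.

    Per-sample SI values are drawn directly around a baseline level, the
    stressed group displaced by ``shift``; the unpaired (Welch) contrast
    is applied at ``alpha``.
    """
    rng = np.random.default_rng(seed)
    base = 0.6
    hits = 0
    for _ in range(n_repeats):
        rows = []
        for r in range(1, n_replicates + 1):
            rows.append(("KG1", "Nor", r, "TG", rng.normal(base, noise_sd)))
            rows.append(("KG1", "LS", r, "TG", rng.normal(base + shift, noise_sd)))
        df = pd.DataFrame(
            rows, columns=["cell_line", "condition", "replicate", "lipid_class", "si"]
        )
        res = contrast_si(df, "KG1", "TG", ("LS", "Nor"), paired=False, alpha=alpha)
        hits += int(res.p_value <= alpha)
    return hits / n_repeats
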