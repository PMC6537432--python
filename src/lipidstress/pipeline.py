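"""End-to-end orchestration: filter -> normalise -> aggregate -> SI -> stats.

:func:`run_pipeline` executes the full analysis on either a real
alignment export + metadata file or a simulated scenario, and writes a
fixed set of tidy CSVs plus a JSON run manifest.  All results are
computed in memory first and written in one pass at the end, so a
failing stage leaves no partial outputs; stage failures re-raise as
:class:`PipelineError` naming the stage.

Outputs (in the chosen directory)::

    fig3_aggregates.csv      per (cell line, condition, class, double-bond
                             stratum, replicate) ratio-scale sum and
                             baseline-relative log2 value
    saturation_indices.csv   per (sample, class) weighted SFA/UFA totals + SI
    tg_sfa_proportions.csv   TG intensity share in 0 / 1 / >=2 SFA buckets
    baseline_si.csv          mean baseline SI per (cell line, class), ranked
    ordination_scores.csv    PCA sample scores + explained variance fractions
    vip_scores.csv           PLS-DA VIP per species, selection flag
    species_anova.csv        per-species repeated-measures ANOVA per cell line
    si_contrasts.csv         SI t-tests, each stress condition vs baseline
    class_counts.csv         per-class species counts and inclusion flags
    manifest.json            parameters, seed, versions, drop/inferred counts
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregate import aggregate_double_bond_strata, class_size_filter, fig3_matrix
from .io import (
    PeakTable,
    join_metadata,
    read_alignment_table,
    read_metadata,
    write_tidy,
)
from .preprocess import (
    impute_half_min,
    log2_transform,
    presence_filter,
    relative_to_sample_median,
)
from .saturation import baseline_si_profile, saturation_index, tg_sfa_stratification
from .simulate import ScenarioConfig, SimulationResult, generate_peak_table
from .stats import contrast_si, pca, per_species_rm_anova, plsda_vip

__all__ = ["PipelineError", "run_pipeline", "report_summary", "OUTPUT_FILES"]

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "fig3_aggregates.csv",
    "saturation_indices.csv",
    "tg_sfa_proportions.csv",
    "baseline_si.csv",
    "ordination_scores.csv",
    "vip_scores.csv",
    "species_anova.csv",
    "si_contrasts.csv",
    "class_counts.csv",
    "manifest.json",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _versions() -> dict[str, str]:
    import sklearn
    import scipy
    import statsmodels

    return {
        "lipidstress": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def run_pipeline(
    outdir: str | Path,
    table: PeakTable | None = None,
    input_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    scenario: ScenarioConfig | None = None,
    seed: int | None = None,
    min_presence: float = 0.90,
    baseline: str = "Nor",
    min_class_n: int = 6,
    exclude_classes: tuple[str, ...] = (),
    pseudo: float = 0.0,
    alpha: float = 0.05,
    anova_alpha: float = 0.001,
    n_components: int = 2,
    vip_threshold: float = 2.0,
    paired_contrasts: bool = True,
    name_column: str = "Metabolite name",
    first_sample_column: str | None = None,
) -> dict:
    """Run the full analysis and write all result tables.

    Exactly one input source must be given: an in-memory ``table`` (with
    metadata joined), ``input_path`` + ``metadata_path`` files, or a
    synthetic ``scenario`` (``seed`` overrides the scenario seed).
    Returns a dict of the result DataFrames keyed by output file stem,
    plus the manifest.
    """
    outdir = Path(outdir)
    n_sources = sum(x is not None for x in (table, input_path, scenario))
    if n_sources != 1:
        raise ValueError("provide exactly one of table, input_path or scenario")

    manifest: dict = {"parameters": {
        "min_presence": min_presence,
        "baseline": baseline,
        "min_class_n": min_class_n,
        "exclude_classes": sorted(exclude_classes),
        "pseudo": pseudo,
        "alpha": alpha,
        "anova_alpha": anova_alpha,
        "n_components": n_components,
        "vip_threshold": vip_threshold,
        "paired_contrasts": paired_contrasts,
    }, "versions": _versions()}

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Stage()

    with stage("load"):
        if scenario is not None:
            if seed is not None:
                scenario = ScenarioConfig.from_dict({**scenario.to_dict(), "seed": seed})
            sim: SimulationResult = generate_peak_table(scenario)
            table = sim.table
            manifest["scenario"] = scenario.to_dict()
            manifest["seed"] = scenario.seed
        elif input_path is not None:
            if metadata_path is None:
                raise ValueError("metadata_path is required with input_path")
            res = read_alignment_table(input_path, name_column, first_sample_column)
            table = join_metadata(res.table, read_metadata(metadata_path))
            manifest["dropped_rows"] = len(res.dropped)
            manifest["dropped_names_head"] = res.dropped[:20]
        if table.samples is None:
            raise ValueError("peak table has no sample metadata")
        manifest["n_species_input"] = table.n_species
        manifest["n_samples"] = table.n_samples

    with stage("presence_filter"):
        table, n_removed = presence_filter(table, min_presence)
        manifest["n_species_removed_by_presence_filter"] = n_removed
        manifest["n_species_analyzed"] = table.n_species

    with stage("median_normalize"):
        scaled = relative_to_sample_median(table)

    with stage("class_filter"):
        included, counts = class_size_filter(scaled.species, min_class_n)
        included -= set(exclude_classes)
        class_counts = pd.DataFrame(
            {
                "lipid_class": sorted(counts),
                "n_species": [counts[c] for c in sorted(counts)],
            }
        )
        class_counts["included"] = class_counts["lipid_class"].isin(included)
        class_counts["excluded_by_option"] = class_counts["lipid_class"].isin(exclude_classes)
        manifest["included_classes"] = sorted(included)

    with stage("aggregate_strata"):
        aggregates = aggregate_double_bond_strata(scaled, included)

    with stage("baseline_relative"):
        fig3 = fig3_matrix(aggregates, baseline=baseline, pseudo=pseudo)

    with stage("saturation_index"):
        si = saturation_index(scaled)
        manifest["inferred_fraction_by_class"] = (
            si.groupby("lipid_class")["inferred_fraction"].first().round(6).to_dict()
        )
        tg_sfa = tg_sfa_stratification(scaled) if "TG" in counts else pd.DataFrame()
        baseline_si = baseline_si_profile(si, baseline=baseline)

    with stage("multivariate"):
        log2_tab = log2_transform(impute_half_min(scaled))
        meta = table.sample_meta_frame()
        ord_res = pca(log2_tab.intensities, n_components=n_components)
        scores = ord_res.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        scores = meta.merge(scores, on="sample_id")
        for j, frac in enumerate(ord_res.explained_variance_fraction):
            scores[f"explained_PC{j + 1}"] = frac

        n_lines = meta["cell_line"].nunique()
        if n_lines >= 2:
            vip_res = plsda_vip(
                log2_tab.intensities,
                meta["cell_line"].to_numpy(),
                n_components=n_components,
                vip_threshold=vip_threshold,
            )
            vip_df = vip_res.vip.rename_axis("species").reset_index()
            vip_df["selected"] = vip_df["vip"] > vip_threshold
            vip_df = vip_df.sort_values("vip", ascending=False, kind="mergesort").reset_index(drop=True)
        else:
            vip_df = pd.DataFrame(columns=["species", "vip", "selected"])
            manifest["plsda_skipped"] = "single cell line"

    with stage("per_species_anova"):
        anova = per_species_rm_anova(log2_tab, alpha=anova_alpha)

    with stage("si_contrasts"):
        rows = []
        for cl in sorted(meta["cell_line"].unique()):
            for cls in sorted(included):
                for cond in [c for c in meta["condition"].unique() if c != baseline]:
                    try:
                        r = contrast_si(
                            si, cl, cls, (cond, baseline), paired=paired_contrasts, alpha=alpha
                        )
                    except ValueError:
                        if not paired_contrasts:
                            continue
                        try:  # pairing impossible (unmatched replicates): unpaired fallback
                            r = contrast_si(si, cl, cls, (cond, baseline), paired=False, alpha=alpha)
                        except ValueError:
                            continue
                    rows.append(
                        {
                            "cell_line": r.cell_line,
                            "lipid_class": r.lipid_class,
                            "condition": r.condition_a,
                            "baseline": r.condition_b,
                            "test_name": r.test_name,
                            "statistic": r.statistic,
                            "p_value": r.p_value,
                            "stars": r.stars,
                            "significant": r.significant,
                            "degenerate": r.degenerate,
                            "n_condition": r.n_a,
                            "n_baseline": r.n_b,
                        }
                    )
        contrasts = pd.DataFrame(rows)

    with stage("write_outputs"):
        outdir.mkdir(parents=True, exist_ok=True)
        results = {
            "fig3_aggregates": fig3,
            "saturation_indices": si,
            "tg_sfa_proportions": tg_sfa,
            "baseline_si": baseline_si,
            "ordination_scores": scores,
            "vip_scores": vip_df,
            "species_anova": anova,
            "si_contrasts": contrasts,
            "class_counts": class_counts,
        }
        for stem, df in results.items():
            write_tidy(df, outdir / f"{stem}.csv")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    results["manifest"] = manifest
    return results


def report_summary(outdir: str | Path) -> str:
    """Human-readable summary of a pipeline output directory."""
    outdir = Path(outdir)
    missing = [f for f in OUTPUT_FILES if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(f"pipeline outputs missing from {outdir}: {missing}")

    si = pd.read_csv(outdir / "saturation_indices.csv")
    contrasts = pd.read_csv(outdir / "si_contrasts.csv")
    class_counts = pd.read_csv(outdir / "class_counts.csv")
    fig3 = pd.read_csv(outdir / "fig3_aggregates.csv")
    manifest = json.loads((outdir / "manifest.json").read_text())

    lines: list[str] = []
    lines.append("lipidstress run summary")
    lines.append("=======================")
    lines.append(
        f"species analyzed: {manifest.get('n_species_analyzed')} "
        f"(of {manifest.get('n_species_input')}; "
        f"{manifest.get('n_species_removed_by_presence_filter')} removed by presence filter)"
    )
    inc = class_counts[class_counts["included"]]
    lines.append(
        "included classes (n > threshold): "
        + ", ".join(f"{r.lipid_class} (n={r.n_species})" for r in inc.itertuples())
    )
    lines.append("")
    lines.append("mean saturation index by cell line / condition (included classes)")
    star_map = {}
    if not contrasts.empty:
        star_map = {
            (r.cell_line, r.lipid_class, r.condition): r.stars
            for r in contrasts.itertuples()
            if isinstance(r.stars, str)
        }
    sub = si[si["lipid_class"].isin(inc["lipid_class"])]
    piv = sub.pivot_table(index=["cell_line", "lipid_class"], columns="condition", values="si")
    for (cl, cls), row in piv.iterrows():
        cells = []
        for cond, v in row.items():
            star = star_map.get((cl, cls, cond), "")
            cells.append(f"{cond}={v:.3f}{star}")
        lines.append(f"  {cl:8s} {cls:5s} " + "  ".join(cells))
    lines.append("")
    lines.append("double-bond stratum aggregates (baseline-relative log2, head)")
    lines.append(fig3.head(10).to_string(index=False))
    return "\n".join(lines)
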