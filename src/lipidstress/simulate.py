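"""Synthetic lipidomics peak tables with known, recoverable structure.

The generator emulates the study design the analysis expects: a panel of
cell lines cultivated under a baseline (``Nor``) and several stress
conditions, each with a small number of replicate cultures, measured
over a fixed inventory of annotated lipid species.

Log2 peak intensities are additive:

    log2 I(s, sample) = class baseline
                      + species offset            ~ N(0, baseline_log2_sd)
                      + cell-line x species offset ~ N(0, cell_line_log2_sd)
                      + sum of applicable condition effects
                      + replicate noise            ~ N(0, noise_log2_sd)

Condition effects (:class:`EffectSpec`) act multiplicatively on the raw
scale, per class:

* ``db_slope`` — log2 shift proportional to a species' largest per-chain
  double-bond count (polyunsaturated-TG suppression under low serum);
* ``uniform_shift`` — the same log2 shift for every species of the class
  (cholesterol-ester depletion under lipoprotein-deficient serum);
* ``species_random`` — zero-mean per-species log2 fluctuations redrawn
  independently for every sample: species-level variability with no
  coherent class-level component, the hypoxia-like null.

The default inventory reproduces the reference class tallies (244
species; 70 TG, 45 PC, 19 CE, ...).  All randomness flows from a single
seed; identical configs give bit-identical tables, and the injected
ground truth is returned (and serialised) alongside so recovery tests
never re-derive expectations from generator internals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CONDITION_ORDER, PeakTable, SampleMeta
from .nomenclature import (
    EXPECTED_CHAIN_COUNT,
    LipidSpecies,
    max_chain_double_bonds,
    parse_lipid_name,
)

__all__ = [
    "TABLE1_CLASS_COUNTS",
    "STUDY_CELL_LINES",
    "EffectSpec",
    "ScenarioConfig",
    "SimulationResult",
    "default_scenario",
    "generate_inventory",
    "generate_peak_table",
    "inject_missingness",
    "write_scenario_dataset",
]

#: reference per-class species counts of the assay (totals: 244 species,
#: 136 phospholipids, 97 neutral lipids)
TABLE1_CLASS_COUNTS: dict[str, int] = {
    "PC": 45,
    "lysoPC": 2,
    "lysoPE": 4,
    "PG": 1,
    "PPE": 29,
    "PPC": 8,
    "PE": 43,
    "BMP": 4,
    "CE": 19,
    "MG": 1,
    "DG": 7,
    "TG": 70,
    "SM": 4,
    "Acylcarnitine": 5,
    "LanosterylOleate": 1,
    "LanosterylPalmitoleate": 1,
}

STUDY_CELL_LINES = ("KCL22", "KG1", "KU812", "SW480", "SW620", "A549")

# chain pools: biologically common even-carbon acyl chains
_CHAIN_CARBONS = (14, 16, 18, 20, 22)
_CHAIN_DB = (0, 1, 2, 3, 4, 5, 6)
_CHAIN_DB_WEIGHTS = (0.30, 0.30, 0.16, 0.10, 0.07, 0.04, 0.03)
_SPHINGOID_CARBONS = (16, 18, 20)
_SPHINGOID_DB = (0, 1, 2)

EFFECT_MODES = ("db_slope", "uniform_shift", "species_random")


@dataclass(frozen=True)
class EffectSpec:
    """One condition effect on one lipid class (or ``"all"``)."""

    condition: str
    lipid_class: str
    mode: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.mode not in EFFECT_MODES:
            raise ValueError(f"unknown effect mode {self.mode!r}; choose from {EFFECT_MODES}")
        if self.mode == "species_random" and self.magnitude < 0:
            raise ValueError("species_random magnitude is a standard deviation, must be >= 0")


def _default_effects() -> tuple[EffectSpec, ...]:
    return (
        EffectSpec("LS", "TG", "db_slope", -0.5),
        EffectSpec("HypLS", "TG", "db_slope", -0.5),
        EffectSpec("LPDS", "CE", "uniform_shift", -1.0),
        EffectSpec("LS", "DG", "uniform_shift", 0.5),
        EffectSpec("Hyp", "all", "species_random", 0.3),
        EffectSpec("HypLS", "all", "species_random", 0.3),
    )


@dataclass
class ScenarioConfig:
    """Generating parameters for one synthetic dataset."""

    class_counts: dict[str, int] = field(default_factory=lambda: dict(TABLE1_CLASS_COUNTS))
    cell_lines: tuple[str, ...] = STUDY_CELL_LINES
    conditions: tuple[str, ...] = CONDITION_ORDER
    replicates: int = 3
    baseline_condition: str = "Nor"
    baseline_log2_mean: float = 14.0
    baseline_log2_sd: float = 1.5
    cell_line_log2_sd: float = 0.5
    noise_log2_sd: float = 0.25
    effects: tuple[EffectSpec, ...] = field(default_factory=_default_effects)
    seed: int = 42

    def __post_init__(self) -> None:
        self.class_counts = dict(self.class_counts)
        self.cell_lines = tuple(self.cell_lines)
        self.conditions = tuple(self.conditions)
        self.effects = tuple(
            e if isinstance(e, EffectSpec) else EffectSpec(**e) for e in self.effects
        )
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        unknown = sorted(set(self.class_counts) - set(EXPECTED_CHAIN_COUNT))
        if unknown:
            raise ValueError(f"unknown lipid classes in class_counts: {unknown}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        for sd in (self.baseline_log2_sd, self.cell_line_log2_sd, self.noise_log2_sd):
            if sd <= 0:
                raise ValueError("standard deviations must be > 0")
        if self.baseline_condition not in self.conditions:
            raise ValueError(
                f"conditions {self.conditions} must include the baseline "
                f"{self.baseline_condition!r}"
            )

    # -- (de)serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_lines"] = list(self.cell_lines)
        d["conditions"] = list(self.conditions)
        d["effects"] = [asdict(e) for e in self.effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_scenario(seed: int = 42) -> ScenarioConfig:
    """The study-design scenario: full inventory, 6 lines x 5 conditions x 3."""
    return ScenarioConfig(seed=seed)


@dataclass
class SimulationResult:
    table: PeakTable
    ground_truth: dict
    config: ScenarioConfig


def _chain_pool_size(lipid_class: str) -> int:
    """Number of distinct species constructible for a class."""
    n_chain = len(_CHAIN_CARBONS) * len(_CHAIN_DB)
    arity = EXPECTED_CHAIN_COUNT[lipid_class]
    if lipid_class in ("PPE", "PPC"):
        return n_chain * n_chain  # vinyl-ether chain x ester chain
    if lipid_class == "SM":
        return len(_SPHINGOID_CARBONS) * len(_SPHINGOID_DB) * n_chain
    # unordered multisets of ester chains
    return math.comb(n_chain + arity - 1, arity)


def _draw_chain(rng: np.random.Generator, linkage_prefix: str = "") -> str:
    carbons = int(rng.choice(_CHAIN_CARBONS))
    db = int(rng.choice(_CHAIN_DB, p=_CHAIN_DB_WEIGHTS))
    return f"{linkage_prefix}{carbons}:{db}"


def _draw_species_name(lipid_class: str, rng: np.random.Generator) -> str:
    arity = EXPECTED_CHAIN_COUNT[lipid_class]
    if lipid_class in ("PPE", "PPC"):
        base = "PE" if lipid_class == "PPE" else "PC"
        return f"{base}({_draw_chain(rng, 'P-')}/{_draw_chain(rng)})"
    if lipid_class == "SM":
        c = int(rng.choice(_SPHINGOID_CARBONS))
        d = int(rng.choice(_SPHINGOID_DB))
        return f"SM(d{c}:{d}/{_draw_chain(rng)})"
    chains = sorted(
        (_draw_chain(rng) for _ in range(arity)),
        key=lambda t: tuple(int(x) for x in t.split(":")),
    )
    return f"{lipid_class}({'/'.join(chains)})"


def generate_inventory(
    class_counts: dict[str, int] | None = None, seed: int = 0
) -> list[LipidSpecies]:
    """Draw a distinct, chain-resolved species inventory per class.

    Deterministic given the seed; with the default counts the inventory
    reproduces the reference tallies exactly (244 species in total).
    """
    counts = dict(TABLE1_CLASS_COUNTS if class_counts is None else class_counts)
    rng = np.random.default_rng(seed)
    inventory: list[LipidSpecies] = []
    for lipid_class in sorted(counts):
        n = counts[lipid_class]
        if n == 0:
            continue
        pool = _chain_pool_size(lipid_class)
        if n > pool:
            raise ValueError(
                f"{lipid_class}: requested {n} species but only {pool} distinct "
                "chain combinations exist"
            )
        names: set[str] = set()
        attempts = 0
        while len(names) < n:
            attempts += 1
            if attempts > 1000 * n:
                raise RuntimeError(f"{lipid_class}: could not draw {n} distinct species")
            names.add(_draw_species_name(lipid_class, rng))
        inventory.extend(parse_lipid_name(nm) for nm in sorted(names))
    return inventory


def generate_peak_table(
    config: ScenarioConfig, inventory: list[LipidSpecies] | None = None
) -> SimulationResult:
    """Simulate a complete peak table (plus injected ground truth).

    Passing a pre-built ``inventory`` skips the (deterministic) inventory
    draw, which is convenient for repeated simulations over a fixed
    species set.
    """
    rng = np.random.default_rng(config.seed)
    if inventory is None:
        inventory = generate_inventory(config.class_counts, seed=int(rng.integers(2**31)))
    else:
        rng.integers(2**31)  # keep the stream aligned with the inventory-drawing path
    names = [sp.raw_name for sp in inventory]
    S = len(inventory)
    classes = np.array([sp.lipid_class for sp in inventory])
    max_db = np.array([max_chain_double_bonds(sp) for sp in inventory], dtype=float)

    samples = [
        SampleMeta(f"{cl}_{cond}_R{rep}", cl, cond, rep)
        for cl in config.cell_lines
        for cond in config.conditions
        for rep in range(1, config.replicates + 1)
    ]
    N = len(samples)
    cond_idx = {c: i for i, c in enumerate(config.conditions)}
    line_idx = {c: i for i, c in enumerate(config.cell_lines)}

    species_offset = rng.normal(0.0, config.baseline_log2_sd, size=S)
    line_offset = rng.normal(0.0, config.cell_line_log2_sd, size=(S, len(config.cell_lines)))

    # deterministic per-condition, per-species log2 shifts
    det_delta = np.zeros((S, len(config.conditions)))
    random_sd = np.zeros((S, len(config.conditions)))
    for eff in config.effects:
        if eff.condition not in cond_idx:
            continue
        mask = np.ones(S, dtype=bool) if eff.lipid_class == "all" else classes == eff.lipid_class
        j = cond_idx[eff.condition]
        if eff.mode == "db_slope":
            det_delta[mask, j] += eff.magnitude * max_db[mask]
        elif eff.mode == "uniform_shift":
            det_delta[mask, j] += eff.magnitude
        else:  # species_random: per-sample, zero-mean fluctuation
            random_sd[mask, j] = np.sqrt(random_sd[mask, j] ** 2 + eff.magnitude**2)

    log2I = np.empty((S, N))
    for k, sm in enumerate(samples):
        j = cond_idx[sm.condition]
        col = (
            config.baseline_log2_mean
            + species_offset
            + line_offset[:, line_idx[sm.cell_line]]
            + det_delta[:, j]
        )
        sd_extra = random_sd[:, j]
        if (sd_extra > 0).any():
            col = col + rng.normal(0.0, 1.0, size=S) * sd_extra
        col = col + rng.normal(0.0, config.noise_log2_sd, size=S)
        log2I[:, k] = col

    intensities = pd.DataFrame(2.0**log2I, index=names, columns=[s.sample_id for s in samples])
    table = PeakTable(list(inventory), intensities, samples)

    ground_truth = {
        "seed": config.seed,
        "effects": [asdict(e) for e in config.effects],
        "det_delta_log2": {
            cond: {names[i]: float(det_delta[i, j]) for i in np.nonzero(det_delta[:, j])[0]}
            for cond, j in cond_idx.items()
        },
        "species_random_sd_log2": {
            cond: {names[i]: float(random_sd[i, j]) for i in np.nonzero(random_sd[:, j])[0]}
            for cond, j in cond_idx.items()
        },
    }
    return SimulationResult(table=table, ground_truth=ground_truth, config=config)


def inject_missingness(table: PeakTable, rate: float, seed: int = 0) -> PeakTable:
    """Mask cells missing uniformly at random at ``rate``; deterministic per seed."""
    if not 0 <= rate < 1:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if rate == 0:
        return table.with_intensities(table.intensities.copy())
    rng = np.random.default_rng(seed)
    mask = rng.random(table.intensities.shape) < rate
    arr = table.intensities.to_numpy(dtype=float, copy=True)
    arr[mask] = np.nan
    vals = pd.DataFrame(arr, index=table.intensities.index, columns=table.intensities.columns)
    return table.with_intensities(vals)


def write_scenario_dataset(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write the alignment-export dialect, metadata CSV and ground truth.

    Produces exactly the files :mod:`lipidstress.io` reads back:
    ``alignment_table.txt`` (tab-delimited, "Metabolite name" column),
    ``sample_metadata.csv``, plus ``ground_truth.json`` and
    ``scenario.yaml``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.table

    align = table.intensities.copy()
    align.insert(0, "Metabolite name", align.index)
    align_path = outdir / "alignment_table.txt"
    align.to_csv(align_path, sep="\t", index=False)

    meta_path = outdir / "sample_metadata.csv"
    table.sample_meta_frame().to_csv(meta_path, index=False)

    gt_path = outdir / "ground_truth.json"
    gt_path.write_text(json.dumps(result.ground_truth, indent=2, sort_keys=True))

    cfg_path = result.config.to_yaml(outdir / "scenario.yaml")
    return {
        "alignment": align_path,
        "metadata": meta_path,
        "ground_truth": gt_path,
        "scenario": cfg_path,
    }
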