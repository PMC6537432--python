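"""Reading alignment exports and sample metadata; tidy result output.

The interchange object between all pipeline stages is :class:`PeakTable`:
a species x samples intensity matrix (pandas DataFrame, NaN = missing)
carrying the parsed :class:`~lipidstress.nomenclature.LipidSpecies`
records and, after :func:`join_metadata`, the per-sample study metadata.

Input dialect is the MS-DIAL-style alignment export: tab-delimited, one
header row, one annotation-name column (default ``"Metabolite name"``)
and one numeric column per sample.  Both column selectors are explicit
parameters; no sniffing.  Blank or non-numeric cells are read as missing,
a literal 0 as zero (alignment gap-filling distinguishes the two).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import LipidParseError, LipidSpecies, parse_lipid_name

__all__ = [
    "CONDITION_ORDER",
    "SampleMeta",
    "PeakTable",
    "AlignmentReadResult",
    "read_alignment_table",
    "read_metadata",
    "join_metadata",
    "write_tidy",
    "read_tidy",
]

logger = logging.getLogger(__name__)

#: canonical ordering of the study's culture conditions
CONDITION_ORDER = ("Nor", "LPDS", "LS", "Hyp", "HypLS")

METADATA_COLUMNS = ("sample_id", "cell_line", "condition", "replicate")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sample: cell line, culture condition, replicate."""

    sample_id: str
    cell_line: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")


def _condition_rank(condition: str) -> tuple[int, str]:
    try:
        return (CONDITION_ORDER.index(condition), condition)
    except ValueError:
        return (len(CONDITION_ORDER), condition)


@dataclass
class PeakTable:
    """Species x samples intensity matrix plus (optionally) sample metadata.

    ``intensities`` is indexed by species ``raw_name`` (matching the order
    of ``species``) with one column per sample id; NaN marks a missing
    measurement, 0 a measured zero.
    """

    species: list[LipidSpecies]
    intensities: pd.DataFrame
    samples: list[SampleMeta] | None = None
    #: True once values are on the log2 scale (negative values allowed)
    log_scale: bool = False

    def __post_init__(self) -> None:
        names = [sp.raw_name for sp in self.species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dupes}")
        if list(self.intensities.index) != names:
            raise ValueError("intensity matrix index does not match species list")
        if self.intensities.columns.duplicated().any():
            raise ValueError("duplicate sample columns in intensity matrix")
        if not self.log_scale:
            vals = self.intensities.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("intensities must be >= 0 or missing")
        if self.samples is not None:
            ids = [s.sample_id for s in self.samples]
            if ids != list(self.intensities.columns):
                raise ValueError("sample metadata order does not match matrix columns")
            triples = [(s.cell_line, s.condition, s.replicate) for s in self.samples]
            if len(set(triples)) != len(triples):
                raise ValueError("(cell_line, condition, replicate) triples must be unique")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def species_names(self) -> list[str]:
        return list(self.intensities.index)

    def species_map(self) -> dict[str, LipidSpecies]:
        return {sp.raw_name: sp for sp in self.species}

    def sample_meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame (requires joined metadata)."""
        if self.samples is None:
            raise ValueError("no sample metadata joined to this table")
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "cell_line": [s.cell_line for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
            }
        )

    def with_intensities(self, intensities: pd.DataFrame, log_scale: bool | None = None) -> "PeakTable":
        """New table with the same species/samples and replaced values."""
        return PeakTable(
            list(self.species),
            intensities,
            None if self.samples is None else list(self.samples),
            self.log_scale if log_scale is None else log_scale,
        )

    def subset_species(self, names: list[str]) -> "PeakTable":
        keep = set(names)
        species = [sp for sp in self.species if sp.raw_name in keep]
        return PeakTable(
            species,
            self.intensities.loc[[sp.raw_name for sp in species]],
            None if self.samples is None else list(self.samples),
            self.log_scale,
        )


@dataclass
class AlignmentReadResult:
    table: PeakTable
    dropped: list[str] = field(default_factory=list)


def read_alignment_table(
    path: str | Path,
    name_column: str = "Metabolite name",
    first_sample_column: str | None = None,
) -> AlignmentReadResult:
    """Read a tab-delimited alignment export into a :class:`PeakTable`.

    All columns from ``first_sample_column`` rightwards are treated as
    samples (every column except ``name_column`` if None).  Rows whose
    annotation does not parse (unknowns, malformed names) are dropped and
    reported in ``dropped``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if name_column not in df.columns:
        raise ValueError(f"alignment table has no {name_column!r} column: {path}")
    if first_sample_column is None:
        sample_cols = [c for c in df.columns if c != name_column]
    else:
        if first_sample_column not in df.columns:
            raise ValueError(f"alignment table has no {first_sample_column!r} column: {path}")
        start = list(df.columns).index(first_sample_column)
        sample_cols = [c for c in df.columns[start:] if c != name_column]
    if not sample_cols:
        raise ValueError(f"alignment table has no sample columns: {path}")

    species: list[LipidSpecies] = []
    rows: list[int] = []
    dropped: list[str] = []
    for i, raw in enumerate(df[name_column]):
        try:
            species.append(parse_lipid_name(raw))
            rows.append(i)
        except LipidParseError:
            dropped.append(raw)
    if dropped:
        logger.info("dropped %d unannotated/unparseable rows", len(dropped))

    names = [sp.raw_name for sp in species]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate species names in alignment table: {dupes}")

    values = df.loc[rows, sample_cols].apply(pd.to_numeric, errors="coerce")
    values.index = names
    if (values.to_numpy() < 0).any():
        raise ValueError("negative intensities in alignment table")
    return AlignmentReadResult(PeakTable(species, values.astype(float)), dropped)


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a comma- or tab-delimited sample metadata file.

    Requires header columns ``sample_id, cell_line, condition, replicate``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file missing columns {missing}: {path}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"].unique())
        raise ValueError(f"duplicate sample_id in metadata: {dupes}")
    meta = [
        SampleMeta(r.sample_id, r.cell_line, r.condition, int(r.replicate))
        for r in df.itertuples(index=False)
    ]
    triples = [(m.cell_line, m.condition, m.replicate) for m in meta]
    if len(set(triples)) != len(triples):
        raise ValueError("duplicate (cell_line, condition, replicate) triples in metadata")
    return meta


def join_metadata(table: PeakTable, meta: list[SampleMeta]) -> PeakTable:
    """Attach sample metadata and order samples by (cell line, condition, replicate).

    Every intensity column must appear exactly once in ``meta`` and vice
    versa; mismatches raise with the offending ids listed.
    """
    ids = [m.sample_id for m in meta]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id in metadata: {dupes}")
    cols = set(table.sample_ids)
    orphan_cols = sorted(cols - set(ids))
    orphan_meta = sorted(set(ids) - cols)
    if orphan_cols or orphan_meta:
        raise ValueError(
            f"sample/metadata mismatch: columns without metadata {orphan_cols}, "
            f"metadata without columns {orphan_meta}"
        )
    ordered = sorted(meta, key=lambda m: (m.cell_line, _condition_rank(m.condition), m.replicate))
    return PeakTable(
        list(table.species),
        table.intensities[[m.sample_id for m in ordered]],
        ordered,
    )


def write_tidy(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format result table as CSV (full float precision)."""
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_tidy(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
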