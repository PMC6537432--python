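"""Shared fixtures: small hand-built peak tables and a default simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lipidstress import (
    PeakTable,
    SampleMeta,
    default_scenario,
    generate_peak_table,
    parse_lipid_name,
)


def build_table(
    data: dict[str, list[float]],
    sample_ids: list[str] | None = None,
    meta: list[SampleMeta] | None = None,
) -> PeakTable:
    """PeakTable from {annotation: intensities}; None marks missing."""
    species = [parse_lipid_name(name) for name in data]
    n = len(next(iter(data.values())))
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    mat = pd.DataFrame(
        {sid: [data[name][j] for name in data] for j, sid in enumerate(sample_ids)},
        index=list(data),
        dtype=float,
    )
    return PeakTable(species, mat, meta)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulation shared across tests (seed fixed)."""
    return generate_peak_table(default_scenario(seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(20210)
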