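"""Shared fixtures: random tabular fixtures generated in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phosphoadhesome.io import (
    CONTROL,
    TREATMENT,
    WINDOW_CENTER,
    PhosphositeRecord,
    RunInfo,
    SpectralCountMatrix,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_runs(n_per_condition: int = 3) -> list[RunInfo]:
    return [
        RunInfo(run_id=f"{cond}_{chr(65 + i)}", condition=cond, replicate=chr(65 + i))
        for cond in (TREATMENT, CONTROL)
        for i in range(n_per_condition)
    ]


def random_matrix(
    rng: np.random.Generator, n_proteins: int = 8, n_per_condition: int = 3, max_count: int = 30
) -> SpectralCountMatrix:
    runs = make_runs(n_per_condition)
    accs = [f"P{i:03d}" for i in range(n_proteins)]
    counts = pd.DataFrame(
        rng.integers(0, max_count, size=(n_proteins, len(runs))),
        index=pd.Index(accs, name="accession"),
        columns=[r.run_id for r in runs],
    )
    # normalize() requires a nonzero column; force one count per run
    for col in counts.columns:
        if counts[col].sum() == 0:
            counts.loc[accs[0], col] = 1
    mw = pd.Series(rng.uniform(10, 250, size=n_proteins), index=accs)
    return SpectralCountMatrix(counts=counts, molecular_weight=mw, runs=runs)


def random_window(rng: np.random.Generator, residue: str) -> str:
    chars = rng.choice(list(AA), size=15)
    chars[WINDOW_CENTER] = residue
    return "".join(chars)


def random_sites(
    rng: np.random.Generator,
    n: int = 10,
    runs: list[RunInfo] | None = None,
    max_count: int = 6,
) -> tuple[list[PhosphositeRecord], list[RunInfo]]:
    runs = runs or make_runs()
    records = []
    seen = set()
    while len(records) < n:
        acc = f"P{rng.integers(0, max(2, n // 2)):03d}"
        pos = int(rng.integers(1, 400))
        if (acc, pos) in seen:
            continue
        seen.add((acc, pos))
        residue = str(rng.choice(["S", "T", "Y"], p=[0.7, 0.15, 0.15]))
        counts = {r.run_id: int(rng.integers(0, max_count)) for r in runs}
        if sum(counts.values()) == 0:
            counts[runs[0].run_id] = 1
        records.append(
            PhosphositeRecord(
                accession=acc,
                position=pos,
                residue=residue,
                window=random_window(rng, residue),
                counts=counts,
            )
        )
    return records, runs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
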