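"""Shared fixtures and table-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from refstab.cq_data import CollapsedCqTable, Design, DEFAULT_DESIGN


def make_collapsed(values, genes=None, genotypes=None, regions=None,
                   design: Design = DEFAULT_DESIGN) -> CollapsedCqTable:
    """Build a CollapsedCqTable from a 2-D array.

    Samples are laid out in one region/genotype unless explicit per-sample
    ``genotypes``/``regions`` lists are given; biological replicate numbers
    count up within each (region, genotype) cell.
    """
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    if genes is None:
        genes = [f"G{i}" for i in range(n_genes)]
    if genotypes is None:
        genotypes = [design.genotypes[0]] * n_samples
    if regions is None:
        regions = [design.regions[0]] * n_samples
    counter: dict[tuple[str, str], int] = {}
    rows = []
    for s in range(n_samples):
        key = (regions[s], genotypes[s])
        counter[key] = counter.get(key, 0) + 1
        sid = f"{regions[s].replace(' ', '-')}|{genotypes[s]}|b{counter[key]}"
        rows.append({"sample_id": sid, "region": regions[s],
                     "genotype": genotypes[s], "bio_rep": counter[key]})
    samples = pd.DataFrame(rows).set_index("sample_id")
    frame = pd.DataFrame(arr, index=genes, columns=samples.index)
    return CollapsedCqTable(frame, samples, design)


def random_collapsed(rng: np.random.Generator, n_genes: int, n_samples: int,
                     two_genotypes: bool = False) -> CollapsedCqTable:
    """A random Cq table in 15..35 cycles; optionally split into the two
    design genotypes (for grouped estimators)."""
    arr = rng.uniform(15.0, 35.0, size=(n_genes, n_samples))
    genotypes = None
    if two_genotypes:
        half = n_samples // 2
        genotypes = ["WT"] * half + ["PWScr"] * (n_samples - half)
    return make_collapsed(arr, genotypes=genotypes)


def table_as_dict(t: CollapsedCqTable) -> dict[str, list[float]]:
    return {g: t.values.loc[g].tolist() for g in t.values.index}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
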