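"""Shared fixtures: tiny hand-built cohorts used across the suite."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pogsa import (
    GeneModelTable,
    GeneSetCollection,
    MutationCatalog,
    MutationEvent,
    PassengerModel,
)


def uniform_gene_models(genes, length=1000.0, contexts=("ctx",)) -> GeneModelTable:
    table = pd.DataFrame(
        {c: [length] * len(genes) for c in contexts},
        index=pd.Index(list(genes), name="gene"),
    )
    return GeneModelTable(table)


@pytest.fixture
def ten_patient_scenarios():
    """The two contrasting ten-mutation configurations of one 10-gene set.

    Universe of 50 genes; pathway = first 10 genes.  'exclusive': each of
    ten patients carries one mutation in a distinct pathway gene (every
    patient altered).  'concentrated': one patient carries all ten
    mutations, the other nine none.  Per-gene totals are identical between
    the two catalogs.
    """
    universe = [f"g{j:02d}" for j in range(50)]
    pathway = universe[:10]
    patients = [f"P{i}" for i in range(10)]
    exclusive = MutationCatalog(
        patients,
        universe,
        [MutationEvent(patients[i], pathway[i], "ctx") for i in range(10)],
    )
    concentrated = MutationCatalog(
        patients,
        universe,
        [MutationEvent(patients[0], g, "ctx") for g in pathway],
    )
    sets = GeneSetCollection({"pathway": tuple(pathway)})
    models = uniform_gene_models(universe)
    rates = PassengerModel({"ctx": 1e-4})
    return {
        "exclusive": exclusive,
        "concentrated": concentrated,
        "sets": sets,
        "models": models,
        "rates": rates,
        "pathway": pathway,
        "universe": universe,
    }


@pytest.fixture
def small_catalog():
    """3 patients, 6 genes, mixed multiplicities."""
    universe = list("ABCDEF")
    events = [
        MutationEvent("s1", "A", "ctx"),
        MutationEvent("s1", "A", "ctx"),  # same gene twice
        MutationEvent("s1", "B", "ctx"),
        MutationEvent("s2", "C", "ctx"),
        # s3 has no events
    ]
    return MutationCatalog(["s1", "s2", "s3"], universe, events)
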