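"""Shared fixtures: simulated samples at the benchmark study conditions.

The "polyclonal reference sample" mirrors the benchmark tumor the analysis
is designed around: ~4,000 cells, three tumor subclones carrying 15 truncal
plus 0/8/28 private mutations (clone totals 15/23/43), 20% diploid cells,
~9% allelic dropout, ~8% doublets, 164x mean depth, and clone-specific CNA
events at copy numbers 1, 3 and 4.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mptseq.model import ClonalModel
from mptseq.simulate import CnaEvent, simulate_dataset, simulate_truth

CNA_EVENTS = [
    CnaEvent(clone=1, amplicons=[100, 101, 102, 103], cn=3),
    CnaEvent(clone=2, amplicons=[104, 105, 106, 107], cn=1),
    CnaEvent(clone=3, amplicons=[108, 109, 110, 111], cn=4),
]


@pytest.fixture(scope="session")
def polyclonal_truth():
    return simulate_truth(seed=1, cna_events=CNA_EVENTS)


@pytest.fixture(scope="session")
def polyclonal_sample(polyclonal_truth):
    counts, genotypes, cells = simulate_dataset(
        polyclonal_truth, 4000, seed=11
    )
    return counts, genotypes, cells


@pytest.fixture(scope="session")
def polyclonal_fit(polyclonal_truth, polyclonal_sample):
    counts, genotypes, _ = polyclonal_sample
    model = ClonalModel.from_simulation(polyclonal_truth, counts, genotypes)
    return model.fit(seed=0)


@pytest.fixture(scope="session")
def small_sample():
    """A fast 600-cell version of the polyclonal sample for unit tests."""
    truth = simulate_truth(seed=3, cna_events=CNA_EVENTS, n_amplicons=120)
    counts, genotypes, cells = simulate_dataset(truth, 600, seed=5)
    return truth, counts, genotypes, cells


def singlet_labels(cells) -> dict:
    return {c.cell_id: c.clone for c in cells if not c.is_doublet}


def majority_clone_map(assignment, cells) -> dict:
    """Cluster label -> majority true clone among its singlet cells."""
    truth = singlet_labels(cells)
    mapping = {}
    for lab in assignment.cluster_labels():
        clones = [truth[c] for c in assignment.cells_in(lab) if c in truth]
        if clones:
            mapping[lab] = pd.Series(clones).mode().iloc[0]
    return mapping
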