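"""Shared fixtures: tiny hand-built graphs and cached synthetic sets."""

import pytest

from quboasm import (
    SequenceRecord,
    build_olc_graph,
    generate_problem_set,
)
from quboasm.olc_graph import OLCGraph

GENERATION_SEED = 12345  # fixed seed for the study problem set


@pytest.fixture
def chain3():
    """The 3-mer chain of 'ATGCA': ATG -> TGC -> GCA, a unique path."""
    frags = [SequenceRecord(f"k{i}", s) for i, s in enumerate(["ATG", "TGC", "GCA"])]
    return build_olc_graph(frags, min_overlap=2)


@pytest.fixture
def chain6():
    """A 6-vertex chain graph built by hand."""
    g = OLCGraph()
    for i in range(6):
        g.add_vertex(f"v{i}", "A" * 3)  # strings unused by partition logic
    for i in range(5):
        g.add_edge(f"v{i}", f"v{i+1}", 2)
    return g


@pytest.fixture(scope="session")
def problem_set():
    """The full 60-problem synthetic set (lengths 5-10, k=3)."""
    pset = generate_problem_set(range(5, 11), per_length=10, k=3, rng_seed=GENERATION_SEED)
    assert pset.complete
    return pset


@pytest.fixture(scope="session")
def problem_set_short(problem_set):
    """The lengths <= 7 half of the study set (annealer-friendly sizes)."""
    short = [p for p in problem_set.problems if len(p.source) <= 7]
    assert len(short) == 30
    return short
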