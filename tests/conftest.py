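"""Shared fixtures: consensus library, simulated cohorts and pipeline runs.

The heavier cohorts are session-scoped so that curation, structure and
transduction results are computed once and shared across test modules.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest
from hypothesis import settings

from svatrx.align import ReferenceIndex
from svatrx.consensus import load_default_library
from svatrx.curation import curate_callset
from svatrx.simulate import SimulationConfig, simulate
from svatrx.sources import classify_polymorphism, find_source_elements
from svatrx.structure import annotate_structures
from svatrx.transduction import call_transductions

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return load_default_library()


def _run_pipeline(result):
    ref = ReferenceIndex(result.reference)
    curation = curate_callset(result.records, ref)
    passing = [
        r
        for r, c in zip(result.records, curation)
        if c.verdict
    ]
    structures = annotate_structures(passing, load_default_library(), curation)
    calls = call_transductions(passing, structures, ref, curation, result.annotation)
    sources = find_source_elements(calls, result.annotation, passing, result.reference)
    classify_polymorphism(
        sources,
        result.annotation,
        {rec[2]: rec[3] for rec in result.del_records},
        passing,
        result.samples,
    )
    return SimpleNamespace(
        sim=result,
        reference=ref,
        curation=curation,
        curation_by_id={c.insertion_id: c for c in curation},
        passing=passing,
        structures=structures,
        structures_by_id={s.insertion_id: s for s in structures},
        calls=calls,
        sources=sources,
        truth=result.truth.insertions.set_index("id"),
        details=result.truth.details,
    )


@pytest.fixture(scope="session")
def cohort200():
    """Unmutated 200-insertion cohort with 10 reference-present decoys."""
    cfg = SimulationConfig(seed=101, n_insertions=200, mutation_rate=0.0, n_decoys=10)
    return simulate(cfg)


@pytest.fixture(scope="session")
def pipeline200(cohort200):
    return _run_pipeline(cohort200)


@pytest.fixture(scope="session")
def cohort_mutated():
    """150-insertion cohort at the default per-base mutation rate."""
    return simulate(SimulationConfig(seed=5, n_insertions=150))


@pytest.fixture(scope="session")
def pipeline_mutated(cohort_mutated):
    return _run_pipeline(cohort_mutated)


@pytest.fixture(scope="session")
def cohort_sources50():
    """A 50-source design for source-element recovery."""
    cfg = SimulationConfig(
        seed=7,
        n_insertions=150,
        mutation_rate=0.0,
        n_sources=50,
        n_alt_sources=4,
        n_nonref_sources=4,
        n_inactive_reference_sva=4,
        lost_source_offspring=0,
        orphan_td_count=1,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def pipeline_sources50(cohort_sources50):
    return _run_pipeline(cohort_sources50)
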