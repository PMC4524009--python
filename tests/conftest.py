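"""Shared fixtures: synthetic genomes, reads, and pre-run pipelines.

Everything is generated programmatically with fixed seeds; the larger
fixtures are session-scoped because several test modules reuse them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from pairlink import (
    LongReadSet,
    build_bloom,
    build_links,
    build_scaffolds,
    extract_pairs,
    junction_spanning_reads,
    make_truth,
    place_kmers,
)
from pairlink.simulate import r7_preset

K = 15
D_RUN = 6000  # pair spacing used for fixture runs; tolerance e*d = 600 > max gap
E_RUN = 0.1
MIN_LINKS = 5
MAX_RATIO = 0.3


@dataclass
class PipelineRun:
    truth: object
    reads: LongReadSet
    filt: object
    store: object
    placement: object
    links: list
    log: object
    layouts: list


def run_pipeline(truth, reads, d=D_RUN, e=E_RUN, k=K, p=0.001, t=2,
                 l=MIN_LINKS, a=MAX_RATIO, backend=None) -> PipelineRun:
    filt = backend if backend is not None else build_bloom(truth.contigs, k, p)
    store = extract_pairs(reads, filt, k, d, t)
    placement = place_kmers(truth.contigs, k, store)
    links, log = build_links(store, placement, truth.contigs, d, e)
    layouts = build_scaffolds(links, truth.contigs, l, a)
    return PipelineRun(truth, reads, filt, store, placement, links, log, layouts)


@pytest.fixture(scope="session")
def small_truth():
    """50 kbp genome in 5 contigs; cheap enough for exhaustive checks."""
    return make_truth(50_000, 5, (100, 300), seed=3)


@pytest.fixture(scope="session")
def fixture_truth():
    """The canonical fixture: 200 kbp, 20 contigs, gaps 100-500 bp, a
    quarter of the contigs stored reverse-complemented."""
    return make_truth(200_000, 20, (100, 500), seed=7, flip_prob=0.25)


def _errorfree_reads(truth, seed=11):
    """190 junction-spanning reads plus 10 random ones: 200 total, 8 kbp."""
    reads = junction_spanning_reads(truth, 8000, 10, seed=seed)
    rng = np.random.default_rng(seed * 100 + 1)
    starts = rng.integers(0, len(truth.genome) - 8000, size=10)
    reads += [(f"read_extra_{i}", truth.genome[s:s + 8000]) for i, s in enumerate(starts)]
    return reads


@pytest.fixture(scope="session")
def errorfree_reads(fixture_truth):
    return LongReadSet.from_records(_errorfree_reads(fixture_truth))


@pytest.fixture(scope="session")
def errorfree_run(fixture_truth, errorfree_reads):
    return run_pipeline(fixture_truth, errorfree_reads)


@pytest.fixture(scope="session")
def noisy_reads(fixture_truth):
    """40 reads per junction corrupted with the early-chemistry preset."""
    return LongReadSet.from_records(
        junction_spanning_reads(fixture_truth, 8000, 40, seed=21, params=r7_preset())
    )


@pytest.fixture(scope="session")
def noisy_run(fixture_truth, noisy_reads):
    return run_pipeline(fixture_truth, noisy_reads)


def true_adjacencies(truth):
    return {frozenset((j.left_id, j.right_id)) for j in truth.junctions}


def scored_junctions(layouts, truth):
    """(recovered true junctions, false joins) over a set of layouts."""
    truth_adj = true_adjacencies(truth)
    merged, false_joins = set(), 0
    for lay in layouts:
        for left, right in zip(lay.entries, lay.entries[1:]):
            pair = frozenset((left.contig_id, right.contig_id))
            if pair in truth_adj:
                merged.add(pair)
            else:
                false_joins += 1
    return merged, false_joins
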