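"""Pair extraction windows, k-mer placement, distance logic, and links."""

import numpy as np
import pytest

from pairlink import (
    LongReadSet,
    build_bloom,
    build_exact_set,
    build_links,
    calc_gap,
    extract_pairs,
    make_truth,
    place_kmers,
    profile_kmer_support,
    within_tolerance,
)
from pairlink._kmer import encode_kmer, revcomp
from pairlink.io_formats import ContigRecord
from pairlink.pairing import KmerPairStore, PairObservations, candidate_windows
from pairlink.simulate import junction_spanning_reads, r7_preset, random_genome

from conftest import run_pipeline


def _brute_windows(L, d, t):
    return sum(1 for w in range(0, max(L, 1), t) if w + d <= L)


class TestCandidateWindows:
    @pytest.mark.parametrize("L,d,t,k", [
        (4000, 4000, 1, 15), (3999, 4000, 1, 15), (8000, 4000, 2, 15),
        (8001, 4000, 3, 15), (10000, 500, 7, 21), (505, 500, 200, 15),
        (12345, 6000, 11, 15),
    ])
    def test_matches_brute_force_enumeration(self, L, d, t, k):
        assert candidate_windows(L, d, t, k) == _brute_windows(L, d, t)

    def test_boundary_read_lengths(self):
        # a read one base shorter than the pair span contributes nothing
        assert candidate_windows(5999, 6000, 1, 15) == 0
        assert candidate_windows(6000, 6000, 1, 15) == 1

    def test_extraction_counts_windows(self, small_truth):
        filt = build_bloom(small_truth.contigs, 15, 0.001)
        reads = LongReadSet.from_records([("r1", small_truth.genome[:5000])])
        store = extract_pairs(reads, filt, 15, 3000, 4)
        assert store.windows_considered == _brute_windows(5000, 3000, 4)

    def test_parameter_guards(self, small_truth):
        filt = build_bloom(small_truth.contigs, 15, 0.001)
        reads = LongReadSet.from_records([])
        with pytest.raises(ValueError):
            extract_pairs(reads, filt, 15, 10, 1)  # d <= k
        with pytest.raises(ValueError):
            extract_pairs(reads, filt, 15, 4000, 0)  # t < 1
        with pytest.raises(ValueError):
            extract_pairs(reads, filt, 21, 4000, 2)  # k mismatch vs filter


class TestCalcGap:
    def test_direct_substitution(self):
        assert calc_gap(4000, 2000, 1000, 385, 15) == 2600

    def test_abutting_contigs(self):
        # footprint exactly d -> gap 0
        assert calc_gap(4000, 2000, 1000, 2985, 15) == 0

    def test_overlap_negative_and_rejected_at_default_deviation(self):
        # footprint 4400 at d=4000: a 400 bp overlap, outside |D-d| < 0.1*d
        D = (2000 - 600) + (2985 + 15)
        assert D == 4400
        assert calc_gap(4000, 2000, 600, 2985, 15) == -400
        assert not within_tolerance(D, 4000, 0.1)

    @pytest.mark.parametrize("D,ok", [(4400, False), (4399, True), (3601, True),
                                      (3600, False), (4000, True)])
    def test_tolerance_bounds_are_strict(self, D, ok):
        assert within_tolerance(D, 4000, 0.1) is ok


def _store_with(kmers, k=15, d=4000, t=1):
    store = KmerPairStore(k=k, d=d, t=t)
    for a, b in kmers:
        obs = store.pairs.setdefault((encode_kmer(a), encode_kmer(b)), PairObservations())
        obs.count += 1
    return store


class TestPlaceKmers:
    def test_forward_strand_single_occurrence(self):
        contig = ContigRecord(id="c1", seq="ACGTACGTACGTTTTTACGG")
        kmer = contig.seq[2:17]
        store = _store_with([(kmer, kmer)])
        placement = place_kmers([contig], 15, store)
        occ = placement.unique(encode_kmer(kmer))
        assert (occ.contig_id, occ.strand, occ.start) == ("c1", "+", 2)
        assert placement.multiplicity(encode_kmer(kmer)) == 1

    def test_reverse_strand_bookkeeping(self):
        contig = ContigRecord(id="c1", seq="ACGTACGTACGTTTTTACGG")
        kmer = revcomp(contig.seq[2:17])
        store = _store_with([(kmer, kmer)])
        placement = place_kmers([contig], 15, store)
        occ = placement.unique(encode_kmer(kmer))
        assert (occ.contig_id, occ.strand, occ.start) == ("c1", "-", 2)

    def test_multiplicity_two_across_contigs(self):
        seq = "ACGTACGTACGTTTTTACGG"
        kmer = seq[0:15]
        store = _store_with([(kmer, kmer)])
        placement = place_kmers(
            [ContigRecord(id="c1", seq=seq), ContigRecord(id="c2", seq=seq)], 15, store
        )
        assert placement.multiplicity(encode_kmer(kmer)) == 2
        assert placement.unique(encode_kmer(kmer)) is None

    def test_absent_kmer_absent_from_placement(self):
        store = _store_with([("A" * 15, "C" * 15)])
        placement = place_kmers([ContigRecord(id="c1", seq="ACGT" * 10)], 15, store)
        assert placement.occurrences == {}


class TestBuildLinks:
    def test_planted_two_contig_link(self):
        """Seven planted single-window reads -> one link, 7 observations,
        mean gap equal to the planted 10 bp (D = 3990 at d = 4000)."""
        truth = make_truth(20_000, 2, (10, 10), seed=5, min_contig_len=8000)
        junction = truth.junctions[0].genome_pos
        reads = [
            (f"r{i}", truth.genome[s:s + 4000])
            for i, s in enumerate(range(junction - 3500, junction - 100, 500))
        ]
        assert len(reads) == 7
        run = run_pipeline(
            truth, LongReadSet.from_records(reads), d=4000, t=4000, l=5, a=0.3
        )
        assert len(run.links) == 1
        link = run.links[0]
        assert link.count == 7
        assert link.mean_gap == 10
        assert link.gaps == [10] * 7  # every footprint D = 4000 - 10 = 3990

    def test_same_contig_pairs_rejected(self, small_truth):
        # reads entirely inside one contig produce only same-contig pairs
        lo, hi = small_truth.segments[0]
        reads = LongReadSet.from_records([("r1", small_truth.genome[lo:lo + 6000])])
        run = run_pipeline(small_truth, reads, d=3000)
        assert run.links == []
        assert run.log.rejected["same_contig"] > 0
        assert run.log.accepted == 0

    def test_conservation_closure(self, noisy_run):
        log, store = noisy_run.log, noisy_run.store
        assert log.total_placed + log.unplaced == store.observations_kept

    def test_mean_gap_rounds_half_away_from_zero(self):
        from pairlink.pairing import ContigLink

        assert ContigLink("a", "+", "b", "+", 2, [1, 2]).mean_gap == 2
        assert ContigLink("a", "+", "b", "+", 2, [-1, -2]).mean_gap == -2


class TestStrandSymmetry:
    def test_reverse_complemented_reads_give_same_links(self, small_truth):
        reads = junction_spanning_reads(small_truth, 6000, 8, seed=17)
        fwd = run_pipeline(small_truth, LongReadSet.from_records(reads), d=4000)
        rc = run_pipeline(
            small_truth,
            LongReadSet.from_records([(rid, revcomp(s)) for rid, s in reads]),
            d=4000,
        )
        key = lambda links: sorted((ln.key(), ln.count, sorted(ln.gaps)) for ln in links)
        assert key(fwd.links) == key(rc.links)


class TestProfileKmerSupport:
    def test_verbatim_reads_full_support(self, small_truth):
        filt = build_exact_set(small_truth.contigs, 15)
        lo, hi = small_truth.segments[1]
        reads = LongReadSet.from_records([("r1", small_truth.genome[lo:hi])])
        assert profile_kmer_support(reads, filt, 15) == 1.0

    def test_unrelated_reads_at_filter_fpr(self, small_truth):
        filt = build_bloom(small_truth.contigs, 15, 0.001)
        reads = LongReadSet.from_records(
            [("r1", random_genome(20_000, np.random.default_rng(123)))]
        )
        assert profile_kmer_support(reads, filt, 15) <= 0.002

    def test_noisy_reads_intermediate_and_decreasing_in_k(self, small_truth):
        params = r7_preset()
        reads = LongReadSet.from_records(
            junction_spanning_reads(small_truth, 6000, 4, seed=31, params=params)
        )
        fracs = []
        for k in (11, 15, 19):
            filt = build_bloom(small_truth.contigs, k, 1e-4)
            fracs.append(profile_kmer_support(reads, filt, k))
        assert 0.002 < fracs[1] < 1.0
        assert fracs[0] > fracs[1] > fracs[2]

    def test_no_data_condition(self, small_truth):
        filt = build_exact_set(small_truth.contigs, 15)
        reads = LongReadSet.from_records([("r1", "NNNNNNNNNNNNNNNNNN")])
        assert profile_kmer_support(reads, filt, 15) is None
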