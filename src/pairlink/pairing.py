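"""Paired spaced k-mers: extraction, placement, and contig linking.

The linking evidence is a pair of k-mers read from the same long sequence
with a fixed spacing d, measured from the 5' end of the first k-mer to
the 3' end of the second — the pair emulates a mate pair of insert
length d whose two k-length "reads" face inwards.  Extraction slides a
window of step t along each read and keeps a candidate pair only when
both k-mers are found in the assembly's membership filter.  Each kept
k-mer is then placed on the contigs (both strands); pairs whose two
members place uniquely, on different contigs, and whose calculated
footprint

    D = (L1 - p1) + (p2 + k)

is within the allowed deviation of d (|D - d| < e*d) become one oriented
link observation.  The gap (positive) or overlap (negative) implied by an
accepted pair is d - D, which is exact integer arithmetic: with error-free
sequences it recovers planted gaps exactly.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from ._kmer import kmer_codes, revcomp, seq_to_codes
from .io_formats import ContigRecord

Orient = str  # '+' or '-'


def flip(orient: Orient) -> Orient:
    return "-" if orient == "+" else "+"


@dataclass
class PairObservations:
    """All observations of one ordered k-mer pair across the read set."""

    count: int = 0
    offsets: List[Tuple[str, int]] = field(default_factory=list)  # (read id, window start)


@dataclass
class KmerPairStore:
    """Unique k-mer pairs harvested from long reads at one spacing d."""

    k: int
    d: int
    t: int
    pairs: Dict[Tuple[int, int], PairObservations] = field(default_factory=dict)
    windows_considered: int = 0
    observations_kept: int = 0

    def member_codes(self) -> np.ndarray:
        """Sorted unique codes occurring as either member of any pair."""
        if not self.pairs:
            return np.empty(0, dtype=np.uint64)
        flat = np.fromiter(
            (v for ab in self.pairs for v in ab), dtype=np.uint64, count=2 * len(self.pairs)
        )
        return np.unique(flat)


def candidate_windows(read_len: int, d: int, t: int, k: int) -> int:
    """Number of window starts {0, t, 2t, ...} with w + d <= read_len."""
    span = read_len - d
    return 0 if span < 0 else span // t + 1


def extract_pairs(reads, filt, k: int, d: int, t: int) -> KmerPairStore:
    """Harvest spaced k-mer pairs from every read, screened by *filt*.

    A window at start w contributes the pair
    ``(read[w:w+k], read[w+d-k:w+d])`` — total span exactly d bases —
    iff both k-mers are ACGT-only and both query true in the membership
    backend; observations accumulate across reads.
    """
    if k < 4:
        raise ValueError(f"k must be >= 4, got {k}")
    if d <= k:
        raise ValueError(f"spacing d={d} must exceed k={k}")
    if t < 1:
        raise ValueError(f"window step t must be >= 1, got {t}")
    if getattr(filt, "k", k) != k:
        raise ValueError(f"membership backend built at k={filt.k}, run requires k={k}")
    store = KmerPairStore(k=k, d=d, t=t)
    for read_id, seq in reads:
        L = len(seq)
        nwin = candidate_windows(L, d, t, k)
        store.windows_considered += nwin
        if nwin == 0:
            continue
        vals, valid = kmer_codes(seq_to_codes(seq), k)
        ws = np.arange(0, L - d + 1, t)
        ok = valid[ws] & valid[ws + d - k]
        ws = ws[ok]
        if ws.size == 0:
            continue
        a = vals[ws]
        b = vals[ws + d - k]
        keep = filt.query_codes(a) & filt.query_codes(b)
        for w, av, bv in zip(ws[keep], a[keep], b[keep]):
            obs = store.pairs.setdefault((int(av), int(bv)), PairObservations())
            obs.count += 1
            obs.offsets.append((read_id, int(w)))
            store.observations_kept += 1
    return store


@dataclass(frozen=True)
class Occurrence:
    contig_id: str
    strand: Orient  # '+' if the k-mer matches the forward strand
    start: int  # 0-based on the contig's stored (forward) coordinates


@dataclass
class KmerPlacement:
    """Where each pair-store k-mer occurs on the contigs (both strands)."""

    k: int
    occurrences: Dict[int, List[Occurrence]] = field(default_factory=dict)

    def multiplicity(self, code: int) -> int:
        return len(self.occurrences.get(code, ()))

    def unique(self, code: int) -> Occurrence | None:
        occ = self.occurrences.get(code)
        return occ[0] if occ is not None and len(occ) == 1 else None


def place_kmers(contigs: Sequence[ContigRecord], k: int, store: KmerPairStore) -> KmerPlacement:
    """Shred contigs at the same k, keeping only pair-store k-mers.

    A k-mer matching the reverse strand at forward coordinate i is
    recorded with strand '-' and start i; multiplicity counts every
    occurrence across all contigs and both strands.
    """
    if store.k != k:
        raise ValueError(f"pair store built at k={store.k}, placement requires k={k}")
    needed = store.member_codes()
    placement = KmerPlacement(k=k)
    if needed.size == 0:
        return placement
    for rec in contigs:
        L = rec.length
        fvals, fvalid = kmer_codes(seq_to_codes(rec.seq), k)
        if fvals.size == 0:
            continue
        hit = fvalid & np.isin(fvals, needed)
        for i in np.nonzero(hit)[0]:
            placement.occurrences.setdefault(int(fvals[i]), []).append(
                Occurrence(rec.id, "+", int(i))
            )
        # reverse strand: the j-th k-mer of revcomp(seq) sits at forward
        # coordinate L - k - j
        rvals, rvalid = kmer_codes(seq_to_codes(revcomp(rec.seq)), k)
        rhit = rvalid & np.isin(rvals, needed)
        for j in np.nonzero(rhit)[0]:
            placement.occurrences.setdefault(int(rvals[j]), []).append(
                Occurrence(rec.id, "-", int(L - k - j))
            )
    return placement


def calc_gap(d: int, L1: int, p1: int, p2: int, k: int) -> int:
    """Gap (positive) or overlap (negative) implied by one accepted pair:
    d - ((L1 - p1) + (p2 + k)), exact integer arithmetic."""
    return d - ((L1 - p1) + (p2 + k))


def within_tolerance(D: int, d: int, e: float) -> bool:
    """Distance test for a calculated footprint D: |D - d| < e*d, strict.

    Strict bounds: at d=4000, e=0.1 the accepted half-width is 400 bp and
    a footprint of exactly 4400 bp (a 400 bp implied overlap) is rejected.
    """
    return abs(D - d) < e * d


def _round_half_away(x: float) -> int:
    import math

    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass
class ContigLink:
    """Directed, oriented linking evidence between two contig extremities."""

    contig1: str
    orient1: Orient
    contig2: str
    orient2: Orient
    count: int = 0
    gaps: List[int] = field(default_factory=list)

    @property
    def mean_gap(self) -> int:
        return _round_half_away(sum(self.gaps) / len(self.gaps))

    def key(self) -> Tuple[str, Orient, str, Orient]:
        return (self.contig1, self.orient1, self.contig2, self.orient2)


REJECT_REASONS = ("same_contig", "non_unique", "out_of_tolerance", "orientation_conflict")


@dataclass
class PairingIssueLog:
    """Tally of accepted vs rejected pair observations, by reason.

    Conservation: over observations whose two k-mers both occur on the
    contigs, accepted + same_contig + non_unique + out_of_tolerance +
    orientation_conflict equals the total.  Observations with an unplaced
    member are counted separately in ``unplaced``.
    """

    accepted: int = 0
    rejected: Counter = field(default_factory=Counter)
    unplaced: int = 0
    records: List[tuple] = field(default_factory=list)  # (reason, c1, c2, D, d)
    distance_counts: Counter = field(default_factory=Counter)

    @property
    def total_placed(self) -> int:
        return self.accepted + sum(self.rejected.values())


def _canonical(c1, o1, p1, L1, c2, o2, p2, L2):
    """Fold the two equivalent directed forms onto one deterministic key.

    (c1,o1)->(c2,o2) read left-to-right equals (c2,flip o2)->(c1,flip o1)
    read the other way; the footprint D is invariant under the flip.
    """
    fwd = (c1, o1, c2, o2)
    rev = (c2, flip(o2), c1, flip(o1))
    return fwd if fwd <= rev else rev


def build_links(
    store: KmerPairStore,
    placement: KmerPlacement,
    contigs: Sequence[ContigRecord],
    d: int,
    e: float,
) -> tuple[list[ContigLink], PairingIssueLog]:
    """Turn pair observations into distance-validated oriented links.

    Each observation is accepted iff both k-mers place uniquely, on
    different contigs, with footprint D within tolerance of d.  The four
    strand combinations of the two placements map onto the link
    orientations; a k-mer on the reverse strand contributes its position
    re-expressed in the link's reading direction, p = L - (start + k).
    If one unordered contig pair accumulates links in more than one
    orientation combination, only the best-supported combination is kept
    and the rest are reclassified as orientation conflicts.
    """
    lengths = {rec.id: rec.length for rec in contigs}
    log = PairingIssueLog()
    by_key: Dict[tuple, ContigLink] = {}
    for (av, bv), obs in store.pairs.items():
        occ_a = placement.occurrences.get(av)
        occ_b = placement.occurrences.get(bv)
        if not occ_a or not occ_b:
            log.unplaced += obs.count
            continue
        if len(occ_a) > 1 or len(occ_b) > 1:
            log.rejected["non_unique"] += obs.count
            continue
        a, b = occ_a[0], occ_b[0]
        if a.contig_id == b.contig_id:
            log.rejected["same_contig"] += obs.count
            log.records.append(("same_contig", a.contig_id, b.contig_id, None, d))
            continue
        L1, L2 = lengths[a.contig_id], lengths[b.contig_id]
        k = store.k
        o1, p1 = (a.strand, a.start) if a.strand == "+" else ("-", L1 - (a.start + k))
        o2, p2 = (b.strand, b.start) if b.strand == "+" else ("-", L2 - (b.start + k))
        D = (L1 - p1) + (p2 + k)
        if not within_tolerance(D, d, e):
            log.rejected["out_of_tolerance"] += obs.count
            log.records.append(("out_of_tolerance", a.contig_id, b.contig_id, D, d))
            continue
        gap = d - D
        key = _canonical(a.contig_id, o1, p1, L1, b.contig_id, o2, p2, L2)
        link = by_key.setdefault(key, ContigLink(*key))
        link.count += obs.count
        link.gaps.extend([gap] * obs.count)
        log.distance_counts[D] += obs.count

    # Keep one orientation combination per unordered contig pair.
    by_pair: Dict[frozenset, List[ContigLink]] = defaultdict(list)
    for link in by_key.values():
        by_pair[frozenset((link.contig1, link.contig2))].append(link)
    links: list[ContigLink] = []
    for group in by_pair.values():
        group.sort(key=lambda ln: (-ln.count, ln.key()))
        winner = group[0]
        links.append(winner)
        log.accepted += winner.count
        for loser in group[1:]:
            log.rejected["orientation_conflict"] += loser.count
            log.records.append(
                ("orientation_conflict", loser.contig1, loser.contig2, None, d)
            )
            for D_lost in (d - g for g in loser.gaps):
                log.distance_counts[D_lost] -= 1
                if log.distance_counts[D_lost] <= 0:
                    del log.distance_counts[D_lost]
    links.sort(key=lambda ln: ln.key())
    return links, log


def profile_kmer_support(reads, filt, k: int) -> float | None:
    """Fraction of read k-mers present in the membership filter.

    A diagnostic for choosing k: verbatim substrings of the contigs score
    1.0, unrelated random sequence scores ~ the filter's FPR, and
    error-containing reads land in between, decreasing with k.  Returns
    None when the reads contribute no ACGT-only k-mer (no data).
    """
    total = 0
    matching = 0
    for _read_id, seq in reads:
        vals, valid = kmer_codes(seq_to_codes(seq), k)
        vals = vals[valid]
        total += int(vals.size)
        if vals.size:
            matching += int(filt.query_codes(vals).sum())
    if total == 0:
        return None
    return matching / total
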