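"""Greedy, ratio-guarded scaffold construction from contig links.

Contigs are taken as seeds in descending length (input order breaks
ties) and extended greedily from both extremities.  A merge happens
only when the best-supported neighbour carries at least l links and any
alternate neighbour carries at most a fraction *a* of that support —
the ambiguity guard that keeps repeat-induced competing linkages from
producing chimeric scaffolds.  Every contig ends up in exactly one
scaffold; contigs with no usable links become singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

from .io_formats import ContigRecord
from .pairing import ContigLink, Orient, flip
from ._kmer import revcomp


@dataclass(frozen=True)
class LayoutEntry:
    contig_id: str
    orient: Orient
    gap_to_next: Optional[int]  # None for the last contig of the scaffold


@dataclass
class ScaffoldLayout:
    """Ordered, oriented contigs with estimated gaps between neighbours."""

    scaffold_id: str
    entries: List[LayoutEntry] = field(default_factory=list)

    @property
    def contig_ids(self) -> List[str]:
        return [e.contig_id for e in self.entries]

    def span(self, contig_by_id: Mapping[str, ContigRecord]) -> int:
        total = 0
        for e in self.entries:
            total += contig_by_id[e.contig_id].length
            if e.gap_to_next is not None:
                total += e.gap_to_next if e.gap_to_next >= 1 else 1
        return total


def select_neighbor(
    candidates: Mapping[Hashable, int], l: int, a: float
) -> Optional[Hashable]:
    """Pick the dominant neighbour, or none when support is weak/ambiguous.

    Merge criterion: the best candidate must carry >= l links and the
    runner-up at most a*best links.  A tie for best is inherently
    ambiguous and yields none.
    """
    if not candidates:
        return None
    ranked = sorted(candidates.items(), key=lambda kv: -kv[1])
    best_key, best_n = ranked[0]
    if best_n < l:
        return None
    if len(ranked) > 1:
        second_n = ranked[1][1]
        if second_n == best_n:
            return None
        if second_n / best_n > a:
            return None
    return best_key


def _adjacency(
    links: Sequence[ContigLink],
) -> Dict[Tuple[str, Orient], Dict[Tuple[str, Orient], Tuple[int, int]]]:
    """Index links by the extremity they leave: (contig, orient) ->
    {(neighbour, orient): (link count, mean gap)} for both directions."""
    adj: Dict[Tuple[str, Orient], Dict[Tuple[str, Orient], Tuple[int, int]]] = {}
    for ln in links:
        fwd_from, fwd_to = (ln.contig1, ln.orient1), (ln.contig2, ln.orient2)
        rev_from, rev_to = (ln.contig2, flip(ln.orient2)), (ln.contig1, flip(ln.orient1))
        payload = (ln.count, ln.mean_gap)
        adj.setdefault(fwd_from, {})[fwd_to] = payload
        adj.setdefault(rev_from, {})[rev_to] = payload
    return adj


def build_scaffolds(
    links: Sequence[ContigLink],
    contigs: Sequence[ContigRecord],
    l: int,
    a: float,
) -> List[ScaffoldLayout]:
    """Lay every contig into exactly one scaffold.

    Extension proceeds rightward from the seed's forward orientation,
    then leftward (by extending the reverse-oriented seed and flipping
    the result); a chosen neighbour already consumed by any scaffold
    stops the walk, so no contig is ever reused and cycles terminate.
    """
    if l < 1:
        raise ValueError(f"minimum links l must be >= 1, got {l}")
    if not 0.0 < a <= 1.0:
        raise ValueError(f"max link ratio a must be in (0, 1], got {a}")
    adj = _adjacency(links)
    order = sorted(range(len(contigs)), key=lambda i: (-contigs[i].length, i))
    used: set[str] = set()
    layouts: List[ScaffoldLayout] = []

    def walk(start: Tuple[str, Orient]) -> List[Tuple[str, Orient, int]]:
        chain: List[Tuple[str, Orient, int]] = []
        cur = start
        while True:
            cands = adj.get(cur, {})
            choice = select_neighbor({kk: cn for kk, (cn, _g) in cands.items()}, l, a)
            if choice is None or choice[0] in used:
                return chain
            _count, gap = cands[choice]
            chain.append((choice[0], choice[1], gap))
            used.add(choice[0])
            cur = choice

    for idx in order:
        seed = contigs[idx]
        if seed.id in used:
            continue
        used.add(seed.id)
        right = walk((seed.id, "+"))
        left = walk((seed.id, "-"))
        entries: List[LayoutEntry] = []
        # left chain was walked outward from the seed's reverse; reading the
        # scaffold left-to-right reverses the order and flips orientations,
        # and each walked gap sits between the entry and its right neighbour.
        for cid, orient, gap in reversed(left):
            entries.append(LayoutEntry(cid, flip(orient), gap))
        tail = [(seed.id, "+", None)] + [(c, o, None) for c, o, _ in right]
        gaps_right = [g for _c, _o, g in right] + [None]
        for (cid, orient, _), gap in zip(tail, gaps_right):
            entries.append(LayoutEntry(cid, orient, gap))
        layouts.append(ScaffoldLayout(scaffold_id=f"scaffold{len(layouts) + 1}", entries=entries))
    return layouts


def emit_sequences(
    layouts: Sequence[ScaffoldLayout], contigs: Sequence[ContigRecord]
) -> List[Tuple[str, str]]:
    """(scaffold id, sequence) per layout: oriented contigs joined by the
    gap encoding (g N's for g >= 1, a single 'n' for overlap/abutment)."""
    from .io_formats import layout_sequence

    contig_by_id = {c.id: c for c in contigs}
    return [(lay.scaffold_id, layout_sequence(lay, contig_by_id)) for lay in layouts]
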