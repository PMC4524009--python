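"""Bloom-filter membership over the draft assembly's k-mers.

The draft's contigs are shredded to k-mers on both strands and inserted
into a Bloom filter sized from the exact k-mer count and a requested
false-positive rate p.  Long-read k-mers are then screened against the
filter before any pairing work, so the pair store only ever holds k-mers
that (probably) occur in the assembly.  The filter guarantees no false
negatives; false positives occur at a measured rate bounded by ~2p and
are weeded out later by the uniqueness/placement checks.

An exact-set backend with the same query contract is provided for small
runs and as an oracle in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._kmer import MAX_K, encode_kmer, hash_pair, kmer_codes, revcomp, seq_to_codes

_MAGIC = b"PAIRLINKBLOOM1\n"


class BloomFormatError(ValueError):
    """Raised when a serialized filter file is corrupt or mismatched."""


def optimal_size(n_expected: int, target_fpr: float) -> tuple[int, int]:
    """Standard optimal (m bits, h hashes) for n expected keys at FPR p."""
    n = max(1, n_expected)
    m = math.ceil(-n * math.log(target_fpr) / (math.log(2) ** 2))
    h = max(1, round(m / n * math.log(2)))
    return m, h


@dataclass
class BloomFilter:
    """Bit-array membership filter queried with packed k-mer codes."""

    m: int
    num_hashes: int
    k: int
    target_fpr: float
    n_inserted: int = 0
    bits: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.bits is None:
            self.bits = np.zeros(self.m, dtype=bool)

    @classmethod
    def sized_for(cls, n_expected: int, target_fpr: float, k: int) -> "BloomFilter":
        if not 0.0 < target_fpr < 0.5:
            raise ValueError(f"target FPR must be in (0, 0.5), got {target_fpr}")
        m, h = optimal_size(n_expected, target_fpr)
        return cls(m=m, num_hashes=h, k=k, target_fpr=target_fpr)

    def _indices(self, vals: np.ndarray) -> Iterable[np.ndarray]:
        h1, h2 = hash_pair(vals)
        m = np.uint64(self.m)
        for i in range(self.num_hashes):
            yield ((h1 + np.uint64(i) * h2) % m).astype(np.intp)

    def insert_codes(self, vals: np.ndarray) -> None:
        vals = np.asarray(vals, dtype=np.uint64)
        for idx in self._indices(vals):
            self.bits[idx] = True
        self.n_inserted += int(vals.size)

    def query_codes(self, vals: np.ndarray) -> np.ndarray:
        vals = np.asarray(vals, dtype=np.uint64)
        hit = np.ones(vals.size, dtype=bool)
        for idx in self._indices(vals):
            hit &= self.bits[idx]
        return hit

    def __contains__(self, kmer: str) -> bool:
        return query(self, kmer)

    def save(self, path) -> None:
        save_bloom(self, path)


@dataclass
class ExactKmerSet:
    """Exact-set backend with the Bloom query contract (zero FPR).

    Stands behind the same interface so the pairing stage is agnostic to
    which membership structure screens its k-mers; used when the Bloom
    filter is switched off and as the oracle in equivalence tests.
    """

    k: int
    target_fpr: float = 0.0
    n_inserted: int = 0
    _keys: set = field(default_factory=set, repr=False)

    def insert_codes(self, vals: np.ndarray) -> None:
        self._keys.update(int(v) for v in np.asarray(vals, dtype=np.uint64))
        self.n_inserted += int(np.asarray(vals).size)

    def query_codes(self, vals: np.ndarray) -> np.ndarray:
        return np.fromiter(
            (int(v) in self._keys for v in np.asarray(vals, dtype=np.uint64)),
            dtype=bool,
            count=int(np.asarray(vals).size),
        )

    def __contains__(self, kmer: str) -> bool:
        return query(self, kmer)


def _shred_into(backend, contigs: Sequence) -> None:
    for rec in contigs:
        for seq in (rec.seq, revcomp(rec.seq)):
            vals, valid = kmer_codes(seq_to_codes(seq.upper()), backend.k)
            backend.insert_codes(vals[valid])


def build_bloom(contigs: Sequence, k: int, p: float) -> BloomFilter:
    """Shred every contig to k-mers on both strands into a sized filter.

    Sizing uses the exact expected count 2 * sum(max(0, len - k + 1)); an
    assembly with no contig of length >= k cannot be indexed.
    """
    if k < 4 or k > MAX_K:
        raise ValueError(f"k must be in [4, {MAX_K}], got {k}")
    n_expected = 2 * sum(max(0, rec.length - k + 1) for rec in contigs)
    if n_expected == 0:
        raise ValueError("no k-mers to index: no contig reaches length k")
    filt = BloomFilter.sized_for(n_expected, p, k)
    _shred_into(filt, contigs)
    return filt


def build_exact_set(contigs: Sequence, k: int) -> ExactKmerSet:
    """Exact-membership analogue of :func:`build_bloom`."""
    if k < 4 or k > MAX_K:
        raise ValueError(f"k must be in [4, {MAX_K}], got {k}")
    if not any(rec.length >= k for rec in contigs):
        raise ValueError("no k-mers to index: no contig reaches length k")
    backend = ExactKmerSet(k=k)
    _shred_into(backend, contigs)
    return backend


def query(backend, kmer: str) -> bool:
    """Membership of one k-mer string (must be ACGT of the backend's k)."""
    if len(kmer) != backend.k:
        raise ValueError(
            f"query length {len(kmer)} does not match filter k={backend.k}"
        )
    val = encode_kmer(kmer)
    return bool(backend.query_codes(np.array([val], dtype=np.uint64))[0])


def save_bloom(filt: BloomFilter, path) -> None:
    """Serialize to a small binary sidecar: magic, JSON header, packed bits."""
    header = json.dumps(
        {
            "m": filt.m,
            "num_hashes": filt.num_hashes,
            "k": filt.k,
            "target_fpr": filt.target_fpr,
            "n_inserted": filt.n_inserted,
        }
    ).encode("ascii")
    packed = np.packbits(filt.bits)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(header).to_bytes(8, "little"))
        fh.write(header)
        fh.write(packed.tobytes())


def load_bloom(path, expect_k: int | None = None) -> BloomFilter:
    """Load a serialized filter; optionally enforce the run's k up front."""
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise BloomFormatError(f"{path}: not a pairlink Bloom filter")
        try:
            hlen = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(hlen))
            m = int(header["m"])
            filt = BloomFilter(
                m=m,
                num_hashes=int(header["num_hashes"]),
                k=int(header["k"]),
                target_fpr=float(header["target_fpr"]),
                n_inserted=int(header["n_inserted"]),
                bits=np.unpackbits(
                    np.frombuffer(fh.read(), dtype=np.uint8), count=m
                ).astype(bool),
            )
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise BloomFormatError(f"{path}: corrupt Bloom filter header") from exc
    if expect_k is not None and filt.k != expect_k:
        raise BloomFormatError(
            f"{path}: filter was built at k={filt.k}, run requires k={expect_k}"
        )
    return filt
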