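"""Low-level k-mer machinery: 2-bit packing and deterministic 64-bit hashing.

k-mers over {A,C,G,T} are packed into ``uint64`` codes (A=0, C=1, G=2, T=3,
most-significant base first), which caps k at 32 — comfortably above the
k = 15..26 range useful for linking with error-containing long reads.
Positions holding any other symbol (N, IUPAC codes, ...) invalidate every
window that covers them; callers mask those windows out.
"""

from __future__ import annotations

import numpy as np

MAX_K = 32

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_CODE_BASE = "ACGT"

# splitmix64 constants; two fixed stream seeds give the double-hash pair.
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)
_SEED_A = np.uint64(0x243F6A8885A308D3)
_SEED_B = np.uint64(0x13198A2E03707344)


def seq_to_codes(seq: str) -> np.ndarray:
    """Per-base codes for *seq* (uint8; 255 marks a non-ACGT symbol)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed codes and validity for every k-window of a base-code array.

    Returns ``(vals, valid)`` of length ``len(codes) - k + 1``; ``vals[i]``
    is meaningful only where ``valid[i]`` (no non-ACGT base in the window).
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bad = np.concatenate(([0], np.cumsum(codes == 255)))
    valid = (bad[k:] - bad[:-k]) == 0
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    vals = np.empty(n, dtype=np.uint64)
    step = 1 << 20
    for lo in range(0, n, step):
        hi = min(lo + step, n)
        chunk = win[lo:hi].astype(np.uint64)
        np.einsum("ij,j->i", chunk, powers, out=vals[lo:hi])
    return vals, valid


def encode_kmer(kmer: str) -> int:
    """Pack one ACGT string into its integer code; raises on other symbols."""
    codes = seq_to_codes(kmer.upper())
    if codes.size > MAX_K:
        raise ValueError(f"k-mer longer than {MAX_K}")
    if (codes == 255).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT symbols")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def decode_kmer(val: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_CODE_BASE[(val >> shift) & 3])
    return "".join(out)


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _splitmix(x: np.ndarray) -> np.ndarray:
    z = (x + _GOLDEN).astype(np.uint64)
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


def hash_pair(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two independent 64-bit hashes per code, for double hashing.

    The second hash is forced odd so that, combined with a power-free
    modulus, the probe sequence h1 + i*h2 cannot collapse.
    """
    vals = np.asarray(vals, dtype=np.uint64)
    h1 = _splitmix(vals ^ _SEED_A)
    h2 = _splitmix(vals ^ _SEED_B) | np.uint64(1)
    return h1, h2
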