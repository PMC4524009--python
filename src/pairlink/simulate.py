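"""Parametric long-read error model, read simulator, and mixture fitting.

Nanopore-style base-calling errors are bursty: stretches of correct
bases (13-15 bp on average in early-chemistry 2D data) alternate with
short runs of mismatches, insertions or deletions.  Run lengths follow
two-component mixtures:

    mismatch run  ~ a_m * Poisson(lam_m)          + (1 - a_m) * Geometric(p_m)
    insertion run ~ a_i * Weibull(lam_i, kappa_i) + (1 - a_i) * Geometric(p_i)
    deletion run  ~ a_d * Weibull(lam_d, kappa_d) + (1 - a_d) * Geometric(p_d)

with mixture weights a_x in (0, 1), Poisson mean lam_m, Weibull scale
lam and shape kappa, and geometric Bernoulli probabilities p_x.  The
structured component reflects systematic base-caller failure modes; the
geometric component captures by-chance matches.  Mismatch run lengths
are tallied zero-indexed, indel run lengths one-indexed (interarrival
convention); Weibull draws are rounded to the nearest integer with a
floor of 1.

This module provides forward sampling (``sample_run_lengths``,
``simulate_read``), maximum-likelihood fitting with a Kolmogorov-Smirnov
goodness-of-fit check (``fit_mixture``), and synthetic genome/contig
fixtures with known junction truth (``make_truth``) so the scaffolder is
fully testable without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from ._kmer import revcomp
from .io_formats import ContigRecord

ErrorKind = Literal["mismatch", "insertion", "deletion"]
KINDS: Tuple[ErrorKind, ...] = ("mismatch", "insertion", "deletion")

_BASES = "ACGT"


@dataclass(frozen=True)
class MismatchMixture:
    """Zero-indexed mismatch run lengths: a*Poisson(lam) + (1-a)*Geom0(p)."""

    a: float
    lam: float
    p: float

    def validate(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"mixture weight a={self.a} outside [0, 1]")
        if self.lam <= 0:
            raise ValueError(f"Poisson mean must be > 0, got {self.lam}")
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"geometric p={self.p} outside (0, 1)")

    @property
    def mean(self) -> float:
        return self.a * self.lam + (1.0 - self.a) * (1.0 - self.p) / self.p


@dataclass(frozen=True)
class IndelMixture:
    """One-indexed indel run lengths: a*round(Weibull(scale, shape)) +
    (1-a)*Geom1(p), with the Weibull draw floored at 1."""

    a: float
    scale: float
    shape: float
    p: float

    def validate(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"mixture weight a={self.a} outside [0, 1]")
        if self.scale <= 0 or self.shape <= 0:
            raise ValueError(
                f"Weibull scale/shape must be > 0, got {self.scale}/{self.shape}"
            )
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"geometric p={self.p} outside (0, 1)")


# Substitution profile: row = true base (A,C,G,T), column = called base.
# Encodes the qualitative trend of early nanopore chemistries: A and T are
# more stable than C and G, and wrong calls skew toward C and G.
DEFAULT_SUBSTITUTION = np.array(
    [
        [0.00, 0.40, 0.40, 0.20],  # A ->
        [0.20, 0.00, 0.50, 0.30],  # C ->
        [0.30, 0.50, 0.00, 0.20],  # G ->
        [0.20, 0.40, 0.40, 0.00],  # T ->
    ]
)


@dataclass(frozen=True)
class ErrorModelParams:
    """Full read-corruption model: per-kind run-length mixtures, the
    relative frequency of each error kind, the mean correct-stretch
    length between error events, and the substitution profile."""

    mismatch: MismatchMixture
    insertion: IndelMixture
    deletion: IndelMixture
    type_weights: Tuple[float, float, float] = (0.4, 0.3, 0.3)
    stretch_mean: float = 14.0
    substitution: np.ndarray = field(default_factory=lambda: DEFAULT_SUBSTITUTION.copy())

    def validate(self) -> None:
        self.mismatch.validate()
        self.insertion.validate()
        self.deletion.validate()
        w = np.asarray(self.type_weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
            raise ValueError(f"type_weights must be 3 nonnegative values summing to 1, got {self.type_weights}")
        if self.stretch_mean < 1.0:
            raise ValueError(f"stretch_mean must be >= 1, got {self.stretch_mean}")
        s = np.asarray(self.substitution, dtype=float)
        if s.shape != (4, 4) or (np.diag(s) != 0).any():
            raise ValueError("substitution profile must be 4x4 with zero diagonal")
        if not np.allclose(s.sum(axis=1), 1.0):
            raise ValueError("substitution profile rows must sum to 1")


def r7_preset() -> ErrorModelParams:
    """Early-chemistry 2D preset, calibrated so simulated reads land at
    ~77 % mean identity with correct stretches of mean 14 bp.  Balanced
    insertion/deletion weights keep read-to-genome coordinate drift
    unbiased.  Calibrated, not transcribed from any fitted table."""
    return ErrorModelParams(
        mismatch=MismatchMixture(a=0.55, lam=3.5, p=0.30),
        insertion=IndelMixture(a=0.5, scale=4.6, shape=1.3, p=0.28),
        deletion=IndelMixture(a=0.5, scale=4.6, shape=1.3, p=0.28),
        type_weights=(0.44, 0.28, 0.28),
        stretch_mean=14.0,
    )


def error_free_preset() -> ErrorModelParams:
    """Degenerate model with no error events (infinite correct stretch);
    simulated reads are verbatim genome slices."""
    return replace(r7_preset(), stretch_mean=math.inf)


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_run_lengths(
    params: ErrorModelParams, kind: ErrorKind, n: int, seed
) -> np.ndarray:
    """Draw n run lengths in the tally convention of *kind*.

    Mismatch draws are zero-indexed (support {0, 1, ...}); indel draws
    are one-indexed (support {1, 2, ...}).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    params.validate()
    rng = _as_rng(seed)
    if kind == "mismatch":
        mm = params.mismatch
        structured = rng.poisson(mm.lam, size=n)
        chance = rng.geometric(mm.p, size=n) - 1
        a = mm.a
    elif kind in ("insertion", "deletion"):
        ind: IndelMixture = getattr(params, kind)
        structured = np.maximum(1, np.rint(ind.scale * rng.weibull(ind.shape, size=n))).astype(int)
        chance = rng.geometric(ind.p, size=n)
        a = ind.a
    else:
        raise ValueError(f"unknown error kind {kind!r}")
    pick = rng.random(n) < a
    return np.where(pick, structured, chance)


def _one_run(params: ErrorModelParams, kind: ErrorKind, rng) -> int:
    """Scalar run-length draw in actual bases (mismatch de-zero-indexed);
    skips re-validation, for the simulator's inner loop."""
    if kind == "mismatch":
        mm = params.mismatch
        if rng.random() < mm.a:
            return int(rng.poisson(mm.lam)) + 1
        return int(rng.geometric(mm.p))  # (geom - 1) zero-indexed, + 1
    ind: IndelMixture = getattr(params, kind)
    if rng.random() < ind.a:
        return max(1, int(round(ind.scale * float(rng.weibull(ind.shape)))))
    return int(rng.geometric(ind.p))


@dataclass
class SimulatedRead:
    """A corrupted read plus the genome interval it consumed and the true
    alignment tallies (identity = matches / alignment columns)."""

    seq: str
    start: int
    end: int
    n_match: int = 0
    n_mismatch: int = 0
    n_ins: int = 0
    n_del: int = 0

    @property
    def footprint(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def identity(self) -> float:
        cols = self.n_match + self.n_mismatch + self.n_ins + self.n_del
        return self.n_match / cols if cols else 1.0


def simulate_read(
    genome: str, start: int, span: int, params: ErrorModelParams, seed
) -> SimulatedRead:
    """Corrupt genome[start:start+span] with bursty errors.

    Correct stretches of geometric length (mean ``params.stretch_mean``)
    alternate with error events; each event's kind is drawn from
    ``type_weights`` and its run length from the kind's mixture.
    Mismatches substitute via the profile, insertions add uniform bases
    without consuming genome, deletions skip genome bases.  With all
    error processes disabled the read is the verbatim template.
    """
    if start < 0 or start + span > len(genome):
        raise ValueError(
            f"window [{start}, {start + span}) outside genome of length {len(genome)}"
        )
    params.validate()
    rng = _as_rng(seed)
    limit = start + span
    pos = start
    out: List[str] = []
    read = SimulatedRead(seq="", start=start, end=start)
    sub_cum = np.cumsum(np.asarray(params.substitution, dtype=float), axis=1)
    w_cum = np.cumsum(np.asarray(params.type_weights, dtype=float))
    p_stretch = 1.0 / params.stretch_mean if math.isfinite(params.stretch_mean) else 0.0
    base_idx = {b: i for i, b in enumerate(_BASES)}
    while pos < limit:
        stretch = limit - pos if p_stretch == 0.0 else min(int(rng.geometric(p_stretch)), limit - pos)
        out.append(genome[pos : pos + stretch])
        read.n_match += stretch
        pos += stretch
        if pos >= limit:
            break
        kind = KINDS[int(np.searchsorted(w_cum, rng.random()))]
        run = _one_run(params, kind, rng)
        if kind == "mismatch":
            run = min(run, limit - pos)
            for _ in range(run):
                row = base_idx.get(genome[pos], None)
                if row is None:  # non-ACGT template base passes through
                    out.append(genome[pos])
                else:
                    out.append(_BASES[int(np.searchsorted(sub_cum[row], rng.random()))])
                read.n_mismatch += 1
                pos += 1
        elif kind == "insertion":
            out.append("".join(_BASES[i] for i in rng.integers(0, 4, size=run)))
            read.n_ins += run
        else:  # deletion
            run = min(run, limit - pos)
            read.n_del += run
            pos += run
    read.seq = "".join(out)
    read.end = pos
    return read


# ---------------------------------------------------------------------------
# Fragment tallies and maximum-likelihood mixture fitting
# ---------------------------------------------------------------------------


@dataclass
class FragmentTally:
    """Histogram of run lengths for one error kind.

    ``zero_indexed`` records the storage convention: mismatch runs are
    zero-indexed, indel runs one-indexed.
    """

    kind: ErrorKind
    counts: Dict[int, int]
    zero_indexed: bool

    @classmethod
    def from_samples(cls, kind: ErrorKind, samples: Sequence[int]) -> "FragmentTally":
        vals, cnts = np.unique(np.asarray(samples, dtype=int), return_counts=True)
        return cls(
            kind=kind,
            counts={int(v): int(c) for v, c in zip(vals, cnts)},
            zero_indexed=(kind == "mismatch"),
        )

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def expand(self) -> np.ndarray:
        return np.repeat(
            np.fromiter(self.counts.keys(), dtype=int),
            np.fromiter(self.counts.values(), dtype=int),
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("length,count\n")
            for v in sorted(self.counts):
                fh.write(f"{v},{self.counts[v]}\n")


def _weibull_rounded_pmf(x: np.ndarray, scale: float, shape: float) -> np.ndarray:
    """pmf of round(Weibull) floored at 1: mass below 1.5 collapses to 1."""
    upper = 1.0 - np.exp(-(((x + 0.5) / scale) ** shape))
    lower = 1.0 - np.exp(-((np.maximum(x - 0.5, 0.0) / scale) ** shape))
    pmf = upper - lower
    return np.where(x == 1, upper, pmf)


def _mixture_pmf(x: np.ndarray, kind: ErrorKind, theta: np.ndarray) -> np.ndarray:
    if kind == "mismatch":
        a, lam, p = theta
        return a * stats.poisson.pmf(x, lam) + (1 - a) * p * (1 - p) ** x
    a, scale, shape, p = theta
    return a * _weibull_rounded_pmf(x, scale, shape) + (1 - a) * p * (1 - p) ** (x - 1)


@dataclass
class MixtureFit:
    """Result of one maximum-likelihood mixture fit."""

    kind: ErrorKind
    params: object  # MismatchMixture | IndelMixture
    loglik: float
    converged: bool
    ks_stat: float
    ks_pvalue: float
    degenerate: bool  # fitted weight within 0.05 of the {0, 1} boundary


class FitError(RuntimeError):
    """Optimizer failed to converge from every restart."""


def _nll(theta: np.ndarray, kind: ErrorKind, vals: np.ndarray, cnts: np.ndarray) -> float:
    pmf = _mixture_pmf(vals, kind, theta)
    if not np.all(np.isfinite(pmf)) or np.any(pmf <= 0):
        return 1e12
    return -float(np.dot(cnts, np.log(pmf)))


def _starts(kind: ErrorKind, vals: np.ndarray, cnts: np.ndarray, rng) -> List[np.ndarray]:
    mean = float(np.dot(vals, cnts) / cnts.sum())
    if kind == "mismatch":
        base = [
            np.array([0.5, max(mean, 0.2), 1.0 / (1.0 + max(mean, 0.2))]),
            np.array([0.7, max(2 * mean, 0.5), 0.5]),
            np.array([0.3, max(mean, 0.2), 0.3]),
        ]
    else:
        base = [
            np.array([0.5, max(mean, 0.6), 1.5, min(0.9, 1.0 / max(mean, 1.05))]),
            np.array([0.7, max(1.5 * mean, 0.8), 1.0, 0.5]),
            np.array([0.3, max(mean, 0.6), 2.0, 0.3]),
        ]
    jitter = [b * rng.uniform(0.7, 1.3, size=b.size) for b in base[:2]]
    return base + jitter


def fit_mixture(
    tally: FragmentTally, kind: Optional[ErrorKind] = None, seed: int = 0
) -> MixtureFit:
    """Maximum-likelihood fit of the two-component mixture for one kind,
    with multiple optimizer restarts and a KS goodness-of-fit test.

    The KS test compares the empirical distribution against the fitted
    mixture CDF; for discrete data the plain KS statistic is
    conservative (no discreteness correction is applied).
    """
    kind = kind or tally.kind
    if tally.n < 100:
        raise ValueError(f"need >= 100 observations to fit, got {tally.n}")
    vals = np.fromiter(sorted(tally.counts), dtype=float)
    cnts = np.array([tally.counts[int(v)] for v in vals], dtype=float)
    if kind == "mismatch":
        bounds = [(1e-4, 1 - 1e-4), (1e-3, None), (1e-4, 1 - 1e-4)]
    else:
        bounds = [(1e-4, 1 - 1e-4), (1e-3, None), (0.05, 50.0), (1e-4, 1 - 1e-4)]
    rng = np.random.default_rng(seed)
    best = None
    for x0 in _starts(kind, vals, cnts, rng):
        res = optimize.minimize(
            _nll, x0, args=(kind, vals, cnts), method="L-BFGS-B", bounds=bounds
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise FitError(f"mixture fit for {kind} failed to converge from all restarts")
    theta = best.x
    if kind == "mismatch":
        fitted = MismatchMixture(a=float(theta[0]), lam=float(theta[1]), p=float(theta[2]))
    else:
        fitted = IndelMixture(
            a=float(theta[0]), scale=float(theta[1]), shape=float(theta[2]), p=float(theta[3])
        )

    ks_stat, ks_p = _ks_discrete(vals, cnts, kind, theta)
    return MixtureFit(
        kind=kind,
        params=fitted,
        loglik=-float(best.fun),
        converged=bool(best.success),
        ks_stat=ks_stat,
        ks_pvalue=ks_p,
        degenerate=min(theta[0], 1.0 - theta[0]) < 0.05,
    )


def _ks_discrete(
    vals: np.ndarray, cnts: np.ndarray, kind: ErrorKind, theta: np.ndarray
) -> Tuple[float, float]:
    """Plain KS of an integer sample against the fitted mixture.

    Both CDFs are step functions on the integers, so the sup distance is
    attained at an atom, approached from the left or the right; the
    p-value comes from the continuous Kolmogorov distribution, which is
    conservative for discrete data (no discreteness correction).
    """
    n = cnts.sum()
    lo = 0 if kind == "mismatch" else 1
    support = np.arange(lo, int(vals.max()) + 1, dtype=float)
    grid = np.cumsum(_mixture_pmf(support, kind, theta))
    idx = vals.astype(int) - lo
    F_right = grid[idx]
    F_left = F_right - _mixture_pmf(vals, kind, theta)
    ecdf_right = np.cumsum(cnts) / n
    ecdf_left = ecdf_right - cnts / n
    d = max(np.abs(ecdf_right - F_right).max(), np.abs(ecdf_left - F_left).max())
    return float(d), float(stats.kstwo.sf(d, int(n)))


# ---------------------------------------------------------------------------
# Synthetic genomes, fragmented contigs, and junction-spanning reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Junction:
    """Truth for one adjacency: left/right contig ids as they appear on
    the genome, their recorded orientations, the planted gap, and the
    genome coordinate where the gap starts."""

    left_id: str
    right_id: str
    left_orient: str
    right_orient: str
    gap: int
    genome_pos: int


@dataclass
class SyntheticTruth:
    """A random genome, contigs cut from it, and the junction truth."""

    genome: str
    contigs: List[ContigRecord]
    junctions: List[Junction]
    orientations: Dict[str, str]
    segments: List[Tuple[int, int]]  # genome interval of each contig, in order

    @property
    def n_junctions(self) -> int:
        return len(self.junctions)

    def reconstruct(self) -> str:
        """Genome rebuilt from contigs and planted gaps (gap bases are
        restored from the genome; identity check when gaps are zero)."""
        parts = []
        for i, (lo, hi) in enumerate(self.segments):
            rec = self.contigs[i]
            parts.append(rec.seq if self.orientations[rec.id] == "+" else revcomp(rec.seq))
            if i + 1 < len(self.segments):
                parts.append(self.genome[hi : self.segments[i + 1][0]])
        return "".join(parts)


def random_genome(length: int, rng) -> str:
    return "".join(_BASES[i] for i in _as_rng(rng).integers(0, 4, size=length))


def make_truth(
    genome_len: int,
    n_contigs: int,
    gap_range: Tuple[int, int],
    seed,
    min_contig_len: int = 2000,
    flip_prob: float = 0.0,
) -> SyntheticTruth:
    """Cut a random genome into contigs with planted gaps.

    Gaps are drawn uniformly from the inclusive *gap_range*; contig
    lengths are min_contig_len plus a multinomial split of the slack.
    With probability *flip_prob* a contig is stored reverse-complemented
    and its recorded orientation is '-'.
    """
    rng = _as_rng(seed)
    lo, hi = gap_range
    if n_contigs < 1 or lo < 0 or hi < lo:
        raise ValueError("inconsistent contig/gap geometry")
    gaps = rng.integers(lo, hi + 1, size=max(0, n_contigs - 1)) if n_contigs > 1 else np.array([], dtype=int)
    slack = genome_len - int(gaps.sum()) - n_contigs * min_contig_len
    if slack < 0:
        raise ValueError(
            f"genome of {genome_len} bp cannot hold {n_contigs} contigs of >= "
            f"{min_contig_len} bp with gaps in {gap_range}"
        )
    extras = rng.multinomial(slack, [1.0 / n_contigs] * n_contigs)
    lengths = (extras + min_contig_len).astype(int)
    genome = random_genome(genome_len, rng)
    segments: List[Tuple[int, int]] = []
    pos = 0
    for i in range(n_contigs):
        segments.append((pos, pos + int(lengths[i])))
        pos += int(lengths[i]) + (int(gaps[i]) if i < n_contigs - 1 else 0)
    contigs: List[ContigRecord] = []
    orientations: Dict[str, str] = {}
    for i, (s, e) in enumerate(segments):
        cid = f"c{i + 1}"
        seq = genome[s:e]
        if flip_prob > 0 and rng.random() < flip_prob:
            contigs.append(ContigRecord(id=cid, seq=revcomp(seq)))
            orientations[cid] = "-"
        else:
            contigs.append(ContigRecord(id=cid, seq=seq))
            orientations[cid] = "+"
    junctions = [
        Junction(
            left_id=f"c{i + 1}",
            right_id=f"c{i + 2}",
            left_orient=orientations[f"c{i + 1}"],
            right_orient=orientations[f"c{i + 2}"],
            gap=int(gaps[i]),
            genome_pos=segments[i][1],
        )
        for i in range(n_contigs - 1)
    ]
    return SyntheticTruth(
        genome=genome,
        contigs=contigs,
        junctions=junctions,
        orientations=orientations,
        segments=segments,
    )


def junction_spanning_reads(
    truth: SyntheticTruth,
    read_len: int,
    per_junction: int,
    seed,
    params: Optional[ErrorModelParams] = None,
    margin: int = 500,
) -> List[Tuple[str, str]]:
    """Reads guaranteed to straddle each junction with >= *margin* flank.

    Error-free verbatim slices when *params* is None, otherwise corrupted
    with :func:`simulate_read`.  Read ids carry the true genome start for
    debugging.
    """
    rng = _as_rng(seed)
    reads: List[Tuple[str, str]] = []
    glen = len(truth.genome)
    for j, junc in enumerate(truth.junctions):
        pos = junc.genome_pos
        lo = max(0, pos - read_len + margin)
        hi = max(lo + 1, min(pos - margin, glen - read_len) + 1)
        for i in range(per_junction):
            start = int(rng.integers(lo, hi))
            if params is None:
                seq = truth.genome[start : start + read_len]
            else:
                seq = simulate_read(truth.genome, start, read_len, params, rng).seq
            reads.append((f"read_j{j + 1}_{i + 1}_pos{start}", seq))
    return reads
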