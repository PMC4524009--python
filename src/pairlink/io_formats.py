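"""Sequence I/O and the scaffolder's output file family.

Input side: a draft assembly as FASTA (contigs below a minimum length are
dropped before any k-mer work) and long sequences — nanopore/PacBio reads
or another assembly draft — as FASTA/FASTQ files listed in a
file-of-filenames.  FASTQ quality strings are ignored; the linking logic
never uses them.

Output side, for prefix ``base``:

``base.scaffold``
    one line per scaffold: ``scaffoldN,totalSize,chain`` where *chain* is
    ``_``-joined tokens ``<f|r><contigId>z<contigLen>``; a token merged to
    its right neighbour carries ``m<gapEstimate>`` (f=forward, r=reverse).
``base.scaffold.fa``
    scaffold sequences, 60 columns; an estimated gap g >= 1 becomes g 'N'
    pad bases, an overlap or abutment (g <= 0) becomes a single 'n'.
``base.log`` (append-only), ``base.pairing_issues``,
``base.pairing_distribution.csv`` (``distance,count``).
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from ._kmer import revcomp

FASTA_WIDTH = 60
DEFAULT_MIN_CONTIG = 500  # reporting convention: sequences >= 500 bp


class FastaFormatError(ValueError):
    """Malformed FASTA/FASTQ input."""


@dataclass(frozen=True)
class ContigRecord:
    """One input sequence: id is the first whitespace token of its header."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def read_assembly(path, min_len: int = DEFAULT_MIN_CONTIG) -> list[ContigRecord]:
    """Read a FASTA assembly, keeping records of length >= *min_len*.

    Bases are uppercased; duplicate ids and headerless leading sequence
    lines are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}, line {lineno}: sequence data before any '>' header"
                )
            break
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if len(seq) >= min_len:
            records.append(ContigRecord(id=rec.id, seq=seq))
    return records


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line[0] == ">":
                return "fasta"
            if line[0] == "@":
                return "fastq"
            raise FastaFormatError(
                f"{path}: first record starts with {line[0]!r}; expected '>' or '@'"
            )
    return "fasta"  # empty file: harmless, yields no reads


class LongReadSet:
    """Re-iterable stream of (read id, sequence) pairs.

    Backed either by the files named in a file-of-filenames (consumed in
    listed order, each exactly once per iteration) or by an in-memory
    list of records (simulated reads).
    """

    def __init__(self, files: Sequence[Path] = (), records: Sequence[tuple[str, str]] = ()):
        self._files = [Path(f) for f in files]
        self._records = list(records)

    @classmethod
    def from_fof(cls, fof_path) -> "LongReadSet":
        fof_path = Path(fof_path)
        files: list[Path] = []
        with open(fof_path) as fh:
            for line in fh:
                name = line.strip()
                if not name or name.startswith("#"):
                    continue
                p = Path(name)
                if not p.is_absolute():
                    p = fof_path.parent / p
                if not p.is_file():
                    raise FileNotFoundError(f"{fof_path}: listed file not found: {p}")
                files.append(p)
        return cls(files=files)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "LongReadSet":
        return cls(records=list(records))

    def __iter__(self) -> Iterator[tuple[str, str]]:
        for name, seq in self._records:
            yield name, seq.upper()
        for path in self._files:
            fmt = _sniff_format(path)
            for rec in SeqIO.parse(str(path), fmt):
                yield rec.id, str(rec.seq).upper()


def read_long_reads(fof_path) -> LongReadSet:
    """Open the file-of-filenames naming FASTA/FASTQ long-sequence files."""
    return LongReadSet.from_fof(fof_path)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, seq) pairs as FASTA at the fixed 60-column width."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def gap_pad(gap: int) -> str:
    """Pad for an estimated gap: g >= 1 -> g N's; overlap/abutting -> 'n'."""
    return "N" * gap if gap >= 1 else "n"


def layout_sequence(layout, contig_by_id) -> str:
    """Concatenate a layout's oriented contigs with gap padding."""
    parts: list[str] = []
    for entry in layout.entries:
        seq = contig_by_id[entry.contig_id].seq
        parts.append(seq if entry.orient == "+" else revcomp(seq))
        if entry.gap_to_next is not None:
            parts.append(gap_pad(entry.gap_to_next))
    return "".join(parts)


def layout_line(layout, contig_by_id) -> str:
    toks = []
    for entry in layout.entries:
        tok = ("f" if entry.orient == "+" else "r") + entry.contig_id
        tok += f"z{contig_by_id[entry.contig_id].length}"
        if entry.gap_to_next is not None:
            tok += f"m{entry.gap_to_next}"
        toks.append(tok)
    total = len(layout_sequence(layout, contig_by_id))
    return f"{layout.scaffold_id},{total}," + "_".join(toks)


def write_outputs(
    layouts: Sequence,
    contigs: Sequence[ContigRecord],
    base: str,
    issues=None,
    distance_counts: Counter | None = None,
    log_lines: Sequence[str] = (),
) -> None:
    """Write the five-file output family for one scaffolding round."""
    base = str(base)
    os.makedirs(os.path.dirname(base) or ".", exist_ok=True)
    contig_by_id = {c.id: c for c in contigs}
    missing = {
        e.contig_id for lay in layouts for e in lay.entries if e.contig_id not in contig_by_id
    }
    if missing:
        raise KeyError(f"layout references unknown contig ids: {sorted(missing)}")

    with open(base + ".scaffold", "w") as fh:
        for lay in layouts:
            fh.write(layout_line(lay, contig_by_id) + "\n")

    write_fasta(
        ((lay.scaffold_id, layout_sequence(lay, contig_by_id)) for lay in layouts),
        base + ".scaffold.fa",
    )

    with open(base + ".log", "a") as fh:
        for line in log_lines:
            fh.write(line.rstrip("\n") + "\n")

    with open(base + ".pairing_issues", "w") as fh:
        if issues is not None:
            for reason, c1, c2, dist, d in issues.records:
                fh.write(f"{reason}\t{c1}\t{c2}\tD={dist}\td={d}\n")

    with open(base + ".pairing_distribution.csv", "w") as fh:
        fh.write("distance,count\n")
        if distance_counts:
            for dist in sorted(distance_counts):
                fh.write(f"{dist},{distance_counts[dist]}\n")
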