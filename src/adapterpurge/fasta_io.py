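"""FASTA input/output and basic assembly statistics.

An assembly is an ordered collection of contigs read from one FASTA file
(one record per contig). Sequences are stored uppercase; IUPAC ambiguity
codes are preserved verbatim — they count toward lengths but (by design)
never match the adapter during scanning.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "Contig",
    "Assembly",
    "AssemblyStats",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "compute_stats",
    "n50",
]


class FastaParseError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class Contig:
    """One assembled contiguous sequence.

    ``id`` is the FASTA header token up to the first whitespace; the
    remainder of the header line is kept as ``description`` but never used
    in any computation.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """A named, ordered set of contigs with unique ids."""

    name: str
    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError(f"assembly {self.name!r} contains no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"assembly {self.name!r} has duplicate contig ids: {dupes}"
            )

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"no contig {contig_id!r} in assembly {self.name!r}")

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)


@dataclass(frozen=True)
class AssemblyStats:
    """Per-assembly size summary: total length X, contig count y, N50."""

    total_length_X: int
    contig_count_y: int
    n50: int


def n50(lengths) -> int:
    """N50 of a collection of contig lengths.

    The length L of the smallest contig such that contigs of length >= L
    together cover at least half of the total assembly length: sort
    descending, cumulate, return the first length whose cumulative sum
    reaches X/2 (X/2 taken exactly, no integer truncation).
    """
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length set is undefined")
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    csum = np.cumsum(arr)
    half = csum[-1] / 2
    idx = int(np.searchsorted(csum, half, side="left"))
    return int(arr[idx])


def compute_stats(assembly: Assembly) -> AssemblyStats:
    """Total length X, contig count y, and N50 for one assembly."""
    lengths = [len(c) for c in assembly.contigs]
    return AssemblyStats(
        total_length_X=int(sum(lengths)),
        contig_count_y=len(lengths),
        n50=n50(lengths),
    )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "r", encoding="ascii")


def read_fasta(path) -> Assembly:
    """Read one FASTA file as an Assembly (name = file stem).

    Sequences are uppercased; record order is preserved. Raises
    :class:`FastaParseError` (naming the offending line number) for an
    empty file or for sequence data appearing before the first header.
    """
    path = Path(path)
    with _open_text(path) as handle:
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaParseError(
                f"{path}: line {lineno}: sequence data before first FASTA header"
            )
        break
    else:
        raise FastaParseError(f"{path}: no FASTA records found")

    contigs = []
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        cid = parts[0] if parts else ""
        desc = parts[1] if len(parts) > 1 else ""
        if not seq:
            raise FastaParseError(f"{path}: record {cid!r} has an empty sequence")
        contigs.append(Contig(id=cid, seq=seq.upper(), description=desc))
    stem = path.name
    for ext in (".gz", ".fasta", ".fa", ".fna"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    return Assembly(name=stem, contigs=contigs)


def write_fasta(assembly: Assembly, path, width: int = 60) -> None:
    """Write an assembly as FASTA with fixed line wrap (default 60)."""
    if width < 1:
        raise ValueError("line width must be positive")
    path = Path(path)
    try:
        with open(path, "w", encoding="ascii") as out:
            for c in assembly.contigs:
                header = f">{c.id} {c.description}".rstrip()
                out.write(header + "\n")
                for i in range(0, len(c.seq), width):
                    out.write(c.seq[i : i + width] + "\n")
    except OSError as exc:
        raise OSError(f"failed writing FASTA to {path}: {exc}") from exc
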