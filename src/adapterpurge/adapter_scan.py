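"""Exact adapter matching in contigs and positional summaries.

Locates every exact, case-insensitive occurrence of the Illumina universal
adapter (default the 12-mer ``AGATCGGAAGAG``) and of its reverse complement
in each contig, including overlapping occurrences, and characterizes hit
positions relative to the contig extremities. Non-ACGT symbols (N or any
IUPAC ambiguity code) never match: matching is exact, so a single
ambiguous base in a window disqualifies it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .fasta_io import Assembly

__all__ = [
    "UNIVERSAL_ADAPTER",
    "FORWARD",
    "REVERSE_COMPLEMENT",
    "AdapterHit",
    "ScanResult",
    "reverse_complement",
    "scan_assembly",
    "extremity_summary",
    "hits_table",
]

#: Illumina TruSeq 12-base universal adapter.
UNIVERSAL_ADAPTER = "AGATCGGAAGAG"

FORWARD = "forward"
REVERSE_COMPLEMENT = "reverse_complement"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = re.compile(r"^[ACGT]+$")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AdapterHit:
    """One exact adapter match.

    Coordinates are 0-based half-open; ``dist_to_start`` is the offset of
    the first matched base from the contig start (= start) and
    ``dist_to_end`` the bases from the last matched base to the contig end
    (contig length − end).
    """

    contig_id: str
    orientation: str
    start: int
    end: int
    dist_to_start: int
    dist_to_end: int


@dataclass
class ScanResult:
    """All adapter hits in one assembly, both orientations."""

    assembly_name: str
    hits: list[AdapterHit] = field(default_factory=list)

    @property
    def k_forward(self) -> int:
        return sum(1 for h in self.hits if h.orientation == FORWARD)

    @property
    def k_reverse(self) -> int:
        return sum(1 for h in self.hits if h.orientation == REVERSE_COMPLEMENT)

    @property
    def k_total(self) -> int:
        return len(self.hits)

    def hits_for(self, contig_id: str) -> list[AdapterHit]:
        return [h for h in self.hits if h.contig_id == contig_id]


def _find_overlapping(seq: str, motif: str):
    """Start offsets of every (possibly overlapping) exact occurrence."""
    pat = re.compile("(?=" + re.escape(motif) + ")")
    return [m.start() for m in pat.finditer(seq)]


def scan_assembly(assembly: Assembly, adapter: str = UNIVERSAL_ADAPTER) -> ScanResult:
    """Scan every contig for the adapter and its reverse complement.

    Overlapping occurrences are all reported (sliding-window semantics),
    matching the all-window-positions null model used for the enrichment
    test. The reverse complement is always derived from ``adapter``.
    """
    adapter = adapter.upper()
    if not adapter or not _ACGT.match(adapter):
        raise ValueError(
            f"adapter must be a nonempty ACGT string, got {adapter!r}"
        )
    rc = reverse_complement(adapter)
    alen = len(adapter)
    result = ScanResult(assembly_name=assembly.name)
    for contig in assembly:
        seq = contig.seq
        clen = len(seq)
        for orientation, motif in ((FORWARD, adapter), (REVERSE_COMPLEMENT, rc)):
            for start in _find_overlapping(seq, motif):
                end = start + alen
                result.hits.append(
                    AdapterHit(
                        contig_id=contig.id,
                        orientation=orientation,
                        start=start,
                        end=end,
                        dist_to_start=start,
                        dist_to_end=clen - end,
                    )
                )
    return result


def extremity_summary(scan: ScanResult, assembly: Assembly) -> dict:
    """Positional summary of hits relative to contig extremities.

    Forward hits are summarized by their distance to the contig END and
    reverse-complement hits by their distance to the contig START (the
    two orientations cluster at opposite extremities in adapter-broken
    assemblies). An orientation with zero hits gets ``None``, never a
    zero-filled record.
    """
    if scan.assembly_name != assembly.name:
        raise ValueError(
            f"scan of {scan.assembly_name!r} does not match assembly {assembly.name!r}"
        )

    def _summ(values):
        if not values:
            return None
        return {
            "n": len(values),
            "mean": sum(values) / len(values),
            "min": min(values),
            "max": max(values),
        }

    fwd = [h.dist_to_end for h in scan.hits if h.orientation == FORWARD]
    rev = [h.dist_to_start for h in scan.hits if h.orientation == REVERSE_COMPLEMENT]
    return {
        "assembly": assembly.name,
        "forward_dist_to_end": _summ(fwd),
        "reverse_dist_to_start": _summ(rev),
        "mean_contig_length": assembly.total_length / len(assembly),
    }


def hits_table(scan: ScanResult) -> pd.DataFrame:
    """Hit table with 1-based inclusive display coordinates."""
    rows = [
        {
            "assembly": scan.assembly_name,
            "contig": h.contig_id,
            "orientation": h.orientation,
            "start": h.start + 1,
            "end": h.end,
            "dist_to_start": h.dist_to_start,
            "dist_to_end": h.dist_to_end,
        }
        for h in scan.hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "assembly",
            "contig",
            "orientation",
            "start",
            "end",
            "dist_to_start",
            "dist_to_end",
        ],
    )
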