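"""Contig-end trimming of adapter-contaminated extremities.

The repair rule: when an adapter hit (either orientation) overlaps the
first `window` bases of a contig, the first `trim_length` bases are
removed; likewise for the last `window`/`trim_length` at the other end.
Defaults are window=300 and trim_length=450 — the trim deliberately
removes a fixed block larger than the detection window so that adapter
fragments and flanking junk go with it. Contigs left shorter than
`min_retained` are dropped and logged rather than emitted as stubs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .adapter_scan import ScanResult
from .fasta_io import Assembly, Contig

__all__ = ["TrimAction", "trim_assembly", "sweep_trim_lengths"]

DEFAULT_WINDOW = 300
DEFAULT_TRIM_LENGTH = 450
DEFAULT_MIN_RETAINED = 100


@dataclass(frozen=True)
class TrimAction:
    """Record of what was removed from one contig (and why)."""

    contig_id: str
    trimmed_start: int
    trimmed_end: int
    dropped: bool
    reason: str


def trim_assembly(
    assembly: Assembly,
    scan: ScanResult,
    window: int = DEFAULT_WINDOW,
    trim_length: int = DEFAULT_TRIM_LENGTH,
    min_retained: int = DEFAULT_MIN_RETAINED,
) -> tuple[Assembly | None, list[TrimAction]]:
    """Excise contaminated contig extremities.

    A hit "within the first/last `window` bases" means the hit interval
    overlaps that window (any overlap leaves adapter residue in it). Both
    ends of one contig can be trimmed. Untouched contigs pass through
    unmodified. Returns (trimmed assembly or None if every contig was
    dropped, trim actions for every contig that had a hit).
    """
    if min_retained < 1:
        raise ValueError("min_retained must be >= 1")
    known = {c.id for c in assembly.contigs}
    for h in scan.hits:
        if h.contig_id not in known:
            raise ValueError(
                f"scan hit references unknown contig {h.contig_id!r}"
            )

    actions: list[TrimAction] = []
    kept: list[Contig] = []
    for contig in assembly:
        hits = scan.hits_for(contig.id)
        clen = len(contig)
        # hit interval [start, end) overlaps [0, window) / [clen-window, clen)
        hit_start = any(h.start < window for h in hits)
        hit_end = any(h.end > clen - window for h in hits)
        if not hits or not (hit_start or hit_end):
            kept.append(contig)
            continue
        t_start = trim_length if hit_start else 0
        t_end = trim_length if hit_end else 0
        remaining = clen - t_start - t_end
        if remaining < min_retained:
            actions.append(
                TrimAction(
                    contig_id=contig.id,
                    trimmed_start=t_start,
                    trimmed_end=t_end,
                    dropped=True,
                    reason=(
                        f"length {clen} - {t_start} - {t_end} = {remaining} "
                        f"< min_retained {min_retained}"
                    ),
                )
            )
            continue
        ends = []
        if t_start:
            ends.append("start")
        if t_end:
            ends.append("end")
        actions.append(
            TrimAction(
                contig_id=contig.id,
                trimmed_start=t_start,
                trimmed_end=t_end,
                dropped=False,
                reason=f"adapter hit within {window} bases of { ' and '.join(ends) }",
            )
        )
        kept.append(
            Contig(
                id=contig.id,
                seq=contig.seq[t_start : clen - t_end],
                description=contig.description,
            )
        )
    if not kept:
        return None, actions
    return Assembly(name=assembly.name, contigs=kept), actions


def sweep_trim_lengths(
    assembly: Assembly,
    scan: ScanResult,
    lengths=(150, 250, 350, 450, 550, 650),
    window: int = DEFAULT_WINDOW,
    min_overlap: int = 40,
    min_retained: int = DEFAULT_MIN_RETAINED,
) -> list[dict]:
    """Trim + reassemble at each candidate trim length; report ΔN50.

    Returns one row per candidate length with the N50 before, after
    trim+merge, and the change. The default grid brackets the default
    450-base trim.
    """
    from .fasta_io import compute_stats
    from .reassembler import find_overlaps, merge

    before = compute_stats(assembly)
    rows = []
    for length in lengths:
        # trim lengths below the detection window are allowed: they may
        # leave adapter residue, which is exactly what the sweep measures
        trimmed, _ = trim_assembly(
            assembly,
            scan,
            window=window,
            trim_length=length,
            min_retained=min_retained,
        )
        if trimmed is None:
            rows.append(
                {
                    "trim_length": length,
                    "n50_before": before.n50,
                    "n50_after": 0,
                    "delta_n50": -before.n50,
                }
            )
            continue
        overlaps = find_overlaps(trimmed, min_overlap=min_overlap)
        merged, _ = merge(trimmed, overlaps)
        after = compute_stats(merged)
        rows.append(
            {
                "trim_length": length,
                "n50_before": before.n50,
                "n50_after": after.n50,
                "delta_n50": after.n50 - before.n50,
            }
        )
    return rows
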