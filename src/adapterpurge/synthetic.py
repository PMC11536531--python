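"""Synthetic adapter-contaminated assemblies with known ground truth.

The generator emulates the contamination structure seen in real
adapter-broken assemblies: at each break point the left contig terminates
in (forward-specific adapter fragment + universal adapter + random junk)
and the right contig begins with (random junk + reverse-complemented
universal adapter + reverse-specific adapter fragment), so the adapter
sits within the extremity detection window. A stretch of genuine genomic
sequence is duplicated across the break, sized so that after the
trim_length excision on both sides exactly ``hidden_overlap`` genuine
bases of overlap remain — which is what makes the trimmed contigs
re-mergeable and the reference recoverable base-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adapter_scan import (
    FORWARD,
    REVERSE_COMPLEMENT,
    UNIVERSAL_ADAPTER,
    reverse_complement,
)
from .fasta_io import Assembly, Contig

__all__ = [
    "FORWARD_SPECIFIC_ADAPTER",
    "REVERSE_SPECIFIC_ADAPTER",
    "TruthTable",
    "make_reference",
    "make_clean_assembly",
    "make_contaminated_assembly",
]

#: Illumina forward- and reverse-specific adapter sequences whose partial
#: fragments flank the universal adapter in contaminated contigs.
FORWARD_SPECIFIC_ADAPTER = "CACACGTCTGAACTCCAGTCA"
REVERSE_SPECIFIC_ADAPTER = "CGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthTable:
    """Ground truth for one synthetic contaminated assembly."""

    reference_seq: str
    planted_hits: list[tuple[str, str, int]] = field(default_factory=list)
    break_points: list[int] = field(default_factory=list)
    hidden_overlap_lengths: list[int] = field(default_factory=list)
    seed: int = 0


def make_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random nucleotide sequence with the given GC fraction.

    Reproducible for a given seed. Chance adapter occurrences are NOT
    removed — they are part of the null model.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 < gc < 1):
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    at = (1 - gc) / 2
    probs = [at, gc / 2, gc / 2, at]  # A, C, G, T
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode("ascii")


def make_clean_assembly(
    reference: str, n_contigs: int, seed: int = 0, name: str = "synthetic"
) -> Assembly:
    """Partition the reference into non-overlapping contigs (null model)."""
    L = len(reference)
    if not (1 <= n_contigs <= L):
        raise ValueError(f"n_contigs must be in [1, {L}], got {n_contigs}")
    rng = np.random.default_rng(seed)
    if n_contigs == 1:
        cuts = []
    else:
        cuts = sorted(rng.choice(np.arange(1, L), size=n_contigs - 1, replace=False))
    bounds = [0, *map(int, cuts), L]
    contigs = [
        Contig(id=f"{name}_c{i}", seq=reference[bounds[i] : bounds[i + 1]])
        for i in range(n_contigs)
    ]
    return Assembly(name=name, contigs=contigs)


def _random_seq(rng, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _junk(rng, length: int, adapter: str) -> str:
    """Random sequence guaranteed not to contain the adapter or its rc."""
    if length == 0:
        return ""
    rc = reverse_complement(adapter)
    for _ in range(100):
        s = _random_seq(rng, length)
        if adapter not in s and rc not in s:
            return s
    raise RuntimeError("could not draw adapter-free junk sequence")


def make_contaminated_assembly(
    reference: str,
    n_breaks: int,
    hidden_overlap: int = 60,
    junk_flank: int | tuple[int, int] = 30,
    seed: int = 0,
    name: str = "synthetic",
    adapter: str = UNIVERSAL_ADAPTER,
    window: int = 300,
    trim_length: int = 450,
    fragment_range: tuple[int, int] = (5, 21),
) -> tuple[Assembly, TruthTable]:
    """Break a reference at ``n_breaks`` points and plant adapter stacks.

    At break b the left contig ends with genuine sequence up to
    b + duplication, then fragment + adapter + junk; the right contig
    starts with junk + rc(adapter) + fragment, then genuine sequence from
    b. The duplication is sized per break as
    hidden_overlap + (trim_length − plant_left) + (trim_length −
    plant_right), so the default 300/450 trim leaves exactly
    ``hidden_overlap`` genuine overlapping bases at each junction:
    scan → trim → merge restores the reference base-exactly.

    ``junk_flank`` may be a fixed length or an inclusive (lo, hi) range
    sampled per plant. The junk places the adapter within ``window``
    bases of the extremity, so every plant triggers trimming.
    """
    L = len(reference)
    rng = np.random.default_rng(seed)
    if n_breaks < 0:
        raise ValueError("n_breaks must be >= 0")
    if hidden_overlap < 0:
        raise ValueError("hidden_overlap must be >= 0")
    if isinstance(junk_flank, tuple):
        junk_lo, junk_hi = junk_flank
    else:
        junk_lo = junk_hi = int(junk_flank)
    frag_lo, frag_hi = fragment_range
    if not (1 <= frag_lo <= frag_hi <= len(FORWARD_SPECIFIC_ADAPTER)):
        raise ValueError(
            f"fragment_range must lie within [1, {len(FORWARD_SPECIFIC_ADAPTER)}]"
        )
    alen = len(adapter)
    if junk_hi >= window:
        raise ValueError(
            f"junk_flank ({junk_hi}) must be < window ({window}) so every "
            f"planted adapter overlaps the detection window"
        )
    max_plant = junk_hi + alen + frag_hi
    if max_plant > trim_length:
        raise ValueError(
            f"junk_flank + adapter + fragment ({max_plant}) must be <= "
            f"trim_length ({trim_length}) so trimming fully excises plants"
        )
    rc_adapter = reverse_complement(adapter)

    if n_breaks == 0:
        assembly = Assembly(name=name, contigs=[Contig(id=f"{name}_c0", seq=reference)])
        return assembly, TruthTable(reference_seq=reference, seed=seed)

    breaks = [round(L * (i + 1) / (n_breaks + 1)) for i in range(n_breaks)]
    max_dup = hidden_overlap + 2 * (trim_length - (junk_lo + alen + frag_lo))
    min_spacing = max_dup + 2 * trim_length - 2 * max_plant + 100
    spacings = [b2 - b1 for b1, b2 in zip([0, *breaks], [*breaks, L])]
    if min(spacings) < min_spacing:
        raise ValueError(
            f"infeasible geometry: spacing between breaks ({min(spacings)}) "
            f"must be >= duplication + retained margin ({min_spacing}); "
            f"use a longer reference or fewer breaks"
        )

    truth = TruthTable(reference_seq=reference, break_points=breaks, seed=seed)
    contigs: list[Contig] = []
    prev = 0
    pending_prefix = ""  # planted start of the next contig
    pending_rc_start = None  # junk length = rc-adapter start offset
    for i, b in enumerate(breaks):
        frag_f = int(rng.integers(frag_lo, frag_hi + 1))
        frag_r = int(rng.integers(frag_lo, frag_hi + 1))
        junk_l = int(rng.integers(junk_lo, junk_hi + 1))
        junk_r = int(rng.integers(junk_lo, junk_hi + 1))
        plant_l = frag_f + alen + junk_l
        plant_r = junk_r + alen + frag_r
        dup = hidden_overlap + (trim_length - plant_l) + (trim_length - plant_r)
        cid = f"{name}_c{i}"
        genuine = reference[prev : b + dup]
        tail = (
            FORWARD_SPECIFIC_ADAPTER[:frag_f]
            + adapter
            + _junk(rng, junk_l, adapter)
        )
        seq = pending_prefix + genuine + tail
        contigs.append(Contig(id=cid, seq=seq))
        if pending_rc_start is not None:
            truth.planted_hits.append((cid, REVERSE_COMPLEMENT, pending_rc_start))
        truth.planted_hits.append(
            (cid, FORWARD, len(pending_prefix) + len(genuine) + frag_f)
        )
        truth.hidden_overlap_lengths.append(hidden_overlap)
        pending_prefix = (
            _junk(rng, junk_r, adapter)
            + rc_adapter
            + reverse_complement(REVERSE_SPECIFIC_ADAPTER)[:frag_r]
        )
        pending_rc_start = junk_r
        prev = b
    cid = f"{name}_c{n_breaks}"
    contigs.append(Contig(id=cid, seq=pending_prefix + reference[prev:]))
    truth.planted_hits.append((cid, REVERSE_COMPLEMENT, pending_rc_start))
    return Assembly(name=name, contigs=contigs), truth
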