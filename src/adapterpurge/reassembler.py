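"""Perfect-overlap contig merging (strict exact-identity reassembler).

Stitches contigs whose extremities share an exact suffix–prefix identity
of at least ``min_overlap`` bases (default 40), in both relative
orientations, using a greedy longest-overlap-first strategy in which each
contig end participates in at most one merge and chains propagate
(A+B, then AB+C). This replaces overlap-consensus assemblers run in
perfect-overlap mode: identity here is required to be 100%, which is
stricter than a 99%-identity consensus join but fully reproducible and
dependency-free.

Overlap taxonomy for a pair of contigs (A, B), where L/R denote the
prefix/suffix ends:

* ``A.R–B.L`` — plain dovetail, ``left/right_orientation`` both ``as_is``;
* ``A.R–B.R`` — right contig reverse-complemented
  (``right_orientation=reverse_complement``);
* ``A.L–B.L`` — left contig reverse-complemented
  (``left_orientation=reverse_complement``);
* containment — one contig exactly inside the other (either orientation),
  reported with ``kind="containment"`` and length = contained length;
* self-overlap (possible circularization) reported with ``kind="self"``
  but never collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .adapter_scan import reverse_complement, scan_assembly
from .fasta_io import Assembly, Contig, compute_stats

__all__ = [
    "Overlap",
    "MergeReport",
    "find_overlaps",
    "merge",
    "run_repair",
    "RepairResult",
]

AS_IS = "as_is"
RC = "reverse_complement"

DEFAULT_MIN_OVERLAP = 40


@dataclass(frozen=True)
class Overlap:
    """Exact terminal identity between two contigs.

    For dovetails, ``length`` bases at the joined ends are identical:
    the suffix of the (possibly flipped) left contig equals the prefix of
    the (possibly flipped) right contig. For containments, ``length`` is
    the contained contig's full length.
    """

    left_id: str
    right_id: str
    length: int
    right_orientation: str = AS_IS
    left_orientation: str = AS_IS
    kind: str = "dovetail"  # dovetail | containment | self

    @property
    def ports(self) -> tuple[tuple[str, str], tuple[str, str]]:
        """(contig, end) pair joined by this dovetail; end in {L, R}."""
        lp = "R" if self.left_orientation == AS_IS else "L"
        rp = "L" if self.right_orientation == AS_IS else "R"
        return (self.left_id, lp), (self.right_id, rp)


@dataclass
class MergeReport:
    assembly_name: str
    n_contigs_before: int
    n_contigs_after: int
    n_contigs_merged: int
    n50_before: int
    n50_after: int

    @property
    def delta_n50(self) -> int:
        return self.n50_after - self.n50_before


def _longest_suffix_prefix(left: str, right: str, min_overlap: int) -> int:
    """Longest k such that left[-k:] == right[:k], k in [min_overlap, maxk].

    Anchored on the first ``min_overlap`` bases of ``right``: any valid
    overlap must place that seed somewhere in the tail of ``left``, so
    C-level ``str.find`` walks candidate anchor positions from the longest
    overlap downward and one slice comparison verifies each. 0 if none.
    """
    maxk = min(len(left), len(right))
    if maxk < min_overlap:
        return 0
    seed = right[:min_overlap]
    pos = left.find(seed, len(left) - maxk)
    while pos != -1:
        k = len(left) - pos
        if right[:k] == left[pos:]:
            return k
        pos = left.find(seed, pos + 1)
    return 0


def find_overlaps(
    assembly: Assembly, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> list[Overlap]:
    """All maximal exact terminal overlaps of length >= min_overlap.

    For every contig pair the four end-pairings are examined (see module
    docstring); for each pairing the longest exact identity is reported.
    Containments and self-overlaps are reported with their ``kind`` set;
    only dovetails participate in merging.
    """
    if min_overlap < 12:
        raise ValueError(f"min_overlap must be >= 12, got {min_overlap}")
    contigs = list(assembly.contigs)
    seqs = {c.id: c.seq for c in contigs}
    rcs = {c.id: reverse_complement(c.seq) for c in contigs}
    overlaps: list[Overlap] = []

    for i, a in enumerate(contigs):
        # self-overlap (possible circular contig): report, never merge
        k = _longest_suffix_prefix_proper(a.seq, a.seq, min_overlap)
        if k:
            overlaps.append(
                Overlap(a.id, a.id, k, kind="self")
            )
        for b in contigs[i + 1 :]:
            sa, sb = seqs[a.id], seqs[b.id]
            # containment (either orientation): full inclusion
            contained = _containment(a, b, sa, sb, rcs)
            if contained is not None:
                overlaps.append(contained)
                continue
            # A.R-B.L and B.R-A.L plain dovetails
            k = _longest_suffix_prefix(sa, sb, min_overlap)
            if k and k < min(len(sa), len(sb)):
                overlaps.append(Overlap(a.id, b.id, k))
            k = _longest_suffix_prefix(sb, sa, min_overlap)
            if k and k < min(len(sa), len(sb)):
                overlaps.append(Overlap(b.id, a.id, k))
            # A.R-B.R: suffix of A vs prefix of rc(B) (symmetric pairing)
            k = _longest_suffix_prefix(sa, rcs[b.id], min_overlap)
            if k and k < min(len(sa), len(sb)):
                overlaps.append(Overlap(a.id, b.id, k, right_orientation=RC))
            # A.L-B.L: suffix of rc(A) vs prefix of B (symmetric pairing)
            k = _longest_suffix_prefix(rcs[a.id], sb, min_overlap)
            if k and k < min(len(sa), len(sb)):
                overlaps.append(Overlap(a.id, b.id, k, left_orientation=RC))
    return overlaps


def _longest_suffix_prefix_proper(left: str, right: str, min_overlap: int) -> int:
    """As _longest_suffix_prefix but excluding the trivial full self-match."""
    maxk = min(len(left), len(right)) - 1
    if maxk < min_overlap:
        return 0
    seed = right[:min_overlap]
    pos = left.find(seed, len(left) - maxk)
    while pos != -1:
        k = len(left) - pos
        if right[:k] == left[pos:]:
            return k
        pos = left.find(seed, pos + 1)
    return 0


def _containment(a, b, sa, sb, rcs):
    if len(sb) <= len(sa):
        if sb in sa:
            return Overlap(a.id, b.id, len(sb), kind="containment")
        if rcs[b.id] in sa:
            return Overlap(
                a.id, b.id, len(sb), right_orientation=RC, kind="containment"
            )
    else:
        if sa in sb:
            return Overlap(b.id, a.id, len(sa), kind="containment")
        if rcs[a.id] in sb:
            return Overlap(
                b.id, a.id, len(sa), right_orientation=RC, kind="containment"
            )
    return None


class _Chain:
    """A growing run of oriented contigs joined by recorded overlaps."""

    __slots__ = ("items", "joins")

    def __init__(self, cid: str):
        self.items: list[tuple[str, int]] = [(cid, +1)]  # (+1 fwd, -1 rc)
        self.joins: list[int] = []  # overlap length between items[i], items[i+1]

    def flip(self) -> None:
        self.items = [(cid, -o) for cid, o in reversed(self.items)]
        self.joins.reverse()


def merge(
    assembly: Assembly, overlaps: list[Overlap]
) -> tuple[Assembly, MergeReport]:
    """Greedy longest-overlap-first merging of dovetail overlaps.

    Each contig end participates in at most one merge; chains propagate.
    Ties are broken by (left_id, right_id) lexicographically, so output is
    deterministic. Contained contigs are absorbed into their container
    (they contribute no sequence) and count as merged. Merged contig ids
    join the member ids with "+", in chain order. The merged strand
    follows the left (first) contig of the chain.
    """
    before = compute_stats(assembly)
    seqs = {c.id: c.seq for c in assembly.contigs}
    desc = {c.id: c.description for c in assembly.contigs}

    chains: dict[str, _Chain] = {c.id: _Chain(c.id) for c in assembly.contigs}
    chain_of: dict[str, _Chain] = dict(chains)
    used_ports: set[tuple[str, str]] = set()
    absorbed: set[str] = set()
    merged_members: set[str] = set()

    containments = [o for o in overlaps if o.kind == "containment"]
    for o in sorted(containments, key=lambda o: (-o.length, o.left_id, o.right_id)):
        if o.right_id in absorbed or o.left_id in absorbed:
            continue
        absorbed.add(o.right_id)
        merged_members.add(o.left_id)
        merged_members.add(o.right_id)

    dovetails = [o for o in overlaps if o.kind == "dovetail"]
    for o in sorted(dovetails, key=lambda o: (-o.length, o.left_id, o.right_id)):
        (a, pa), (b, pb) = o.ports
        if a in absorbed or b in absorbed:
            continue
        if (a, pa) in used_ports or (b, pb) in used_ports:
            continue
        ca, cb = chain_of[a], chain_of[b]
        if ca is cb:
            continue  # would circularize the chain; leave as-is
        # expose port pa on the RIGHT extremity of chain ca
        if not _expose_right(ca, a, pa):
            continue
        if not _expose_left(cb, b, pb):
            continue
        # verify the sequences still match at merge time
        la = _oriented(seqs, *ca.items[-1])
        lb = _oriented(seqs, *cb.items[0])
        if la[-o.length :] != lb[: o.length]:
            raise RuntimeError(
                f"inconsistent overlap at merge time: {a}/{b} length {o.length}"
            )
        used_ports.add((a, pa))
        used_ports.add((b, pb))
        ca.items.extend(cb.items)
        ca.joins.append(o.length)
        ca.joins.extend(cb.joins)
        for cid, _ in cb.items:
            chain_of[cid] = ca
        merged_members.add(a)
        merged_members.add(b)

    out_contigs: list[Contig] = []
    emitted: set[int] = set()
    for c in assembly.contigs:
        if c.id in absorbed:
            continue
        chain = chain_of[c.id]
        if id(chain) in emitted:
            continue
        emitted.add(id(chain))
        seq = _oriented(seqs, *chain.items[0])
        for (cid, orient), k in zip(chain.items[1:], chain.joins):
            nxt = _oriented(seqs, cid, orient)
            if seq[-k:] != nxt[:k]:
                raise RuntimeError(
                    f"overlap invariant breached while building chain at {cid}"
                )
            seq = seq + nxt[k:]
        cid_out = "+".join(cid for cid, _ in chain.items)
        out_contigs.append(
            Contig(id=cid_out, seq=seq, description=desc.get(cid_out, ""))
        )

    out = Assembly(name=assembly.name, contigs=out_contigs)
    after = compute_stats(out)
    report = MergeReport(
        assembly_name=assembly.name,
        n_contigs_before=before.contig_count_y,
        n_contigs_after=after.contig_count_y,
        n_contigs_merged=len(merged_members),
        n50_before=before.n50,
        n50_after=after.n50,
    )
    return out, report


def _oriented(seqs, cid, orient):
    return seqs[cid] if orient == +1 else reverse_complement(seqs[cid])


def _expose_right(chain: _Chain, cid: str, port: str) -> bool:
    """Flip chain if needed so contig cid sits at the right end with
    ``port`` facing outward. False if cid is interior or port faces inward."""
    want = +1 if port == "R" else -1
    if chain.items[-1][0] == cid and chain.items[-1][1] == want:
        return True
    if chain.items[0][0] == cid and chain.items[0][1] == -want:
        chain.flip()
        return True
    return False


def _expose_left(chain: _Chain, cid: str, port: str) -> bool:
    want = +1 if port == "L" else -1
    if chain.items[0][0] == cid and chain.items[0][1] == want:
        return True
    if chain.items[-1][0] == cid and chain.items[-1][1] == -want:
        chain.flip()
        return True
    return False


@dataclass
class RepairResult:
    """Everything produced by one end-to-end repair run."""

    assembly: Assembly
    merge_report: MergeReport
    trim_actions: list
    scan: object
    overlaps: list[Overlap] = field(default_factory=list)


def run_repair(
    assembly: Assembly,
    adapter: str | None = None,
    window: int = 300,
    trim_length: int = 450,
    min_retained: int = 100,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> RepairResult:
    """Full repair pipeline: scan → trim → find overlaps → merge.

    The output assembly contains no adapter hit overlapping a contig
    extremity window that survived trimming. Raises a ValueError if every
    contig is dropped (fully contaminated short input).
    """
    from . import trimmer
    from .adapter_scan import UNIVERSAL_ADAPTER

    adapter = adapter or UNIVERSAL_ADAPTER
    scan = scan_assembly(assembly, adapter=adapter)
    trimmed, actions = trimmer.trim_assembly(
        assembly,
        scan,
        window=window,
        trim_length=trim_length,
        min_retained=min_retained,
    )
    if trimmed is None:
        raise ValueError(
            f"assembly {assembly.name!r}: every contig was dropped by "
            f"trimming (fully contaminated input); nothing to reassemble"
        )
    overlaps = find_overlaps(trimmed, min_overlap=min_overlap)
    merged, report = merge(trimmed, overlaps)
    # ΔN50 is reported against the ORIGINAL assembly, not the trimmed one
    before = compute_stats(assembly)
    report = MergeReport(
        assembly_name=report.assembly_name,
        n_contigs_before=before.contig_count_y,
        n_contigs_after=report.n_contigs_after,
        n_contigs_merged=report.n_contigs_merged,
        n50_before=before.n50,
        n50_after=report.n50_after,
    )
    return RepairResult(
        assembly=merged,
        merge_report=report,
        trim_actions=actions,
        scan=scan,
        overlaps=overlaps,
    )
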