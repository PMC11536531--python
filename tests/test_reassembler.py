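import numpy as np
import pytest

from adapterpurge.adapter_scan import reverse_complement
from adapterpurge.fasta_io import Assembly, Contig, compute_stats
from adapterpurge.reassembler import find_overlaps, merge, run_repair
from adapterpurge.synthetic import make_contaminated_assembly, make_reference


def asm(*seqs, name="t"):
    return Assembly(
        name=name, contigs=[Contig(id=f"c{i}", seq=s) for i, s in enumerate(seqs)]
    )


def brute_force_overlaps(contigs, min_overlap):
    """Quadratic oracle: longest k per end-pairing via direct slicing."""
    found = set()
    seqs = {c.id: c.seq for c in contigs}
    rc = {c.id: reverse_complement(c.seq) for c in contigs}

    def longest(left, right):
        for k in range(min(len(left), len(right)) - 1, min_overlap - 1, -1):
            if left[-k:] == right[:k]:
                return k
        return 0

    ids = [c.id for c in contigs]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if (k := longest(seqs[a], seqs[b])):
                found.add((a, b, k, "as_is", "as_is"))
            if (k := longest(seqs[b], seqs[a])):
                found.add((b, a, k, "as_is", "as_is"))
            if (k := longest(seqs[a], rc[b])):
                found.add((a, b, k, "as_is", "reverse_complement"))
            if (k := longest(rc[a], seqs[b])):
                found.add((a, b, k, "reverse_complement", "as_is"))
    return found


class TestFindOverlaps:
    def test_constructed_suffix_prefix_overlap(self):
        left = "AAAACCCCGGGGTTTTAACCGGTTACGT"
        right = left[-12:] + "AAAAGGGGCCCCTTTT"
        (ov,) = [
            o
            for o in find_overlaps(asm(left, right), min_overlap=12)
            if o.kind == "dovetail"
        ]
        assert (ov.left_id, ov.right_id, ov.length) == ("c0", "c1", 12)

    def test_shared_overlap_below_min_overlap_not_reported(self):
        left = "AAAACCCCGGGG"
        right = "CCCCGGGGTTAA"  # 8-base identity, below the floor
        assert find_overlaps(asm(left, right), min_overlap=12) == []

    def test_minimum_overlap_floor(self):
        with pytest.raises(ValueError, match=">= 12"):
            find_overlaps(asm("A" * 50, "T" * 50), min_overlap=8)

    def test_overlap_found_at_exact_threshold(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        left = "".join(bases[i] for i in rng.integers(0, 4, 100))
        right = left[-40:] + "".join(bases[i] for i in rng.integers(0, 4, 100))
        (ov,) = [o for o in find_overlaps(asm(left, right)) if o.kind == "dovetail"]
        assert (ov.left_id, ov.right_id, ov.length) == ("c0", "c1", 40)

    def test_shared_kmer_below_threshold_ignored(self):
        core = "ACGTACGTACGTACGTACGT"  # 20-mer share, min_overlap 40
        a = make_reference(100, seed=1) + core
        b = core + make_reference(100, seed=2)
        assert all(o.kind != "dovetail" for o in find_overlaps(asm(a, b)))

    def test_reverse_complement_dovetail(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        left = "".join(bases[i] for i in rng.integers(0, 4, 200))
        right_rc = left[-60:] + "".join(bases[i] for i in rng.integers(0, 4, 150))
        right = reverse_complement(right_rc)
        (ov,) = [o for o in find_overlaps(asm(left, right)) if o.kind == "dovetail"]
        assert ov.right_orientation == "reverse_complement"
        assert ov.length == 60

    def test_containment_reported_with_contained_length(self):
        outer = make_reference(500, seed=4)
        inner = outer[100:300]
        (ov,) = [o for o in find_overlaps(asm(outer, inner)) if o.kind == "containment"]
        assert ov.length == 200
        assert (ov.left_id, ov.right_id) == ("c0", "c1")

    def test_matches_quadratic_oracle_on_random_contigs(self):
        rng = np.random.default_rng(17)
        bases = "ACGT"
        for trial in range(5):
            n = int(rng.integers(2, 8))
            contigs = []
            for i in range(n):
                seq = "".join(bases[j] for j in rng.integers(0, 4, 1000))
                contigs.append(Contig(id=f"c{i}", seq=seq))
            # plant one guaranteed overlap per trial
            k = int(rng.integers(40, 200))
            contigs[1] = Contig(id="c1", seq=contigs[0].seq[-k:] + contigs[1].seq)
            assembly = Assembly(name=f"r{trial}", contigs=contigs)
            got = {
                (o.left_id, o.right_id, o.length, o.left_orientation, o.right_orientation)
                for o in find_overlaps(assembly, min_overlap=40)
                if o.kind == "dovetail"
            }
            assert got == brute_force_overlaps(contigs, 40)


class TestMerge:
    def test_two_contigs_single_overlap(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        a = "".join(bases[i] for i in rng.integers(0, 4, 300))
        b = a[-50:] + "".join(bases[i] for i in rng.integers(0, 4, 300))
        assembly = asm(a, b)
        merged, report = merge(assembly, find_overlaps(assembly))
        assert len(merged) == 1
        assert merged.contigs[0].id == "c0+c1"
        assert merged.contigs[0].seq == a + b[50:]
        assert report.n_contigs_merged == 2
        assert report.delta_n50 == report.n50_after - report.n50_before

    def test_no_overlaps_is_identity(self, tiny_assembly):
        merged, report = merge(tiny_assembly, [])
        assert [(c.id, c.seq) for c in merged] == [
            (c.id, c.seq) for c in tiny_assembly
        ]
        assert report.delta_n50 == 0
        assert report.n_contigs_merged == 0

    def test_five_piece_chain_reconstructs_genome(self):
        genome = make_reference(5000, seed=6)
        cuts = [0, 1000, 2000, 3000, 4000, 5000]
        pieces = [
            genome[max(0, lo - 60) : hi] for lo, hi in zip(cuts[:-1], cuts[1:])
        ]  # 60-base genuine overlap between neighbours
        assembly = asm(*pieces)
        merged, report = merge(assembly, find_overlaps(assembly))
        assert len(merged) == 1
        assert merged.contigs[0].seq == genome
        assert report.n_contigs_merged == 5
        assert report.n_contigs_after == 1

    def test_merged_strand_follows_left_contig(self):
        rng = np.random.default_rng(7)
        bases = "ACGT"
        a = "".join(bases[i] for i in rng.integers(0, 4, 300))
        tail = "".join(bases[i] for i in rng.integers(0, 4, 300))
        b = reverse_complement(a[-50:] + tail)
        assembly = asm(a, b)
        merged, _ = merge(assembly, find_overlaps(assembly))
        assert len(merged) == 1
        assert merged.contigs[0].seq == a + tail

    def test_greedy_prefers_longest_overlap(self):
        rng = np.random.default_rng(8)
        bases = "ACGT"
        a = "".join(bases[i] for i in rng.integers(0, 4, 500))
        long_right = a[-120:] + "".join(bases[i] for i in rng.integers(0, 4, 300))
        short_right = a[-50:] + "".join(bases[i] for i in rng.integers(0, 4, 300))
        assembly = asm(a, long_right, short_right)
        merged, _ = merge(assembly, find_overlaps(assembly))
        joined = {c.id for c in merged}
        assert "c0+c1" in joined  # 120 beats 50
        assert "c2" in joined

    def test_merging_without_drops_never_decreases_n50(self):
        rng = np.random.default_rng(9)
        bases = "ACGT"
        for trial in range(5):
            genome = "".join(bases[i] for i in rng.integers(0, 4, 4000))
            cuts = sorted(rng.choice(np.arange(500, 3500), 3, replace=False))
            bounds = [0, *[int(c) for c in cuts], 4000]
            pieces = [
                genome[max(0, lo - 80) : hi]
                for lo, hi in zip(bounds[:-1], bounds[1:])
            ]
            assembly = asm(*pieces, name=f"m{trial}")
            merged, report = merge(assembly, find_overlaps(assembly))
            assert report.n50_after >= report.n50_before

    def test_sequence_conservation_no_invented_bases(self):
        genome = make_reference(3000, seed=10)
        pieces = [genome[:1100], genome[1000:2100], genome[2000:]]
        assembly = asm(*pieces)
        merged, _ = merge(assembly, find_overlaps(assembly))
        for contig in merged:
            assert contig.seq in genome  # every output substring of the source


class TestRunRepair:
    def test_contaminated_assembly_improves_n50(self):
        ref = make_reference(40_000, seed=11)
        assembly, _ = make_contaminated_assembly(ref, 4, seed=11)
        result = run_repair(assembly)
        assert result.merge_report.delta_n50 > 0
        assert result.assembly.contigs[0].seq == ref

    def test_clean_assembly_is_identity(self):
        ref = make_reference(10_000, seed=12)
        assembly = asm(ref[:5000], ref[5000:], name="clean")
        from adapterpurge.adapter_scan import scan_assembly

        if scan_assembly(assembly).k_total:
            pytest.skip("seed produced a chance adapter hit")
        result = run_repair(assembly)
        assert [(c.id, c.seq) for c in result.assembly] == [
            (c.id, c.seq) for c in assembly
        ]
        assert result.merge_report.delta_n50 == 0

    def test_fully_contaminated_input_is_explicit_error(self):
        from adapterpurge.adapter_scan import UNIVERSAL_ADAPTER

        seq = "CTCTTCCGATCT" + "A" * 200 + UNIVERSAL_ADAPTER
        assembly = asm(seq)
        with pytest.raises(ValueError, match="every contig was dropped"):
            run_repair(assembly)
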