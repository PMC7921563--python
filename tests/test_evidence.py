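"""CAGE/PAS read filters, internal-priming resolution, exact placement, peaks."""

import numpy as np
import pytest

from intactrna import evidence
from intactrna.evidence import (
    EndTag,
    Placement,
    call_end_peaks,
    exact_place,
    filter_cage_read,
    process_pas_reads,
    resolve_internal_priming,
    screen_pas_read,
)


class TestCageFilter:
    def test_gg_retained_and_trimmed(self):
        assert filter_cage_read("GGACGT") == "ACGT"

    def test_ng_retained(self):
        assert filter_cage_read("TGACGT") == "ACGT"

    def test_second_base_not_g_rejected(self):
        assert filter_cage_read("TTACGT") is None

    def test_too_short_rejected(self):
        assert filter_cage_read("GG") is None

    def test_random_reads_match_predicate_oracle(self, rng):
        bases = np.array(list("ACGT"))
        reads = ["".join(bases[rng.integers(0, 4, size=20)]) for _ in range(1000)]
        retained = {r for r in reads if filter_cage_read(r) is not None}
        oracle = {r for r in reads if r[1] == "G"}
        assert retained == oracle
        for r in retained:
            assert filter_cage_read(r) == r[2:]

    def test_order_independence(self, rng):
        """Pure per-read function: shuffling reads never changes the retained set."""
        bases = np.array(list("ACGT"))
        reads = ["".join(bases[rng.integers(0, 4, size=12)]) for _ in range(200)]
        out1 = [filter_cage_read(r) for r in reads]
        shuffled = list(reads)
        rng.shuffle(shuffled)
        assert {r for r, o in zip(reads, out1) if o} == {
            r for r in shuffled if filter_cage_read(r)
        }


class TestPasScreen:
    def test_example_tail_split(self):
        assert screen_pas_read("GGGCCCTTAAA", min_body=1) == ("CCCTT", "CCCTTAAA", 3)

    def test_two_terminal_a_rejected(self):
        assert screen_pas_read("GGGCCCTTAA", min_body=1) is None

    def test_prefix_alternates(self):
        # NGG, NNG, GNG all admit: third base G is the common requirement
        for head in ("TGG", "TTG", "GTG", "GGG"):
            assert screen_pas_read(head + "CCCTAAA", min_body=1) is not None
        assert screen_pas_read("GGTCCCTAAA", min_body=1) is None

    def test_internal_a_runs_untouched(self):
        tailless, tailed, n = screen_pas_read("GGGAAACCCAAAA", min_body=1)
        assert tailless == "AAACCC"
        assert tailed == "AAACCCAAAA"
        assert n == 4

    def test_random_tails_match_run_length_oracle(self, rng):
        bases = np.array(list("CGT"))  # body free of A so the tail is the only run
        for _ in range(300):
            body = "".join(bases[rng.integers(0, 3, size=10)])
            tail = int(rng.integers(0, 9))
            out = screen_pas_read("GGG" + body + "A" * tail, min_body=1)
            if tail >= 3:
                assert out == (body, body + "A" * tail, tail)
            else:
                assert out is None


class TestInternalPriming:
    def test_tailless_maps_retained(self):
        call = resolve_internal_priming("r", Placement("chr1", "+", 100, 130), None, 5)
        assert call.status == "retained"
        assert call.cleavage_site == EndTag("chr1", "+", 130)

    def test_minus_strand_cleavage_site(self):
        call = resolve_internal_priming("r", Placement("chr1", "-", 100, 130), None, 5)
        assert call.cleavage_site == EndTag("chr1", "-", 100)

    def test_tailed_maps_discarded(self):
        call = resolve_internal_priming(
            "r", Placement("chr1", "+", 100, 130), Placement("chr1", "+", 100, 136), 6
        )
        assert call.status == "internal_priming"
        assert call.cleavage_site is None

    def test_neither_maps(self):
        assert resolve_internal_priming("r", None, None).status == "rejected_structure"

    def test_inconsistent_placements_error(self):
        with pytest.raises(ValueError):
            resolve_internal_priming(
                "r", Placement("chr1", "+", 0, 30), Placement("chr2", "+", 0, 36)
            )


class TestExactPlace:
    def test_probe_from_genome(self, rng):
        bases = np.array(list("ACGT"))
        genome = {"chr1": "".join(bases[rng.integers(0, 4, size=5000)])}
        probe = genome["chr1"][1000:1020]
        p = exact_place(probe, genome)
        assert p is not None and (p.start, p.end, p.strand) == (1000, 1020, "+")

    def test_absent_probe(self, rng):
        genome = {"chr1": "ACGT" * 500}
        assert exact_place("TTTTTTTTTTTTTTTTTTTT", genome) is None

    def test_matches_naive_search_oracle(self, rng):
        from intactrna.annotation import reverse_complement

        bases = np.array(list("ACGT"))
        genome = {"c1": "".join(bases[rng.integers(0, 4, size=3000)])}
        ref = genome["c1"]
        for _ in range(200):
            if rng.random() < 0.7:
                start = int(rng.integers(0, len(ref) - 25))
                probe = ref[start : start + 25]
                if rng.random() < 0.5:
                    probe = reverse_complement(probe)
            else:
                probe = "".join(bases[rng.integers(0, 4, size=25)])
            fwd = [i for i in range(len(ref) - 24) if ref[i : i + 25] == probe]
            rc = reverse_complement(probe)
            rev = [i for i in range(len(ref) - 24) if ref[i : i + 25] == rc]
            hits = [(i, "+") for i in fwd] + [(i, "-") for i in rev]
            got = exact_place(probe, genome)
            if len(hits) == 1:
                assert got == Placement("c1", hits[0][1], hits[0][0], hits[0][0] + 25)
            else:
                assert got is None


def union_find_peaks(tag_counts, max_gap):
    """Brute-force connected components of the <=max_gap adjacency graph."""
    positions = sorted(tag_counts)
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            p = parent[p]
        return p

    for a in positions:
        for b in positions:
            if a < b and b - a <= max_gap:
                parent[find(b)] = find(a)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    return sorted(sorted(g) for g in groups.values())


class TestPeaks:
    def test_single_cluster(self):
        tags = [EndTag("chr1", "+", 100, 5), EndTag("chr1", "+", 102, 3)]
        peaks = call_end_peaks(tags, max_gap=20, min_count=2)
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.total_count, p.mode) == (100, 103, 8, 100)

    def test_singleton_below_min_count(self):
        assert call_end_peaks([EndTag("chr1", "+", 100)], min_count=2) == []

    def test_mode_tie_break_is_five_prime_most(self):
        tags = [EndTag("chr1", "-", 100, 3), EndTag("chr1", "-", 105, 3)]
        assert call_end_peaks(tags)[0].mode == 105  # 5'-most on '-' is the highest coord
        tags_p = [EndTag("chr1", "+", 100, 3), EndTag("chr1", "+", 105, 3)]
        assert call_end_peaks(tags_p)[0].mode == 100

    def test_matches_union_find_oracle(self, rng):
        positions = rng.integers(0, 2000, size=500)
        tag_counts = {}
        for p in positions:
            tag_counts[int(p)] = tag_counts.get(int(p), 0) + 1
        tags = [EndTag("chr1", "+", p, c) for p, c in tag_counts.items()]
        peaks = call_end_peaks(tags, max_gap=20, min_count=1)
        oracle = union_find_peaks(tag_counts, 20)
        got = sorted(sorted(p_ for p_ in tag_counts if pk.start <= p_ < pk.end) for pk in peaks)
        assert got == oracle

    def test_peaks_disjoint_and_counts_conserved(self, rng):
        positions = rng.integers(0, 3000, size=400)
        tags = [EndTag("chr1", "+", int(p)) for p in positions]
        peaks = call_end_peaks(tags, max_gap=10, min_count=1)
        spans = sorted((p.start, p.end) for p in peaks)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert sum(p.total_count for p in peaks) == len(tags)


class TestSimulatedArtifacts:
    def test_trap_reads_all_flagged_genuine_all_retained(self, default_sim):
        """Every PAS read from a genomic A-run trap is internal priming;
        every true-polyA read is retained (noise-free setting)."""
        _, truth, _, _, pas = default_sim
        _, calls = process_pas_reads(pas, truth.genome)
        status = {c.read_id: c.status for c in calls}
        for lab in truth.pas_read_labels:
            expected = "internal_priming" if lab.kind == "trap" else "retained"
            assert status[lab.read_id] == expected, lab

    def test_no_retained_call_has_tailed_placement(self, default_sim):
        """Internal-priming exclusion is absolute."""
        _, truth, _, _, pas = default_sim
        sites, calls = process_pas_reads(pas, truth.genome)
        retained_ids = {c.read_id for c in calls if c.status == "retained"}
        screened = {rid: screen_pas_read(seq, min_body=18) for rid, seq in pas}
        for rid in retained_ids:
            _, tailed, _ = screened[rid]
            assert exact_place(tailed, truth.genome) is None

    def test_genuine_cleavage_sites_exact(self, default_sim):
        _, truth, _, _, pas = default_sim
        _, calls = process_pas_reads(pas, truth.genome)
        call_by_id = {c.read_id: c for c in calls}
        for lab in truth.pas_read_labels:
            if lab.kind == "genuine":
                site = call_by_id[lab.read_id].cleavage_site
                assert site is not None and site.position == lab.site
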