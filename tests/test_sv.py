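"""Structural-variant calling from alignment blocks."""

import random

import pytest

from intertaxon.sv import (
    AlignmentBlock,
    align_genomes,
    annotate_genes,
    call_svs,
    filter_svs,
    pair_reciprocal,
    read_blocks,
    write_blocks,
)
from intertaxon.simulate import SimConfig, SVSpec, apply_svs, evolve_lineage, generate_ancestor

from conftest import five_event_scenario


class TestBlockIO:
    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "blocks.tsv"
        path.write_text("")
        assert read_blocks(path) == []

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "blocks.tsv"
        path.write_text("chrA\t1\t100\tq1\t1\t100\t+\t99.0\n")  # 8 columns
        with pytest.raises(ValueError, match=":1:"):
            read_blocks(path)

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "blocks.tsv"
        path.write_text("chrA\t500\t100\tq1\t1\t401\t+\t99.0\t401\n")
        with pytest.raises(ValueError, match=":1:"):
            read_blocks(path)

    def test_roundtrip_sorted_by_query(self, tmp_path):
        blocks = [
            AlignmentBlock("chrB", 1, 100, "q2", 1, 100, "+", 99.0),
            AlignmentBlock("chrA", 200, 300, "q1", 150, 250, "-", 98.0),
            AlignmentBlock("chrA", 1, 100, "q1", 1, 100, "+", 99.5),
        ]
        path = tmp_path / "blocks.tsv"
        write_blocks(blocks, path)
        out = read_blocks(path)
        assert len(out) == 3
        assert [(b.query, b.query_start) for b in out] == [("q1", 1), ("q1", 150), ("q2", 1)]


class TestCallSvs:
    def test_single_collinear_block_yields_no_events(self):
        blocks = [AlignmentBlock("chr1", 1, 100_000, "q1", 1, 100_000, "+", 99.0)]
        assert call_svs(blocks) == []

    def test_embedded_minus_run_is_an_inversion(self):
        blocks = [
            AlignmentBlock("chr1", 1, 100_000, "q1", 1, 100_000, "+", 99.0),
            AlignmentBlock("chr1", 100_001, 150_000, "q1", 100_001, 150_000, "-", 99.0),
            AlignmentBlock("chr1", 150_001, 200_000, "q1", 150_001, 200_000, "+", 99.0),
        ]
        events = call_svs(blocks)
        assert [e.kind for e in events] == ["inversion"]
        assert events[0].size == pytest.approx(50_000, abs=1)

    def test_majority_rule_assigns_translocation_to_minority_chromosome(self):
        blocks = [
            AlignmentBlock("chr2", 1, 60_000, "q2", 1, 60_000, "+", 99.0),
            AlignmentBlock("chr7", 10_001, 50_000, "q2", 60_001, 100_000, "+", 99.0),
        ]
        events = call_svs(blocks)
        assert len(events) == 1
        assert events[0].kind == "translocation"
        assert events[0].ref_chrom == "chr7"
        assert events[0].contig_primary == "chr2"
        assert events[0].size == 40_000

    def test_classification_invariant_to_block_order(self):
        reference, rearranged, _ = five_event_scenario(seed=301)
        blocks = align_genomes(reference, rearranged)
        shuffled = blocks[:]
        random.Random(0).shuffle(shuffled)
        key = lambda e: (e.kind, e.ref_chrom, e.ref_start, e.size)
        assert sorted(map(key, call_svs(blocks))) == sorted(map(key, call_svs(shuffled)))


class TestReciprocalPairing:
    def test_simulated_reciprocal_exchange_is_linked(self):
        cfg = SimConfig(ancestor_length=80_000, n_chromosomes=2, seed=71)
        ref = generate_ancestor(cfg)
        query, _ = evolve_lineage(ref, 0.02, 72, "q")
        rearranged, _ = apply_svs(query, [
            SVSpec("reciprocal_translocation", donor="chr1", breakpoint=60_000,
                   acceptor="chr2", acceptor_breakpoint=50_000)
        ])
        svs = pair_reciprocal(call_svs(align_genomes(ref, rearranged)))
        recip = [e for e in svs if e.kind == "reciprocal_translocation"]
        assert len(recip) == 2
        assert {recip[0].partner_id, recip[1].partner_id} == {
            recip[0].event_id, recip[1].event_id
        }

    def test_one_way_move_stays_nonreciprocal(self):
        cfg = SimConfig(ancestor_length=80_000, n_chromosomes=2, seed=73)
        ref = generate_ancestor(cfg)
        query, _ = evolve_lineage(ref, 0.02, 74, "q")
        rearranged, _ = apply_svs(query, [
            SVSpec("nonreciprocal_translocation", donor="chr1", breakpoint=20_000,
                   acceptor="chr2", acceptor_breakpoint=40_000, size=15_000)
        ])
        svs = pair_reciprocal(call_svs(align_genomes(ref, rearranged)))
        trans = [e for e in svs if "translocation" in e.kind]
        assert len(trans) == 1
        assert trans[0].kind == "nonreciprocal_translocation"
        assert trans[0].partner_id is None

    def test_no_translocations_is_a_noop(self):
        assert pair_reciprocal([]) == []


class TestFiveEventArchitecture:
    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_across_seeds(self, seed):
        reference, rearranged, truth = five_event_scenario(seed=400 + seed)
        svs = pair_reciprocal(call_svs(align_genomes(reference, rearranged)))
        svs = filter_svs(svs, min_size=1_000)
        kinds = sorted(e.kind for e in svs)
        assert kinds == [
            "deletion", "inversion", "nonreciprocal_translocation",
            "nonreciprocal_translocation", "reciprocal_translocation",
            "reciprocal_translocation",
        ]
        by_kind = {}
        for e in svs:
            by_kind.setdefault(e.kind, []).append(e.size)
        assert by_kind["deletion"][0] == pytest.approx(5_000, abs=200)
        assert by_kind["inversion"][0] == pytest.approx(48_700, abs=200)
        assert sorted(by_kind["nonreciprocal_translocation"]) == pytest.approx(
            [14_300, 43_300], abs=200
        )
        assert sorted(by_kind["reciprocal_translocation"]) == pytest.approx(
            [5_400, 31_800], abs=200
        )

    def test_size_filter_removes_sub_kilobase_events(self):
        reference, rearranged, _ = five_event_scenario(seed=450)
        svs = pair_reciprocal(call_svs(align_genomes(reference, rearranged)))
        small = [e for e in svs if e.kind == "deletion" and e.size < 1_000]
        assert small, "the planted 500-bp deletion should be called before filtering"
        assert all(e.size > 1_000 for e in filter_svs(svs, min_size=1_000))


class TestFilterAndAnnotate:
    def _events(self, sizes, chrom="chr1"):
        from intertaxon.sv import StructuralVariant

        return [
            StructuralVariant(i, "deletion", chrom, 1_000 * (i + 1),
                              1_000 * (i + 1) + size - 1, "q1", 1, size, size, chrom)
            for i, size in enumerate(sizes)
        ]

    def test_size_filter_is_strict(self):
        kept = filter_svs(self._events([500, 1_500, 2_000]), min_size=1_000)
        assert [e.size for e in kept] == [1_500, 2_000]

    def test_exclusion_regions_remove_overlapping_calls(self):
        events = self._events([1_500, 1_500])  # at ref 1000.. and 2000..
        kept = filter_svs(events, min_size=1_000, exclusion_regions=[("chr1", 900, 1_100)])
        assert len(kept) == 1
        assert kept[0].ref_start == 2_000

    def test_empty_exclusion_set_is_size_filter_only(self):
        events = self._events([1_500])
        assert len(filter_svs(events, 1_000, exclusion_regions=[])) == 1

    def test_gene_overlap_counting(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t2000\t2999\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tgene\t3500\t3999\t.\t+\t.\tID=g2\n"
            "chr1\tsrc\tgene\t4100\t4800\t.\t-\t.\tID=g3\n"
            "chr1\tsrc\tgene\t9000\t9500\t.\t+\t.\tID=g4\n"
        )
        from intertaxon.sv import StructuralVariant

        spanning = StructuralVariant(0, "deletion", "chr1", 1_900, 4_101, "q", 1, 1, 2_202, "chr1")
        outside = StructuralVariant(1, "deletion", "chr1", 5_000, 8_000, "q", 1, 1, 3_001, "chr1")
        annotated = annotate_genes([spanning, outside], gff)
        assert annotated[0].genes_overlapped == 3  # third gene caught by its first bp
        assert annotated[1].genes_overlapped == 0
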