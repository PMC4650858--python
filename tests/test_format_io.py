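import warnings

import pytest

from chromlink import (
    GenomicRange,
    InteractionSet,
    ParseError,
    export_bed12,
    export_graph,
    make_interaction_set,
    read_bedpe,
    read_chiapet_tool,
    read_homer_interactions,
    read_tag_pairs_bedpe,
    read_tag_pairs_sam,
    subset,
    write_bedpe,
)
from chromlink.fixtures import (
    FixtureConfig,
    generate_interactions,
    write_chiapet_fixture,
    write_homer_fixture,
)
from conftest import random_interaction_set


class TestBedpe:
    def test_zero_based_conversion(self, tmp_path):
        p = tmp_path / "one.bedpe"
        p.write_text("chr1\t99\t200\tchr1\t499\t600\t.\t5\t.\t.\n")
        iset = read_bedpe(p)
        assert len(iset) == 1
        assert iset.anchor_one[0] == GenomicRange("chr1", 100, 200)
        assert iset.anchor_two[0] == GenomicRange("chr1", 500, 600)
        assert iset.counts == [5]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bedpe"
        p.write_text("")
        assert len(read_bedpe(p)) == 0

    def test_written_coordinates_are_half_open(self, tmp_path):
        iset = make_interaction_set(
            [GenomicRange("chr1", 100, 200)],
            [GenomicRange("chr1", 500, 600)],
            [5],
        )
        p = tmp_path / "out.bedpe"
        write_bedpe(iset, p)
        line = [l for l in p.read_text().splitlines() if not l.startswith("#")][0]
        f = line.split("\t")
        assert f[1:3] == ["99", "200"] and f[4:6] == ["499", "600"]
        assert f[7] == "5"

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "empty_out.bedpe"
        write_bedpe(make_interaction_set([], [], []), p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")

    @pytest.mark.parametrize("seed", range(8))
    def test_round_trip_identity_with_metadata(self, tmp_path, seed):
        iset = random_interaction_set(seed=seed, n=500).sort()
        p = tmp_path / "rt.bedpe"
        write_bedpe(iset, p)
        back = read_bedpe(p)
        assert back == iset

    def test_short_line_error_has_line_number(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t99\t200\tchr1\t499\t600\t.\t5\t.\t.\nchr1\t1\t2\n")
        with pytest.raises(ParseError, match="line 2"):
            read_bedpe(p)

    def test_non_integer_coordinate_error(self, tmp_path):
        p = tmp_path / "bad2.bedpe"
        p.write_text("chr1\tx\t200\tchr1\t499\t600\t.\t5\t.\t.\n")
        with pytest.raises(ParseError, match="line 1"):
            read_bedpe(p)

    def test_dot_score_defaults_to_one_with_warning(self, tmp_path):
        p = tmp_path / "dot.bedpe"
        p.write_text("chr1\t99\t200\tchr1\t499\t600\t.\t.\t.\t.\n")
        with pytest.warns(UserWarning, match="non-integer score"):
            iset = read_bedpe(p)
        assert iset.counts == [1]


class TestHomer:
    def test_header_only_gives_empty_set(self, tmp_path):
        p = tmp_path / "h.txt"
        write_homer_fixture(make_interaction_set([], [], []), p)
        assert len(read_homer_interactions(p)) == 0

    def test_fixture_round_trip_counts_and_fdr(self, tmp_path):
        iset, _ = generate_interactions(FixtureConfig(seed=3, n_interactions=3))
        p = tmp_path / "h.txt"
        write_homer_fixture(iset, p)
        back = read_homer_interactions(p)
        assert len(back) == 3
        assert back.counts == iset.counts
        assert back.anchor_one == [
            GenomicRange(a.chrom, a.start, a.end) for a in iset.anchor_one
        ]
        assert back.metadata["fdr"] == pytest.approx(iset.metadata["fdr"])

    def test_fdr_column_passes_through(self, tmp_path):
        p = tmp_path / "h.txt"
        header = "\t".join(
            ["ID", "chr(1)", "start(1)", "end(1)", "chr(2)", "start(2)",
             "end(2)", "Interaction Reads", "FDR"]
        )
        p.write_text(
            header + "\nx\tchr1\t100\t200\tchr1\t500\t600\t7\t0.04\n"
        )
        iset = read_homer_interactions(p)
        assert iset.metadata["fdr"] == [0.04]
        assert iset.counts == [7]

    def test_missing_required_column_named(self, tmp_path):
        p = tmp_path / "h.txt"
        p.write_text("chr(1)\tstart(1)\tend(1)\tchr(2)\tstart(2)\tend(2)\n")
        with pytest.raises(ParseError, match="interaction reads"):
            read_homer_interactions(p)


class TestChiapetTool:
    def test_fixture_round_trip(self, tmp_path):
        iset, _ = generate_interactions(FixtureConfig(seed=4, n_interactions=4))
        p = tmp_path / "c.txt"
        write_chiapet_fixture(iset, p)
        back = read_chiapet_tool(p)
        assert len(back) == 4
        assert sum(back.counts) == sum(iset.counts)
        assert back.metadata["p_value"] == pytest.approx(iset.metadata["p_value"])

    def test_significance_filter_on_read_back(self, tmp_path):
        iset = make_interaction_set(
            [GenomicRange("chr1", 100, 200)],
            [GenomicRange("chr1", 900, 1000)],
            [3],
            {"p_value": [0.001], "fdr": [0.01]},
        )
        p = tmp_path / "c.txt"
        write_chiapet_fixture(iset, p)
        kept = subset(read_chiapet_tool(p), "counts > 2 AND fdr < 0.05")
        assert len(kept) == 1

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("")
        assert len(read_chiapet_tool(p)) == 0

    def test_zero_based_flag_shifts_starts(self, tmp_path):
        p = tmp_path / "c.txt"
        p.write_text("chr1\t99\t200\tchr1\t499\t600\t3\t0.01\t0.02\n")
        iset = read_chiapet_tool(p, zero_based=True)
        assert iset.anchor_one[0].start == 100


class TestBed12:
    def test_block_arithmetic(self, tmp_path):
        iset = make_interaction_set(
            [GenomicRange("chr1", 100, 200)],
            [GenomicRange("chr1", 500, 600)],
            [5],
        )
        p = tmp_path / "o.bed"
        export_bed12(iset, p)
        f = p.read_text().strip().split("\t")
        assert f[1] == "99" and f[2] == "600"
        assert f[9] == "2"
        assert f[10] == "101,101" and f[11] == "0,400"

    def test_trans_pairs_skipped_with_warning(self, tmp_path):
        iset = make_interaction_set(
            [GenomicRange("chr1", 100, 200), GenomicRange("chr1", 100, 200)],
            [GenomicRange("chr1", 500, 600), GenomicRange("chr2", 500, 600)],
            [1, 1],
        )
        p = tmp_path / "o.bed"
        with pytest.warns(UserWarning, match="skipped 1"):
            skipped = export_bed12(iset, p)
        assert skipped == 1
        assert len(p.read_text().splitlines()) == 1

    def test_score_clamped_and_counts_in_name(self, tmp_path):
        iset = make_interaction_set(
            [GenomicRange("chr1", 100, 200)],
            [GenomicRange("chr1", 500, 600)],
            [5000],
        )
        p = tmp_path / "o.bed"
        export_bed12(iset, p)
        f = p.read_text().strip().split("\t")
        assert f[4] == "1000"
        assert f[3].endswith("_5000")

    def test_ucsc_block_consistency_on_random_sets(self, tmp_path):
        iset = random_interaction_set(seed=40, n=500)
        p = tmp_path / "o.bed"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            export_bed12(iset, p)
        lines = p.read_text().splitlines()
        assert lines
        for line in lines:
            f = line.split("\t")
            chrom_start, chrom_end = int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].split(",")]
            starts = [int(x) for x in f[11].split(",")]
            assert int(f[9]) == 2 and len(sizes) == 2 == len(starts)
            assert starts[0] == 0
            assert starts[1] + sizes[1] == chrom_end - chrom_start
            assert starts[1] >= starts[0] + sizes[0]  # blocks must not overlap


class TestGraphExport:
    def test_simple_edges(self, tmp_path):
        A, B, C = (
            GenomicRange("chr1", 1, 10),
            GenomicRange("chr1", 100, 110),
            GenomicRange("chr2", 1, 10),
        )
        iset = make_interaction_set([A, B], [B, C], [3, 2])
        p = tmp_path / "g.tsv"
        stats = export_graph(iset, p)
        assert stats == {"nodes": 3, "edges": 2}
        lines = p.read_text().splitlines()
        assert lines[0].split("\t")[:3] == ["node1", "node2", "weight"]

    def test_parallel_edges_merge_weights(self, tmp_path):
        A, B = GenomicRange("chr1", 1, 10), GenomicRange("chr1", 100, 110)
        iset = make_interaction_set([A, B], [B, A], [3, 4])
        p = tmp_path / "g.tsv"
        stats = export_graph(iset, p)
        assert stats == {"nodes": 2, "edges": 1}
        weight = int(p.read_text().splitlines()[1].split("\t")[2])
        assert weight == 7

    def test_matches_brute_force_dictionary_build(self, tmp_path):
        iset = random_interaction_set(seed=41, n=500)
        p = tmp_path / "g.tsv"
        stats = export_graph(iset, p)
        edges = {}
        nodes = set()
        for a, b, c in zip(iset.anchor_one, iset.anchor_two, iset.counts):
            ka, kb = str(a), str(b)
            nodes.update((ka, kb))
            key = tuple(sorted((ka, kb)))
            edges[key] = edges.get(key, 0) + c
        assert stats == {"nodes": len(nodes), "edges": len(edges)}
        got = {}
        for line in p.read_text().splitlines()[1:]:
            f = line.split("\t")
            got[(f[0], f[1])] = int(f[2])
        assert got == edges

    def test_feature_id_mode_requires_annotation(self, tmp_path):
        iset = random_interaction_set(seed=42, n=10)
        with pytest.raises(Exception, match="annotat"):
            export_graph(iset, tmp_path / "g.tsv", node_by="feature_id")


class TestDialectInterchange:
    def test_any_dialect_to_bedpe_and_back(self, tmp_path):
        iset, _ = generate_interactions(FixtureConfig(seed=5, n_interactions=50))
        iset = iset.sort()
        homer = tmp_path / "h.txt"
        write_homer_fixture(iset, homer)
        via_homer = read_homer_interactions(homer)
        bedpe = tmp_path / "x.bedpe"
        write_bedpe(via_homer, bedpe)
        back = read_bedpe(bedpe)
        assert back.counts == via_homer.sort().counts
        assert back.anchor_one == via_homer.sort().anchor_one
        assert back.metadata["fdr"] == pytest.approx(
            via_homer.sort().metadata["fdr"]
        )


class TestTagPairIO:
    def test_bedpe_round_trip(self, tmp_path):
        from chromlink.fixtures import generate_tag_pairs
        from chromlink.io import write_tag_pairs_bedpe

        pairs = generate_tag_pairs(FixtureConfig(seed=6, n_tag_pairs=100))
        p = tmp_path / "t.bedpe"
        write_tag_pairs_bedpe(pairs, p)
        back = read_tag_pairs_bedpe(p)
        assert back == pairs

    def test_indefinite_strand_rejected(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t99\t200\tchr1\t499\t600\t.\t1\t.\t+\n")
        with pytest.raises(ParseError, match="line 1"):
            read_tag_pairs_bedpe(p)

    def test_sam_pairs(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t99\tchr1\t101\t60\t50M\t=\t401\t350\t"
            + "A" * 50 + "\t" + "I" * 50 + "\n"
            "r1\t147\tchr1\t401\t60\t50M\t=\t101\t-350\t"
            + "A" * 50 + "\t" + "I" * 50 + "\n"
        )
        pairs = read_tag_pairs_sam(sam)
        assert len(pairs) == 1
        assert pairs[0].end1.start == 101 and pairs[0].end1.strand == "+"
        assert pairs[0].end2.start == 401 and pairs[0].end2.strand == "-"
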