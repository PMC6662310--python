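"""Chromatin network construction and regulator assignment."""

import numpy as np
import pytest

from conftest import (
    brute_force_loop_assignment,
    brute_force_proximity,
    random_regulome,
)
from tripath.graph_model import GeneAnnotation, TableParseError
from tripath.noncoding import (
    GenomicInterval,
    Loop,
    assign_by_loops,
    assign_by_proximity,
    build_network,
    count_regulators,
    read_bed,
    read_bedpe,
    write_bed,
    write_bedpe,
)
from tripath.scoring import ParameterError


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


class TestIntervals:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            iv(100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)


class TestBuildNetwork:
    def test_disjoint_anchors(self):
        net = build_network([Loop(iv(100, 200), iv(500, 600))])
        assert len(net.nodes) == 2 and len(net.edges) == 1

    def test_overlapping_left_anchors_merge(self):
        loops = [
            Loop(iv(100, 200), iv(500, 600)),
            Loop(iv(150, 250), iv(900, 950)),
        ]
        net = build_network(loops)
        assert iv(100, 250) in net.nodes
        assert len(net.nodes) == 3 and len(net.edges) == 2

    def test_self_overlapping_loop_becomes_self_edge(self):
        net = build_network([Loop(iv(100, 300), iv(200, 400))])
        assert net.nodes == [iv(100, 400)]
        assert net.edges == [(0, 0)]

    def test_interchromosomal_loops_retained(self):
        net = build_network([Loop(iv(0, 100), iv(0, 100, chrom="chr2"))])
        assert len(net.nodes) == 2 and len(net.edges) == 1

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(5)
        loops, _, _ = random_regulome(rng, 30, 0, 0)
        net = build_network(loops)
        renet = build_network([Loop(n, n) for n in net.nodes])
        assert sorted(renet.nodes) == sorted(net.nodes)

    def test_zero_loops_rejected(self):
        with pytest.raises(ParameterError):
            build_network([])


class TestAssignByLoops:
    def setup_method(self):
        self.genes = {"G": GeneAnnotation("G", "chr1", 150, "+")}

    def test_direct_neighbor_assigned(self):
        net = build_network([Loop(iv(100, 200), iv(5000, 5200))])
        asg = assign_by_loops(net, self.genes, [iv(5050, 5100)], promoter_window=100)
        assert asg.regions("G") == {iv(5050, 5100)}
        assert asg.provenance("G", iv(5050, 5100)) == "loop"

    def test_same_node_assigned(self):
        net = build_network([Loop(iv(100, 400), iv(9000, 9100))])
        asg = assign_by_loops(net, self.genes, [iv(300, 350)], promoter_window=100)
        assert asg.regions("G") == {iv(300, 350)}

    def test_hops_gate_two_step_paths(self):
        loops = [
            Loop(iv(100, 200), iv(5000, 5200)),
            Loop(iv(5100, 5300), iv(9000, 9200)),
        ]
        net = build_network(loops)
        far = [iv(9050, 9100)]
        one = assign_by_loops(net, self.genes, far, promoter_window=100, hops=1)
        two = assign_by_loops(net, self.genes, far, promoter_window=100, hops=2)
        assert one.count("G") == 0
        assert two.regions("G") == set(far)

    def test_detached_promoter_gets_nothing(self):
        net = build_network([Loop(iv(900_000, 900_100), iv(950_000, 950_100))])
        asg = assign_by_loops(net, self.genes, [iv(950_050, 950_090)])
        assert asg.count("G") == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        loops, regions, genes = random_regulome(rng, int(rng.integers(2, 30)), 15, 6)
        hops = int(rng.integers(1, 3))
        w = int(rng.integers(0, 500))
        net = build_network(loops)
        asg = assign_by_loops(net, genes, regions, promoter_window=w, hops=hops)
        oracle = brute_force_loop_assignment(loops, genes, regions, w, hops)
        assert {g: asg.regions(g) for g in asg.genes() if asg.count(g)} == oracle

    def test_hops_monotonicity(self):
        rng = np.random.default_rng(77)
        loops, regions, genes = random_regulome(rng, 25, 15, 6)
        net = build_network(loops)
        prev: dict = {}
        for hops in (1, 2, 3):
            asg = assign_by_loops(net, genes, regions, promoter_window=300, hops=hops)
            for g, regs in prev.items():
                assert regs <= asg.regions(g)
            prev = {g: asg.regions(g) for g in asg.genes()}


class TestAssignByProximity:
    def setup_method(self):
        self.genes = {"G": GeneAnnotation("G", "chr1", 1000, "+")}

    def test_closest_edge_distance(self):
        region = [iv(1500, 1600)]
        assert assign_by_proximity(self.genes, region, 600).count("G") == 1
        assert assign_by_proximity(self.genes, region, 400).count("G") == 0

    def test_region_covering_tss(self):
        assert assign_by_proximity(self.genes, [iv(900, 1100)], 1).count("G") == 1

    def test_other_chromosome_ignored(self):
        assert assign_by_proximity(self.genes, [iv(900, 1100, "chr2")], 10_000).count("G") == 0

    def test_invalid_distance(self):
        with pytest.raises(ParameterError):
            assign_by_proximity(self.genes, [], 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        _, regions, genes = random_regulome(rng, 2, 20, 8)
        d = int(rng.integers(1, 2000))
        asg = assign_by_proximity(genes, regions, d)
        oracle = brute_force_proximity(genes, regions, d)
        assert {g: asg.regions(g) for g in asg.genes() if asg.count(g)} == oracle

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        _, regions, genes = random_regulome(rng, 2, 20, 8)
        shift = 12_345
        genes2 = {
            g: GeneAnnotation(g, a.chrom, a.tss + shift, a.strand) for g, a in genes.items()
        }
        regions2 = [GenomicInterval(r.chrom, r.start + shift, r.end + shift) for r in regions]
        a = assign_by_proximity(genes, regions, 800)
        b = assign_by_proximity(genes2, regions2, 800)
        for g in genes:
            assert {(r.chrom, r.start + shift, r.end + shift) for r in a.regions(g)} == {
                (r.chrom, r.start, r.end) for r in b.regions(g)
            }

    def test_distance_monotonicity(self):
        rng = np.random.default_rng(9)
        _, regions, genes = random_regulome(rng, 2, 20, 8)
        prev: dict = {}
        for d in (200, 800, 3000):
            asg = assign_by_proximity(genes, regions, d)
            for g, regs in prev.items():
                assert regs <= asg.regions(g)
            prev = {g: asg.regions(g) for g in asg.genes()}


class TestCounting:
    def test_distinct_regions_counted(self):
        from tripath.noncoding import RegulatorAssignment

        a = RegulatorAssignment()
        for k in range(3):
            a.add("G", iv(1000 * k, 1000 * k + 100), "loop")
        assert count_regulators(a, "G") == 3
        assert count_regulators(a, "other") == 0

    def test_duplicate_region_counted_once(self):
        from tripath.noncoding import RegulatorAssignment

        a = RegulatorAssignment()
        a.add("G", iv(0, 100), "loop")
        a.add("G", iv(0, 100), "loop")
        assert count_regulators(a, "G") == 1


class TestBedIO:
    def test_bedpe_round_trip(self, tmp_path):
        loops = [
            Loop(iv(100, 200), iv(500, 600), score=7.0),
            Loop(iv(0, 50, "chr2"), iv(80, 120), score=None),
        ]
        path = tmp_path / "loops.bedpe"
        write_bedpe(loops, path)
        again = read_bedpe(path)
        assert [(l.anchor_a, l.anchor_b, l.score) for l in again] == [
            (l.anchor_a, l.anchor_b, l.score) for l in loops
        ]

    def test_bed_round_trip_with_header(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("track name=test\n# comment\nchr1\t10\t20\nchr1\t30\t40\textra\n")
        assert read_bed(path) == [iv(10, 20), iv(30, 40)]

    def test_malformed_bedpe_reports_line(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t10\t20\tchr1\n")
        with pytest.raises(TableParseError, match=":1:"):
            read_bedpe(path)
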