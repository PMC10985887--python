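"""Junction extraction, clustering, assembly and NUMT calling."""

import numpy as np
import pytest

import mitovar as mv
from mitovar import fnumt
from mitovar.fnumt import (
    JunctionRead, NumtCall, align_contig_to_mt, assemble_numt_contig,
    breakpoint_distance, classify_origin, cluster_junctions,
    count_discordant_support, estimate_zygosity, extract_junction_reads,
)
from mitovar.simulate import NumtSimConfig, plant_numt


@pytest.fixture(scope="module")
def fixture_numt(mt_ref):
    cfg = NumtSimConfig(mt_start=4000, mt_end=4500, zygosity="hom",
                        n_mismatches=2)
    reads, nuclear, truth = plant_numt(mt_ref, cfg, seed=42)
    return cfg, reads, nuclear, truth


class TestExtraction:
    def test_both_orientations_found(self, fixture_numt, mt_ref):
        _, reads, nuclear, truth = fixture_numt
        junctions = extract_junction_reads(reads, mt_ref,
                                           {nuclear.name: nuclear})
        sides = {j.side for j in junctions}
        assert sides == {"start", "end"}
        starts = [j for j in junctions if j.side == "start"]
        assert {j.mt_coord for j in starts} == {truth.mt_start}
        assert {j.nuclear_bp for j in starts} == {truth.bp_left}

    def test_fully_mapped_read_is_not_a_junction(self, mt_ref, read_factory):
        read = read_factory(100, "A" * 150, contig="chr1")
        nuclear = mv.CircularReference.random_nuclear(1, 2000, "chr1")
        assert extract_junction_reads([read], mt_ref,
                                      {"chr1": nuclear}) == []

    def test_short_clip_excluded(self, fixture_numt, mt_ref, read_factory):
        _, _, nuclear, _ = fixture_numt
        clip = mt_ref.sequence[100:110]          # 10 bp < default minimum
        seq = nuclear.sequence[200:340] + clip
        read = read_factory(201, seq, contig=nuclear.name, cigar="140M10S")
        assert extract_junction_reads([read], mt_ref,
                                      {nuclear.name: nuclear}) == []


class TestClustering:
    def _junction(self, side, bp, mt_coord, i=0):
        return JunctionRead(f"r{side}{bp}{i}", "chr1", bp, mt_coord, side,
                            "SM" if side == "start" else "MS", "+",
                            "A" * 30, "A" * 30)

    def test_both_orientations_give_one_candidate(self):
        js = [self._junction("start", 5000, 4000, i) for i in range(5)]
        js += [self._junction("end", 5001, 4500, i) for i in range(5)]
        cands = cluster_junctions(js)
        assert len(cands) == 1
        c = cands[0]
        assert (c.mt_start, c.mt_end, c.bp_left, c.bp_right) == \
            (4000, 4500, 5000, 5001)
        assert c.segment_size == 500

    def test_single_orientation_discarded(self):
        js = [self._junction("start", 5000, 4000, i) for i in range(8)]
        assert cluster_junctions(js) == []

    def test_two_loci_give_two_candidates(self):
        js = []
        for base in (5000, 15000):
            js += [self._junction("start", base, 4000, i) for i in range(3)]
            js += [self._junction("end", base + 1, 4500, i)
                   for i in range(3)]
        assert len(cluster_junctions(js)) == 2

    def test_strand_conflict_discarded(self):
        js = [self._junction("start", 5000, 4000, i) for i in range(3)]
        ends = [self._junction("end", 5001, 4500, i) for i in range(3)]
        for j in ends:
            j.mt_strand = "-"
        assert cluster_junctions(js + ends) == []


class TestDiscordant:
    def _pair(self, qname, nuc_pos, mt_pos, nuclear="chr1"):
        qual = np.full(150, 37, dtype=np.uint8)
        return mv.AlignedRead(qname, nuclear, nuc_pos, 60, "150M",
                              "A" * 150, qual, mate_contig="chrM",
                              mate_pos=mt_pos, is_proper_pair=False)

    def _candidate(self):
        return NumtCall(mt_start=4000, mt_end=4500, segment_size=500,
                        nuclear_contig="chr1", bp_left=5000, bp_right=5001,
                        n_junction_start=3, n_junction_end=3)

    def test_planted_pairs_counted(self):
        reads = [self._pair(f"p{i}", 4800 + i, 4100 + i) for i in range(8)]
        assert count_discordant_support(reads, self._candidate()) == 8

    def test_distant_mate_not_counted(self):
        reads = [self._pair("far", 105_000, 4100)]
        assert count_discordant_support(reads, self._candidate()) == 0

    def test_mate_outside_segment_not_counted(self):
        reads = [self._pair("off", 4800, 9000)]
        assert count_discordant_support(reads, self._candidate()) == 0


class TestZygosity:
    def test_full_fraction_is_homozygous(self):
        z, f = estimate_zygosity(None, 30, 30.0)
        assert (z, f) == ("hom", 1.0)

    def test_half_fraction_is_heterozygous(self):
        z, f = estimate_zygosity(None, 15, 30.0)
        assert (z, f) == ("het", 0.5)

    def test_zero_coverage_errors(self):
        with pytest.raises(ValueError):
            estimate_zygosity(None, 10, 0.0)


class TestAssembly:
    def test_tiled_reads_reassemble_template(self, mt_ref):
        template = mt_ref.segment(6000, 6400)
        reads = [template[s:s + 150] for s in range(0, 251, 50)]
        contig, assembled = assemble_numt_contig(reads)
        assert assembled
        assert contig == template

    def test_identical_pair_returns_the_sequence(self):
        seq = "ACGT" * 20
        contig, assembled = assemble_numt_contig([seq, seq])
        assert contig == seq and assembled

    def test_disjoint_sequences_flagged_unassembled(self, mt_ref):
        a = mt_ref.segment(1000, 1150)
        b = mt_ref.segment(9000, 9150)
        contig, assembled = assemble_numt_contig([a, b])
        assert not assembled
        assert contig in (a, b)


class TestContigAlignment:
    def test_exact_segment_has_no_mismatches(self, mt_ref):
        placement = align_contig_to_mt(mt_ref.segment(7000, 7400), mt_ref)
        assert placement is not None
        assert placement.mismatches == ()
        assert (placement.mt_first, placement.mt_last) == (7001, 7400)

    def test_planted_substitutions_recovered_exactly(self, mt_ref):
        seg = list(mt_ref.segment(7000, 7400))
        for off in (55, 200):
            seg[off] = "A" if seg[off] != "A" else "G"
        placement = align_contig_to_mt("".join(seg), mt_ref)
        got = {(p, obs) for p, _, obs in placement.mismatches}
        want = {(7001 + off, seg[off]) for off in (55, 200)}
        assert got == want

    def test_origin_spanning_contig_placed_on_unrolled_reference(self,
                                                                 mt_ref):
        contig = mt_ref.segment(16400, 200)   # wraps the origin
        contig = contig.replace("N", "A")
        placement = align_contig_to_mt(contig, mt_ref)
        assert placement is not None
        assert placement.mt_first == 16401
        assert placement.mt_last == 200
        assert placement.mt_first > placement.mt_last

    def test_foreign_sequence_rejected(self, mt_ref):
        rng = np.random.default_rng(0)
        junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert align_contig_to_mt(junk, mt_ref) is None


class TestOriginClassification:
    def _call(self, bp_left):
        return NumtCall(mt_start=100, mt_end=600, segment_size=500,
                        nuclear_contig="chr1", bp_left=bp_left,
                        bp_right=bp_left + 1, n_junction_start=3,
                        n_junction_end=3)

    def test_nearby_breakpoints_are_germline(self):
        out = classify_origin([self._call(5000)], [self._call(5003)])
        assert [o[0] for o in out] == ["germline"]

    def test_tumor_only_is_somatic(self):
        out = classify_origin([self._call(5000)], [])
        assert [o[0] for o in out] == ["somatic"]

    def test_distant_sites_are_distinct_events(self):
        out = classify_origin([self._call(5000)], [self._call(5500)])
        assert sorted(o[0] for o in out) == ["loss", "somatic"]


class TestBreakpointDistance:
    def _call(self, mt_start=4000, mt_end=4500, bp_left=5000, bp_right=5001):
        return NumtCall(mt_start=mt_start, mt_end=mt_end, segment_size=500,
                        nuclear_contig="chr1", bp_left=bp_left,
                        bp_right=bp_right, n_junction_start=3,
                        n_junction_end=3)

    def test_identical_call_distances_zero(self):
        assert breakpoint_distance(self._call(), self._call()) == \
            [0, 0, 0, 0]

    def test_two_bp_offset_on_one_nuclear_side(self):
        call = self._call(bp_right=5003)
        assert sorted(breakpoint_distance(call, self._call())) == \
            [0, 0, 0, 2]

    def test_circular_metric_at_origin(self):
        call = self._call(mt_start=16569)
        truth = self._call(mt_start=1)
        assert breakpoint_distance(call, truth)[0] == 1

    def test_unmatched_errors(self):
        with pytest.raises(ValueError):
            breakpoint_distance(None, self._call())


class TestEndToEnd:
    def test_pipeline_recovers_planted_numt(self, fixture_numt, mt_ref):
        cfg, reads, nuclear, truth = fixture_numt
        calls, fps = fnumt.call_numts(reads, mt_ref,
                                      {nuclear.name: nuclear},
                                      mean_autosomal_coverage=cfg.depth)
        assert len(calls) == 1
        call = calls[0]
        assert breakpoint_distance(call, truth) == [0, 0, 0, 0]
        assert call.zygosity == "hom"
        assert call.n_discordant > 0
        got = {(f.mt_pos, f.obs) for f in fps}
        want = {(p, obs) for p, _, obs in truth.mismatches}
        assert got == want

    def test_no_mismatches_planted_means_none_reported(self, mt_ref):
        cfg = NumtSimConfig(mt_start=9000, mt_end=9400, zygosity="het")
        reads, nuclear, truth = plant_numt(mt_ref, cfg, seed=17)
        calls, fps = fnumt.call_numts(reads, mt_ref,
                                      {nuclear.name: nuclear},
                                      mean_autosomal_coverage=cfg.depth)
        assert len(calls) == 1 and fps == []

    def test_single_orientation_artifact_yields_no_call(self, fixture_numt,
                                                        mt_ref):
        """Reads clipped on only one breakpoint side never become a NUMT."""
        _, reads, nuclear, _ = fixture_numt
        junctions = extract_junction_reads(reads, mt_ref,
                                           {nuclear.name: nuclear})
        start_ids = {j.read_id for j in junctions if j.side == "start"}
        one_sided = [r for r in reads
                     if not ("S" in r.cigar and r.qname not in start_ids)]
        calls, _ = fnumt.call_numts(one_sided, mt_ref,
                                    {nuclear.name: nuclear},
                                    mean_autosomal_coverage=30)
        assert calls == []
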