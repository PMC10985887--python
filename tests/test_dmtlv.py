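"""Likelihood machinery, consensus construction and the two-round caller."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitovar as mv
from mitovar import dmtlv
from mitovar.dmtlv import (
    AlleleObservation, PcrModel, PileupColumn, allele_likelihood,
    build_consensus, build_read_families, combined_quality, lrt_allele,
    lrt_grid_oracle, merge_callsets, pcr_error_rate, select_indel,
)
from mitovar.reference import VariantCall


def make_column(k, n, e, g="G", ref="A"):
    obs = [AlleleObservation(g, e) for _ in range(k)]
    obs += [AlleleObservation(ref, e) for _ in range(n - k)]
    return PileupColumn(100, ref, obs)


class TestAlleleLikelihood:
    def test_certain_allele_without_error(self):
        assert allele_likelihood("G", 1e-9, 1.0) == pytest.approx(1.0)

    def test_pure_error_term(self):
        assert allele_likelihood("G", 0.003, 0.0) == pytest.approx(0.001)

    def test_mixed_fraction(self):
        # (1 - 0.001) * 0.5 + (0.001 / 3) * 0.5
        assert allele_likelihood("G", 0.001, 0.5) == \
            pytest.approx(0.49966667, abs=1e-7)

    @pytest.mark.parametrize("e,theta", [(0.0, 0.5), (1.0, 0.5),
                                         (0.01, -0.1), (0.01, 1.1)])
    def test_out_of_range_arguments(self, e, theta):
        with pytest.raises(ValueError):
            allele_likelihood("G", e, theta)

    @given(st.floats(1e-6, 0.5), st.floats(0.0, 1.0))
    def test_probability_bounds(self, e, theta):
        p = allele_likelihood("G", e, theta)
        assert 0.0 <= p <= 1.0


class TestLrt:
    def test_no_support_is_null(self):
        res = lrt_allele(make_column(0, 100, 1e-3), "G")
        assert (res.theta_hat, res.t, res.p_value) == (0.0, 0.0, 1.0)
        assert not res.passed

    def test_empty_column_errors(self):
        with pytest.raises(ValueError):
            lrt_allele(PileupColumn(1, "A", []), "G")

    def test_strong_support_rejects_null(self):
        res = lrt_allele(make_column(500, 1000, 1e-3), "G")
        assert res.passed
        assert res.p_value < 1e-200
        assert res.theta_hat == pytest.approx(0.5, abs=0.01)

    def test_optimizer_matches_grid_search(self):
        """Bounded optimiser vs exhaustive grid on small random columns."""
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(1, 21))
            k = int(rng.integers(0, n + 1))
            e = float(rng.uniform(1e-4, 0.02))
            col = make_column(k, n, e)
            res = lrt_allele(col, "G")
            theta_g, t_g = lrt_grid_oracle(col, "G")
            assert abs(res.theta_hat - theta_g) <= 1e-3
            assert abs(res.t - t_g) <= 1e-3

    def test_statistic_monotone_in_support(self):
        ts = [lrt_allele(make_column(k, 100, 0.005), "G").t
              for k in range(0, 20)]
        assert all(b >= a - 1e-9 for a, b in zip(ts, ts[1:]))

    def test_boundary_mixture_halves_tail(self):
        col = make_column(3, 100, 0.005)
        mixed = lrt_allele(col, "G", boundary_mix=True)
        plain = lrt_allele(col, "G", boundary_mix=False)
        assert mixed.p_value == pytest.approx(plain.p_value / 2)


class TestPcrModel:
    def test_zero_per_cycle_error(self):
        assert pcr_error_rate(0.0, 12) == 0.0

    def test_zero_cycles(self):
        assert pcr_error_rate(1e-6, 0) == 0.0

    def test_coalescent_rate_value(self):
        assert pcr_error_rate(1e-6, 10) == \
            pytest.approx(1.0225e-3, rel=1e-3)

    def test_negative_cycles_error(self):
        with pytest.raises(ValueError):
            pcr_error_rate(1e-6, -1)

    def test_overall_rate_scales_with_templates(self):
        model = PcrModel(cycles=12, per_cycle_error=1e-6)
        assert model.p_pcr(4) == pytest.approx(4 * model.e_pcr ** 2)


class TestCombinedQuality:
    @pytest.mark.parametrize("total,q,ch", [(0.1, 10, "+"),
                                            (1e-3, 30, "?"),
                                            (1.0, 0, "!")])
    def test_phred_encoding(self, total, q, ch):
        assert combined_quality(total, 0.0) == (q, ch)

    def test_nonpositive_sum_errors(self):
        with pytest.raises(ValueError):
            combined_quality(0.0, 0.0)


class TestReadFamilies:
    def test_pairs_sharing_coordinates_group(self, read_factory):
        reads = []
        for name, p1, p2 in [("a", 10, 200), ("b", 10, 200),
                             ("c", 10, 250), ("d", 30, 200)]:
            reads.append(read_factory(p1, "ACGTACGTAC", qname=name))
            reads.append(read_factory(p2, "ACGTACGTAC", qname=name,
                                      is_reverse=True))
        fams = build_read_families(reads)
        assert len(fams) == 3
        assert sorted(f.n_fragments for f in fams) == [1, 1, 2]

    def test_unique_coordinates_give_one_family_per_pair(self, read_factory):
        reads = []
        for i in range(5):
            reads.append(read_factory(10 + i, "ACGTACGTAC", qname=f"r{i}"))
            reads.append(read_factory(200 + i, "ACGTACGTAC", qname=f"r{i}",
                                      is_reverse=True))
        assert len(build_read_families(reads)) == 5

    def test_duplicates_are_signal_not_noise(self, read_factory):
        reads = []
        for name in ("a", "b"):
            reads.append(read_factory(10, "ACGTACGTAC", qname=name,
                                      is_duplicate=name == "b"))
            reads.append(read_factory(200, "ACGTACGTAC", qname=name,
                                      is_duplicate=name == "b",
                                      is_reverse=True))
        fams = build_read_families(reads)
        assert len(fams) == 1 and fams[0].n_fragments == 2

    def test_unpaired_reads_form_singletons(self, read_factory):
        reads = [read_factory(10, "ACGTACGTAC", qname=f"s{i}",
                              is_paired=False) for i in range(3)]
        assert len(build_read_families(reads)) == 3


class TestConsensus:
    def _passed(self, length, entries=()):
        passed = np.zeros((length, 4), dtype=bool)
        for pos, code in entries:
            passed[pos - 1, code] = True
        return passed

    def test_concordant_family_reproduces_read(self, read_factory, mt_ref):
        seq = mt_ref.sequence[9:19]
        fam = build_read_families(
            [read_factory(10, seq, qname=f"r", is_reverse=i % 2 == 1)
             for i in range(2)] * 1)[0]
        cons = build_consensus(fam, self._passed(mt_ref.length), mt_ref)
        assert len(cons) == 1
        assert cons[0].base_string() == seq
        # two agreeing members combine their error probabilities
        assert cons[0].quals[0] > 35

    def test_failed_allele_masked_to_n(self, read_factory, mt_ref):
        seq = list(mt_ref.sequence[9:19])
        seq[3] = "A" if seq[3] != "A" else "C"
        seq = "".join(seq)
        fam = build_read_families([read_factory(10, seq, qname="r")])[0]
        cons = build_consensus(fam, self._passed(mt_ref.length), mt_ref)
        assert cons[0].base_string()[3] == "N"

    def test_retained_allele_survives(self, read_factory, mt_ref):
        seq = list(mt_ref.sequence[9:19])
        alt = "A" if seq[3] != "A" else "C"
        seq[3] = alt
        seq = "".join(seq)
        fam = build_read_families([read_factory(10, seq, qname="r")])[0]
        passed = self._passed(mt_ref.length, [(13, "ACGT".index(alt))])
        cons = build_consensus(fam, passed, mt_ref)
        assert cons[0].base_string() == seq

    def test_discordant_passing_alleles_split_family(self, read_factory,
                                                     mt_ref):
        ref_seq = mt_ref.sequence[9:19]
        alt = "A" if ref_seq[3] != "A" else "C"
        alt_seq = ref_seq[:3] + alt + ref_seq[4:]
        reads = [read_factory(10, ref_seq, qname="a"),
                 read_factory(10, ref_seq, qname="b"),
                 read_factory(10, alt_seq, qname="c")]
        for read in reads:
            read.is_paired = False
        fam = build_read_families(reads)
        assert len(fam) == 3  # unpaired -> singletons; force one family
        family = dmtlv.ReadFamily(("t",), reads, n_fragments=3)
        passed = self._passed(mt_ref.length, [(13, "ACGT".index(alt))])
        cons = build_consensus(family, passed, mt_ref)
        assert len(cons) == 2
        assert sorted(c.n_members for c in cons) == [1, 2]


class TestSelectIndel:
    def _cons_with(self, indels):
        return dmtlv.ConsensusSequence(
            family_key=("x",), positions=np.array([5]),
            bases=np.array([0], dtype=np.uint8), errors=np.array([1e-3]),
            quals=np.array([30], dtype=np.uint8),
            strands=np.array([0], dtype=np.uint8),
            n_members=1, n_fragments=1, indels=indels)

    def test_max_support_wins(self):
        consensi = [self._cons_with([(5, "INS", "A")]) for _ in range(5)]
        consensi += [self._cons_with([(5, "INS", "AA")]) for _ in range(2)]
        sel = select_indel(5, consensi)
        assert (sel.kind, sel.alt, sel.support) == ("INS", "A", 5)

    def test_no_indels_gives_none(self):
        assert select_indel(5, [self._cons_with([])]) is None

    def test_tie_breaks_deterministically(self):
        consensi = [self._cons_with([(5, "DEL", 1)]) for _ in range(3)]
        consensi += [self._cons_with([(5, "INS", "G")]) for _ in range(3)]
        sel = select_indel(5, consensi)
        # '-' sorts before 'G': the deletion wins every run
        assert (sel.kind, sel.support) == ("DEL", 3)


class TestMergeCallsets:
    def _call(self, pos, vaf, ref="A", alt="G", source="x"):
        return VariantCall("chrM", pos, ref, alt, "SNV", vaf, source=source)

    def test_disjoint_union(self):
        low = [self._call(10, 0.005)]
        high = [self._call(20, 0.3)]
        merged = merge_callsets(low, high, cutoff=0.01)
        assert {c.pos for c in merged} == {10, 20}

    def test_same_locus_prefers_high_vaf_set(self):
        low = [self._call(10, 0.009, source="low")]
        high = [self._call(10, 0.02, source="high")]
        merged = merge_callsets(low, high, cutoff=0.01)
        assert len(merged) == 1 and merged[0].source == "high"

    def test_zero_cutoff_keeps_only_high(self):
        low = [self._call(10, 0.005)]
        high = [self._call(20, 0.3)]
        merged = merge_callsets(low, high, cutoff=0.0)
        assert {c.pos for c in merged} == {20}

    def test_low_calls_outside_band_dropped(self):
        low = [self._call(10, 0.5), self._call(11, 1e-4)]
        assert merge_callsets(low, [], cutoff=0.01) == []

    def test_conflicting_reference_alleles_error(self):
        low = [self._call(10, 0.005, ref="A")]
        high = [self._call(10, 0.02, ref="C")]
        with pytest.raises(ValueError):
            merge_callsets(low, high, cutoff=0.01)


class TestCallerPipeline:
    def test_block_and_read_list_paths_agree(self, mt_ref):
        cfg = mv.VariantSimConfig(vaf=0.2, depth=80)
        block, ledger = mv.simulate_dataset(mt_ref, cfg, seed=3)
        fast = mv.call_variants(block, mt_ref)
        slow = mv.call_variants(list(block.to_reads()), mt_ref)
        assert {c.key() for c in fast} == {c.key() for c in slow}

    def test_all_snvs_have_both_strand_support(self, mt_ref,
                                               shallow_dataset):
        _, block, _ = shallow_dataset
        calls = mv.call_variants(block, mt_ref)
        snvs = [c for c in calls if c.vtype == "SNV"]
        assert snvs
        assert all(c.fwd_support > 0 and c.rev_support > 0 for c in snvs)

    def test_blacklisted_positions_flagged_not_suppressed(self, mt_ref,
                                                          shallow_dataset):
        _, block, _ = shallow_dataset
        calls = mv.call_variants(block, mt_ref)
        # the placeholder base at 3107 always mismatches the reference
        flagged = [c for c in calls if c.pos == 3107]
        assert flagged and all(c.filter == "blacklist" for c in flagged)

    def test_recovers_planted_variants_at_shallow_depth(self, mt_ref,
                                                        shallow_dataset):
        _, block, ledger = shallow_dataset
        calls = mv.call_variants(block, mt_ref)
        metrics = mv.score_calls(calls, ledger)
        assert metrics["SNV"]["f1"] >= 0.85
        assert metrics["SNV"]["ppv"] == 1.0
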