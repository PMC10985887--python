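"""mtCN arithmetic, NUMT-FP / copy-number filters, mutational spectrum."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitovar as mv
from mitovar.filters import (
    collapse_substitution, compute_mtcn, count_spectrum, filter_mtcn_floor,
    filter_numtfp, max_truncating_vaf, numtfp_vaf_threshold, tn_ratio,
)
from mitovar.fnumt import NumtCall, NumtFP
from mitovar.reference import VariantCall


def snv(pos, vaf, ref="A", alt="G"):
    return VariantCall("chrM", pos, ref, alt, "SNV", vaf)


class TestMtcn:
    def test_normal_sample_formula(self):
        assert compute_mtcn(1000, 10, 1.0, 2.0).mtcn == pytest.approx(200.0)

    def test_purity_ploidy_correction(self):
        # purity 0.5, ploidy 4 -> factor 0.5*4 + 0.5*2 = 3
        assert compute_mtcn(1000, 10, 0.5, 4.0).mtcn == pytest.approx(300.0)

    @given(st.floats(1.0, 1e5), st.floats(0.1, 1e3))
    def test_normal_defaults_reduce_to_twice_the_ratio(self, mt_cov, auto):
        rec = compute_mtcn(mt_cov, auto, 1.0, 2.0)
        assert rec.mtcn == pytest.approx(2.0 * mt_cov / auto)

    @pytest.mark.parametrize("kw", [dict(mt_coverage=0),
                                    dict(autosomal_coverage=0),
                                    dict(purity=0.0), dict(purity=1.5),
                                    dict(ploidy=0)])
    def test_invalid_inputs(self, kw):
        args = dict(mt_coverage=1000, autosomal_coverage=10,
                    purity=1.0, ploidy=2.0)
        args.update(kw)
        with pytest.raises(ValueError):
            compute_mtcn(**args)

    def test_tn_ratio(self):
        t = compute_mtcn(1000, 50, 0.8, 2.5, role="tumor")
        n = compute_mtcn(1000, 25, 1.0, 2.0, role="normal")
        assert tn_ratio(t, n).ratio == pytest.approx(t.mtcn / n.mtcn)


class TestNumtFpThreshold:
    def test_het_threshold(self):
        assert numtfp_vaf_threshold(999, "het") == pytest.approx(0.001)

    def test_hom_threshold(self):
        assert numtfp_vaf_threshold(2, "hom") == pytest.approx(0.5)

    @given(st.floats(0.1, 1e5))
    def test_hom_exceeds_het_for_all_mtcn(self, mtcn):
        assert numtfp_vaf_threshold(mtcn, "hom") > \
            numtfp_vaf_threshold(mtcn, "het")


def make_numt(mt_start=1000, mt_end=2000, zygosity="het", assembled=True):
    return NumtCall(mt_start=mt_start, mt_end=mt_end,
                    segment_size=mt_end - mt_start,
                    nuclear_contig="chr1", bp_left=5000, bp_right=5001,
                    n_junction_start=5, n_junction_end=5,
                    zygosity=zygosity, assembled=assembled)


class TestFilterNumtFp:
    """mtCN 999, het -> threshold 0.001."""

    MTCN = 999.0

    def test_mismatch_near_threshold_removed(self):
        numt = make_numt()
        fps = [NumtFP(1500, "A", "G")]
        kept, removed = filter_numtfp([snv(1500, 0.0015)], [numt], fps,
                                      self.MTCN)
        assert kept == [] and len(removed) == 1
        assert "mismatch" in removed[0].reason

    def test_mismatch_far_above_threshold_retained(self):
        # ratio (0.005 - 0.001)/0.001 = 4 >= 1: may be a true variant
        numt = make_numt()
        fps = [NumtFP(1500, "A", "G")]
        kept, removed = filter_numtfp([snv(1500, 0.005)], [numt], fps,
                                      self.MTCN)
        assert len(kept) == 1 and removed == []

    def test_non_mismatch_call_in_assembled_segment_retained(self):
        kept, removed = filter_numtfp([snv(1500, 0.0015)], [make_numt()],
                                      [], self.MTCN)
        assert len(kept) == 1

    def test_call_outside_every_segment_retained(self):
        fps = [NumtFP(1500, "A", "G")]
        kept, _ = filter_numtfp([snv(9000, 0.0001)], [make_numt()], fps,
                                self.MTCN)
        assert len(kept) == 1

    def test_unassembled_segment_uses_vaf_rule_alone(self):
        numt = make_numt(assembled=False)
        kept, removed = filter_numtfp([snv(1500, 0.0015)], [numt], [],
                                      self.MTCN)
        assert kept == [] and "unassembled" in removed[0].reason

    def test_circular_segment_membership(self):
        numt = make_numt(mt_start=16400, mt_end=200)
        fps = [NumtFP(50, "A", "G")]
        kept, removed = filter_numtfp([snv(50, 0.0015)], [numt], fps,
                                      self.MTCN)
        assert kept == []


class TestFilterMtcnFloor:
    def test_below_floor_removed(self):
        kept, removed = filter_mtcn_floor([snv(10, 0.001)], mtcn=500)
        assert kept == [] and len(removed) == 1

    def test_boundary_exactly_at_floor_retained(self):
        kept, removed = filter_mtcn_floor([snv(10, 1 / 500)], mtcn=500)
        assert len(kept) == 1 and removed == []

    def test_high_mtcn_keeps_low_vaf(self):
        kept, _ = filter_mtcn_floor([snv(10, 0.001)], mtcn=10_000)
        assert len(kept) == 1

    def test_idempotent_and_conserving(self):
        calls = [snv(i, v) for i, v in
                 enumerate([0.0005, 0.002, 0.01, 0.3], start=10)]
        kept, removed = filter_mtcn_floor(calls, mtcn=1000)
        assert len(kept) + len(removed) == len(calls)
        again, none = filter_mtcn_floor(kept, mtcn=1000)
        assert again == kept and none == []

    def test_numtfp_filter_idempotent_and_conserving(self):
        numt = make_numt()
        fps = [NumtFP(1500, "A", "G"), NumtFP(1600, "A", "G")]
        calls = [snv(1500, 0.0015), snv(1600, 0.02), snv(8000, 0.001)]
        kept, removed = filter_numtfp(calls, [numt], fps, 999.0)
        assert len(kept) + len(removed) == len(calls)
        again, none = filter_numtfp(kept, [numt], fps, 999.0)
        assert again == kept and none == []


def test_mtcn_floor_removes_depth_dependent_noise():
    """Sub-1/mtCN noise grows with depth; the floor makes counts flat."""
    mtcn = 500.0
    real = [0.01, 0.05, 0.2]
    counts_before, counts_after = [], []
    for depth in (1000, 2000, 4000, 8000):
        noise = [snv(100 + i, 0.5 / mtcn) for i in range(depth // 1000)]
        calls = [snv(5000 + i, v) for i, v in enumerate(real)] + noise
        counts_before.append(len(calls))
        kept, _ = filter_mtcn_floor(calls, mtcn)
        counts_after.append(len(kept))
    depths = [1000, 2000, 4000, 8000]
    assert np.corrcoef(depths, counts_before)[0, 1] > 0.9
    assert len(set(counts_after)) == 1  # depth-independent after filtering


class TestSpectrum:
    def test_purine_substitution_collapses(self):
        assert collapse_substitution("G", "T") == ("C>A", True)
        assert collapse_substitution("C", "T") == ("C>T", False)

    def test_counts_conserve_snvs(self, mt_ref):
        rng = np.random.default_rng(5)
        calls = []
        for pos in rng.integers(10, mt_ref.length - 10, size=10):
            ref = mt_ref.base(int(pos))
            if ref == "N":
                continue
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            calls.append(snv(int(pos), 0.1, ref=ref, alt=alt))
        spec = count_spectrum(calls, mt_ref)
        assert spec.total == len(calls)
        assert sum(spec.contexts.values()) == sum(spec.six.values())

    def test_context_wraps_at_origin(self, mt_ref):
        ref = mt_ref.base(1)
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        spec = count_spectrum([snv(1, 0.1, ref=ref, alt=alt)], mt_ref)
        sub, flipped = collapse_substitution(ref, alt)
        tri = mt_ref.base(mt_ref.length) + ref + mt_ref.base(2)
        if flipped:
            tri = mv.reference.revcomp(tri)
        assert spec.contexts == {f"{tri[0]}[{sub}]{tri[2]}": 1}

    def test_placeholder_context_goes_to_undetermined_bin(self, mt_ref):
        # position 3106 has the 'N' placeholder in its context
        ref = mt_ref.base(3106)
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        spec = count_spectrum([snv(3106, 0.1, ref=ref, alt=alt)], mt_ref)
        assert spec.undetermined == 1 and spec.total == 1


class TestTruncatingVaf:
    def test_absent_flagged_zero(self):
        out = max_truncating_vaf([snv(10, 0.1)], {})
        assert out == {"max_tvaf": 0.0, "mean_tvaf": 0.0, "n": 0,
                       "present": False}

    def test_max_and_mean(self):
        calls = [snv(10, 0.01), snv(20, 0.044), snv(30, 0.9)]
        cons = {(10, "A", "G"): "stop-gain", (20, "A", "G"): "frameshift"}
        out = max_truncating_vaf(calls, cons)
        assert out["max_tvaf"] == pytest.approx(0.044)
        assert out["mean_tvaf"] == pytest.approx(0.027)
        assert out["n"] == 2 and out["present"]

    def test_single_call_max_equals_mean(self):
        out = max_truncating_vaf([snv(10, 0.2)],
                                 {(10, "A", "G"): "stop-gain"})
        assert out["max_tvaf"] == out["mean_tvaf"] == pytest.approx(0.2)
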