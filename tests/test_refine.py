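import copy
import random

import numpy as np
import pytest

from markermap import refine as rf
from markermap.core import (FilterReason, Genotype, StructuralVariant,
                            SVClass, TandemRepeatRegion, VariantCall,
                            VariantClass)

from conftest import random_seq, write_fasta, write_sam


def snp(pos, depth=20, ref_n=None, alt_n=None, genotype=Genotype.ALT_HOM,
        chrom="chr1"):
    if alt_n is None:
        alt_n = depth if genotype is Genotype.ALT_HOM else depth // 2
    if ref_n is None:
        ref_n = 0 if genotype is Genotype.ALT_HOM else depth - alt_n
    return VariantCall(chrom, pos, "A", "C", VariantClass.SNP, depth,
                       ref_n, alt_n, genotype, 60.0)


class TestFilterBySv:
    # deletion interval from a transposed element: 3,728,969-3,730,413 (1-based)
    DEL = StructuralVariant(SVClass.DELETION, "chr1", 3_728_968, 3_730_413,
                            pair_support=20)

    def test_snp_inside_sv_flagged(self):
        calls = [snp(3_729_500)]
        rf.filter_by_sv(calls, [self.DEL], margin=500)
        assert FilterReason.SV_OVERLAP in calls[0].filter_reasons
        assert calls[0].filter_detail["SV_OVERLAP"] == "deletion"

    def test_adjacent_within_margin(self):
        calls = [snp(3_730_413 + 400)]
        rf.filter_by_sv(calls, [self.DEL], margin=500)
        assert calls[0].filter_reasons == {FilterReason.SV_ADJACENT}

    def test_just_past_margin_passes(self):
        calls = [snp(3_730_413 + 501)]       # margin + 1 past the end
        rf.filter_by_sv(calls, [self.DEL], margin=500)
        assert calls[0].is_pass

    def test_empty_sv_list_unchanged(self):
        calls = [snp(3_729_500)]
        rf.filter_by_sv(calls, [], margin=500)
        assert calls[0].is_pass


class TestFilterTandemIndels:
    REPEAT = TandemRepeatRegion("chr1", 99, 119, 2, 10.0, 40)   # (AG)10

    def _het_indel(self, ev):
        call = VariantCall("chr1", 99, "AAG", "A", VariantClass.DELETION,
                           depth=20, ref_support=6, alt_support=14,
                           genotype=Genotype.HET, quality=60.0,
                           tandem_evidence=ev)
        return call

    def test_unit_loss_with_nonspanning_ref_becomes_hom(self):
        # spanning reads unanimously show one AG lost; ref evidence only from
        # reads terminating inside the repeat
        call = self._het_indel({"ref": (0, 6), "alt": (14, 0)})
        rf.filter_tandem_indels([call], [self.REPEAT])
        assert call.genotype is Genotype.ALT_HOM
        assert call.ref_support == 0
        assert call.is_pass
        assert call.tandem_units == -1

    def test_nonspanning_only_alt_flagged(self):
        call = self._het_indel({"ref": (10, 0), "alt": (0, 4)})
        rf.filter_tandem_indels([call], [self.REPEAT])
        assert FilterReason.TANDEM_NONSPAN in call.filter_reasons

    def test_genuine_het_kept(self):
        call = self._het_indel({"ref": (5, 2), "alt": (9, 1)})
        rf.filter_tandem_indels([call], [self.REPEAT])
        assert call.is_pass and call.genotype is Genotype.HET

    def test_non_unit_multiple_not_retyped(self):
        call = VariantCall("chr1", 99, "AAGA", "A", VariantClass.DELETION,
                           depth=20, ref_support=10, alt_support=10,
                           genotype=Genotype.HET, quality=60.0,
                           tandem_evidence={"ref": (5, 0), "alt": (5, 0)})
        rf.filter_tandem_indels([call], [self.REPEAT])
        assert call.tandem_units is None

    def test_indel_outside_repeats_unchanged(self):
        call = VariantCall("chr1", 5000, "AAG", "A", VariantClass.DELETION,
                           depth=20, ref_support=10, alt_support=10,
                           genotype=Genotype.HET, quality=60.0)
        before = copy.deepcopy(call)
        rf.filter_tandem_indels([call], [self.REPEAT])
        assert call.genotype == before.genotype and call.is_pass


def quantile_oracle(values, q):
    """Independent linear-interpolation quantile (textbook formula)."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * q
    lo = int(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestFilterByDepth:
    def _population(self, rng, n=1000, mean=20):
        calls = [snp(10 + 3 * i, depth=max(1, int(rng.gauss(mean, 5))))
                 for i in range(n)]
        return calls

    def test_high_depth_in_top_tail_flagged(self):
        rng = random.Random(0)
        calls = self._population(rng)
        calls.append(snp(99_991, depth=85))   # >= 4 x 20 and in the top tail
        rf.filter_by_depth(calls, 20.0, rf.RefinementConfig())
        assert FilterReason.DEPTH_EXTREME in calls[-1].filter_reasons

    def test_mid_distribution_passes(self):
        rng = random.Random(1)
        calls = self._population(rng)
        calls.append(snp(99_991, depth=21))
        rf.filter_by_depth(calls, 20.0, rf.RefinementConfig())
        assert FilterReason.DEPTH_EXTREME not in calls[-1].filter_reasons

    def test_bottom_tail_flagged_in_independent_mode(self):
        rng = random.Random(2)
        calls = self._population(rng)
        calls.append(snp(99_991, depth=2, alt_n=2, ref_n=0))
        cfg = rf.RefinementConfig(min_support=1, bottom_tail_independent=True)
        rf.filter_by_depth(calls, 20.0, cfg)
        assert FilterReason.DEPTH_EXTREME in calls[-1].filter_reasons

    def test_bottom_tail_conjunctive_by_default(self):
        # the stated rule needs both triggers: a bottom-tail depth cannot
        # also satisfy the fold-excess requirement, so it passes
        rng = random.Random(2)
        calls = self._population(rng)
        calls.append(snp(99_991, depth=2, alt_n=2, ref_n=0))
        rf.filter_by_depth(calls, 20.0, rf.RefinementConfig(min_support=1))
        assert FilterReason.DEPTH_EXTREME not in calls[-1].filter_reasons

    def test_high_depth_outside_tail_not_flagged(self):
        # fold rule alone must not trigger: depth 85 in a distribution whose
        # top tail sits far higher
        calls = [snp(10 + 3 * i, depth=60 + i) for i in range(1000)]
        calls.append(snp(99_991, depth=85))
        rf.filter_by_depth(calls, 20.0, rf.RefinementConfig())
        assert FilterReason.DEPTH_EXTREME not in calls[-1].filter_reasons

    def test_low_support_flagged(self):
        calls = [snp(10, depth=20, ref_n=18, alt_n=2, genotype=Genotype.HET)]
        with pytest.warns(UserWarning, match="tails disabled"):
            rf.filter_by_depth(calls, 20.0, rf.RefinementConfig(min_support=3))
        assert FilterReason.LOW_SUPPORT in calls[0].filter_reasons

    def test_few_candidates_disables_tails(self):
        calls = [snp(10 + i, depth=90) for i in range(10)]
        with pytest.warns(UserWarning, match="tails disabled"):
            rf.filter_by_depth(calls, 20.0, rf.RefinementConfig())
        # fold rule still applies without the tail conjunct
        assert all(FilterReason.DEPTH_EXTREME in c.filter_reasons for c in calls)

    def test_zero_mean_depth_errors(self):
        with pytest.raises(ValueError):
            rf.filter_by_depth([snp(10)], 0.0, rf.RefinementConfig())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_percentile_oracle(self, seed):
        rng = random.Random(seed)
        calls = [snp(10 + 3 * i, depth=rng.randint(1, 120),
                     genotype=Genotype.ALT_HOM)
                 for i in range(rng.randint(150, 400))]
        for c in calls:
            c.alt_support = c.depth
        cfg = rf.RefinementConfig(min_support=1, bottom_tail_independent=True)
        rf.filter_by_depth(calls, 20.0, cfg)
        depths = [c.depth for c in calls]
        low = quantile_oracle(depths, 0.01)
        high = quantile_oracle(depths, 0.99)
        for c in calls:
            expect = (c.depth >= 80 and (c.depth >= high or c.depth < low)) \
                or c.depth < low
            assert (FilterReason.DEPTH_EXTREME in c.filter_reasons) == expect


class TestFilterByAlleleRatio:
    def _population(self, rng, n=500):
        calls = []
        for i in range(n):
            depth = 30
            alt_n = rng.binomial(depth, 0.5)
            calls.append(snp(10 + 3 * i, depth=depth, ref_n=depth - alt_n,
                             alt_n=alt_n, genotype=Genotype.HET))
        return calls

    def test_balanced_het_passes_extreme_flagged(self):
        rng = np.random.default_rng(3)
        calls = self._population(rng)
        balanced = snp(90_001, depth=40, ref_n=20, alt_n=20, genotype=Genotype.HET)
        extreme = snp(90_011, depth=40, ref_n=2, alt_n=38, genotype=Genotype.HET)
        calls += [balanced, extreme]
        rf.filter_by_allele_ratio(calls, rf.RefinementConfig())
        assert FilterReason.ALLELE_RATIO not in balanced.filter_reasons
        assert FilterReason.ALLELE_RATIO in extreme.filter_reasons

    def test_hom_exempt(self):
        rng = np.random.default_rng(4)
        calls = self._population(rng)
        hom = snp(90_001, depth=40, ref_n=0, alt_n=40, genotype=Genotype.ALT_HOM)
        calls.append(hom)
        rf.filter_by_allele_ratio(calls, rf.RefinementConfig())
        assert hom.is_pass

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_percentile_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = self._population(rng, n=int(rng.integers(120, 300)))
        rf.filter_by_allele_ratio(calls, rf.RefinementConfig())
        ratios = [c.alt_support / (c.ref_support + c.alt_support) for c in calls]
        lo = quantile_oracle(ratios, 0.005)
        hi = quantile_oracle(ratios, 0.995)
        for c, r in zip(calls, ratios):
            expect = not lo <= r <= hi
            assert (FilterReason.ALLELE_RATIO in c.filter_reasons) == expect


class TestCascadeProperties:
    def _scenario(self, seed=0):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(300):
            depth = int(rng.poisson(20)) + 1
            if rng.random() < 0.3:
                alt_n = int(rng.binomial(depth, 0.5))
                gt = Genotype.HET
            else:
                alt_n = depth
                gt = Genotype.ALT_HOM
            calls.append(snp(100 + 50 * i, depth=depth, ref_n=depth - alt_n,
                             alt_n=alt_n, genotype=gt))
        svs = [StructuralVariant(SVClass.DELETION, "chr1", 2_000, 3_500,
                                 pair_support=9)]
        return calls, svs

    def test_order_insensitive_pass_set(self):
        cfg = rf.RefinementConfig()
        calls_a, svs = self._scenario()
        calls_b = copy.deepcopy(calls_a)
        rf.filter_by_sv(calls_a, svs, cfg.sv_margin)
        rf.filter_by_depth(calls_a, 20.0, cfg)
        rf.filter_by_allele_ratio(calls_a, cfg)
        rf.filter_by_allele_ratio(calls_b, cfg)
        rf.filter_by_depth(calls_b, 20.0, cfg)
        rf.filter_by_sv(calls_b, svs, cfg.sv_margin)
        assert [c.filter_reasons for c in calls_a] == \
            [c.filter_reasons for c in calls_b]

    def test_no_silent_drops_and_subset(self):
        calls, svs = self._scenario(1)
        out = rf.refine_candidates(calls, svs, mean_depth=20.0)
        assert out is calls                       # annotated in place, none dropped
        removed = [c for c in calls if not c.is_pass]
        assert all(c.filter_reasons for c in removed)
        assert set(id(c) for c in rf.pass_calls(calls)) <= set(id(c) for c in calls)

    def test_idempotent(self):
        calls, svs = self._scenario(2)
        rf.refine_candidates(calls, svs, mean_depth=20.0)
        first = [set(c.filter_reasons) for c in calls]
        first_gt = [c.genotype for c in calls]
        rf.refine_candidates(calls, svs, mean_depth=20.0)
        assert [set(c.filter_reasons) for c in calls] == first
        assert [c.genotype for c in calls] == first_gt

    def test_summary_partitions_removed(self):
        calls, svs = self._scenario(3)
        rf.refine_candidates(calls, svs, mean_depth=20.0)
        summary = rf.filter_summary(calls)
        assert summary["candidates"] == summary["removed"] + summary["pass"]
        assert summary["removed"] == sum(1 for c in calls if not c.is_pass)


class TestMergeSamples:
    def test_union_with_regenotyping_from_stored_depths(self):
        a = [snp(100, depth=20, alt_n=20, ref_n=0)]
        b_other = [snp(500, depth=18, alt_n=18, ref_n=0)]
        records = rf.merge_samples({"A": a, "B": b_other})
        assert [r["pos"] for r in records] == [100, 500]
        rec100 = records[0]
        gt_a, ad_a, _ = rec100["samples"]["A"]
        gt_b, ad_b, dp_b = rec100["samples"]["B"]
        assert gt_a is Genotype.ALT_HOM
        assert gt_b is Genotype.MISSING and dp_b == 0

    def test_regenotype_from_alignments(self, tmp_path):
        seq = random_seq(1000, seed=6)
        ref = write_fasta(tmp_path / "g.fa", {"chr1": seq})
        from markermap.core import GenomeIndex
        genome = GenomeIndex.from_fasta(ref)
        # sample A: PASS alt-hom call at pos 301 (0-based 300)
        alt_base = "A" if seq[300] != "A" else "C"
        a = [VariantCall("chr1", 301, seq[300], alt_base, VariantClass.SNP,
                         20, 0, 20, Genotype.ALT_HOM, 60.0)]
        # sample B: 15 reference reads across the locus, no call
        reads = [dict(qname=f"b{i}", pos=250 + i, cigar="100M",
                      seq=seq[250 + i:350 + i]) for i in range(15)]
        sam_b = write_sam(tmp_path / "b.sam", reads, contigs=(("chr1", 1000),))
        records = rf.merge_samples({"A": a, "B": []},
                                   alignments={"B": sam_b}, genome=genome)
        gt_b, ad_b, dp_b = records[0]["samples"]["B"]
        assert gt_b is Genotype.REF_HOM
        assert ad_b == (15, 0) and dp_b == 15

    def test_same_locus_one_record_two_genotypes(self):
        a = [snp(100, depth=20, alt_n=20, ref_n=0)]
        b = [snp(100, depth=22, alt_n=11, ref_n=11, genotype=Genotype.HET)]
        records = rf.merge_samples({"A": a, "B": b})
        assert len(records) == 1
        assert records[0]["samples"]["A"][0] is Genotype.ALT_HOM
        assert records[0]["samples"]["B"][0] is Genotype.HET

    def test_non_pass_loci_excluded_from_union(self):
        a = [snp(100)]
        a[0].filter_reasons.add(FilterReason.SV_OVERLAP)
        b = [snp(500)]
        records = rf.merge_samples({"A": a, "B": b})
        assert [r["pos"] for r in records] == [500]

    def test_conflicting_refs_error(self):
        a = [VariantCall("chr1", 100, "A", "C", VariantClass.SNP, 10, 0, 10,
                         Genotype.ALT_HOM, 60.0)]
        b = [VariantCall("chr1", 100, "G", "C", VariantClass.SNP, 10, 0, 10,
                         Genotype.ALT_HOM, 60.0)]
        with pytest.raises(ValueError, match="chr1:100"):
            rf.merge_samples({"A": a, "B": b})

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            rf.merge_samples({"A": [snp(100)]})
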