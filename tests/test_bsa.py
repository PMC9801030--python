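import numpy as np
import pytest

from markermap import bsa
from markermap.core import (Genotype, GenomeIndex, StructuralVariant, SVClass,
                            VariantCall, VariantClass)
from markermap.recomb import Marker, MarkerObservation

from conftest import write_fasta


def obs(pos, p, m, chrom="chr1"):
    marker = Marker(chrom, pos, "A", "C", paternal="A", maternal="C")
    return MarkerObservation(marker, p, m)


def observations_from_profile(length, ratio_at, spacing=2_000, depth=30,
                              seed=0):
    """Deterministic observations whose paternal fraction follows
    ``ratio_at(pos)`` exactly (rounded to read counts)."""
    out = []
    for pos in range(spacing, length, spacing):
        r = ratio_at(pos)
        p = int(round(depth * r))
        out.append(obs(pos, p, depth - p))
    return out


class TestBuildRatioTrack:
    def test_flat_het_pool(self):
        L = 10_000_000
        observations = observations_from_profile(L, lambda pos: 0.5)
        (track,) = bsa.build_ratio_track(observations,
                                         chrom_lengths={"chr1": L})
        assert track.smoothed is not None
        assert np.allclose(track.smooth_ratio, 0.5)
        assert np.allclose(track.d1, 0.0, atol=1e-12)
        assert np.allclose(track.d2, 0.0, atol=1e-12)

    def test_empty_observations_error(self):
        with pytest.raises(ValueError):
            bsa.build_ratio_track([])

    def test_short_chromosome_skips_smoothing(self):
        observations = observations_from_profile(800_000, lambda pos: 0.5)
        with pytest.warns(UserWarning, match="smoothing skipped"):
            (track,) = bsa.build_ratio_track(
                observations, chrom_lengths={"chr1": 800_000})
        assert track.smoothed is None

    def test_rise_into_causal_locus(self):
        L = 12_000_000
        causal = 6_000_000

        def ratio(pos):
            return 0.5 + 0.5 * max(0.0, 1 - abs(pos - causal) / 6e6)

        observations = observations_from_profile(L, ratio)
        (track,) = bsa.build_ratio_track(observations,
                                         chrom_lengths={"chr1": L})
        r = track.smooth_ratio
        peak_idx = int(np.nanargmax(r))
        win = track.smoothed[peak_idx]
        assert win.start <= causal <= win.end


class TestFindCandidateRegions:
    def _track(self, ratio_fn, L=20_000_000):
        observations = observations_from_profile(L, ratio_fn)
        (track,) = bsa.build_ratio_track(observations,
                                         chrom_lengths={"chr1": L})
        return track

    def test_single_peak(self):
        causal = 6_100_000
        track = self._track(
            lambda pos: 0.5 + 0.48 * max(0.0, 1 - abs(pos - causal) / 5e6))
        regions = bsa.find_candidate_regions(track, mutant_parent="paternal")
        assert len(regions) == 1
        region = regions[0]
        assert region.kind is bsa.RegionKind.PEAK
        assert region.start <= causal <= region.end
        assert region.extreme_value > 0.9

    def test_flat_track_empty(self):
        track = self._track(lambda pos: 0.5)
        assert bsa.find_candidate_regions(track, mutant_parent=None) == []

    def test_two_separated_maxima(self):
        def ratio(pos):
            bump1 = 0.45 * max(0.0, 1 - abs(pos - 4e6) / 2.5e6)
            bump2 = 0.45 * max(0.0, 1 - abs(pos - 15e6) / 2.5e6)
            return 0.5 + bump1 + bump2

        track = self._track(ratio)
        regions = bsa.find_candidate_regions(track, mutant_parent="paternal")
        assert len(regions) == 2
        assert regions[0].contains(4_000_000)
        assert regions[1].contains(15_000_000)

    def test_expected_ratio_test_discards_weak_peaks(self):
        track = self._track(
            lambda pos: 0.5 + 0.15 * max(0.0, 1 - abs(pos - 8e6) / 4e6))
        assert bsa.find_candidate_regions(track, mutant_parent="paternal") == []

    def test_mirror_symmetry(self):
        def ratio(pos):
            return 0.5 + 0.45 * max(0.0, 1 - abs(pos - 8e6) / 4e6)

        track = self._track(ratio)
        mirror = self._track(lambda pos: 1.0 - ratio(pos))
        peaks = bsa.find_candidate_regions(track, mutant_parent="paternal")
        valleys = bsa.find_candidate_regions(mirror, mutant_parent="maternal")
        assert len(peaks) == len(valleys) == 1
        assert peaks[0].kind is bsa.RegionKind.PEAK
        assert valleys[0].kind is bsa.RegionKind.VALLEY
        assert (peaks[0].start, peaks[0].end) == (valleys[0].start, valleys[0].end)
        assert peaks[0].extreme_value == pytest.approx(
            1.0 - valleys[0].extreme_value, abs=1e-9)


def pool_call(pos, ref, alt, ratio, depth=40, het=None):
    alt_n = int(round(depth * ratio))
    gt = Genotype.HET if (het if het is not None else alt_n < depth) else Genotype.ALT_HOM
    return VariantCall("chr1", pos, ref, alt, VariantClass.SNP, depth,
                       depth - alt_n, alt_n, gt, 60.0)


class TestEmsFilter:
    def test_strong_novel_transition_retained(self):
        call = pool_call(100, "G", "A", 0.92)
        assert bsa.ems_candidate_filter([call], set()) == [call]

    def test_low_ratio_rejected_rule1(self):
        call = pool_call(100, "G", "A", 0.60)
        assert bsa.ems_candidate_filter([call], set()) == []
        assert call.filter_detail["ems_reject"] == "rule1:ratio"

    def test_parental_allele_rejected_rule2(self):
        call = pool_call(100, "G", "A", 0.95)
        out = bsa.ems_candidate_filter([call], {("chr1", 100, "A")})
        assert out == []
        assert call.filter_detail["ems_reject"] == "rule2:parental"

    def test_non_transition_rejected_rule3(self):
        call = pool_call(100, "A", "C", 0.95)
        assert bsa.ems_candidate_filter([call], set()) == []
        assert call.filter_detail["ems_reject"] == "rule3:not-transition"

    def test_ct_transition_retained(self):
        call = pool_call(100, "C", "T", 0.90)
        assert bsa.ems_candidate_filter([call], set()) == [call]

    def test_rule_order_is_1_2_3(self):
        # fails every rule; recorded reason must be rule 1
        call = pool_call(100, "A", "C", 0.3)
        bsa.ems_candidate_filter([call], {("chr1", 100, "C")})
        assert call.filter_detail["ems_reject"] == "rule1:ratio"


class TestTdnaScan:
    REGION = bsa.CandidateRegion("chr1", 1_000_000, 3_000_000,
                                 bsa.RegionKind.PEAK, 0.95, 2_000_000)

    def test_novel_sv_in_region_reported(self):
        sv = StructuralVariant(SVClass.INSERTION, "chr1", 2_000_000, 2_000_400,
                               pair_support=9)
        out = bsa.tdna_candidate_scan([sv], [], [self.REGION])
        assert out == [sv]

    def test_parental_sv_excluded(self):
        sv = StructuralVariant(SVClass.INSERTION, "chr1", 2_000_000, 2_000_400,
                               pair_support=9)
        parental = StructuralVariant(SVClass.INSERTION, "chr1", 1_999_900,
                                     2_000_300, pair_support=5)
        assert bsa.tdna_candidate_scan([sv], [parental], [self.REGION]) == []

    def test_outside_region_excluded_and_ranked(self):
        inside_weak = StructuralVariant(SVClass.INSERTION, "chr1", 1_500_000,
                                        1_500_300, pair_support=3)
        inside_strong = StructuralVariant(SVClass.INSERTION, "chr1", 2_500_000,
                                          2_500_300, pair_support=11)
        outside = StructuralVariant(SVClass.INSERTION, "chr1", 9_000_000,
                                    9_000_300, pair_support=30)
        out = bsa.tdna_candidate_scan([inside_weak, inside_strong, outside],
                                      [], [self.REGION])
        assert out == [inside_strong, inside_weak]


GFF = """\
##gff-version 3
chr1\ttest\tgene\t1001\t2000\t.\t+\t.\tID=gene1
chr1\ttest\tmRNA\t1001\t2000\t.\t+\t.\tID=mRNA1;Parent=gene1
chr1\ttest\texon\t1001\t1300\t.\t+\t.\tID=exon1;Parent=mRNA1
chr1\ttest\texon\t1501\t2000\t.\t+\t.\tID=exon2;Parent=mRNA1
chr1\ttest\tfive_prime_UTR\t1001\t1100\t.\t+\t.\tID=utr5;Parent=mRNA1
chr1\ttest\tCDS\t1101\t1300\t.\t+\t0\tID=cds1;Parent=mRNA1
chr1\ttest\tCDS\t1501\t1703\t.\t+\t.\tID=cds2;Parent=mRNA1
chr1\ttest\tthree_prime_UTR\t1704\t2000\t.\t+\t.\tID=utr3;Parent=mRNA1
chr1\ttest\tgene\t5001\t5600\t.\t-\t.\tID=gene2
chr1\ttest\tmRNA\t5001\t5600\t.\t-\t.\tID=mRNA2;Parent=gene2
chr1\ttest\texon\t5001\t5600\t.\t-\t.\tID=exon3;Parent=mRNA2
chr1\ttest\tCDS\t5001\t5600\t.\t-\t0\tID=cds3;Parent=mRNA2
"""


@pytest.fixture(scope="module")
def annotation_setup(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("anno")
    # CDS of gene1: 200 + 203 = 403 bases -> pad cds2 to make total 402 (x3)
    gff = GFF.replace("1501\t1703", "1501\t1702")
    gff_path = tmp / "genes.gff3"
    gff_path.write_text(gff)
    seq = ["A"] * 10_000
    # gene1 CDS: fill with a repeating GGA codon pattern (Gly)
    coding = "GGA" * 200
    for i in range(200):
        seq[1100 + i] = coding[i]
    for i in range(202):
        seq[1500 + i] = coding[i % 3]
    # gene2 (minus strand): reverse-complement of ATG GGA ... acceptable
    for i in range(600):
        seq[5000 + i] = "TCC"[i % 3]     # revcomp(GGA) chains
    fasta = write_fasta(tmp / "g.fa", {"chr1": "".join(seq)})
    genome = GenomeIndex.from_fasta(fasta)
    db = bsa.load_gene_db(str(gff_path))
    return db, genome


def _variant(pos, ref, alt):
    return VariantCall("chr1", pos, ref, alt, VariantClass.SNP, 30, 0, 30,
                       Genotype.ALT_HOM, 60.0)


class TestAnnotateMutation:
    def test_synonymous_third_position(self, annotation_setup):
        db, genome = annotation_setup
        # codon GGA at 1101-1103; GGA->GGG stays glycine
        ann = bsa.annotate_mutation(_variant(1103, "A", "G"), db, genome)
        assert ann.feature_class is bsa.FeatureClass.EXON
        assert ann.coding_effect is bsa.CodingEffect.SYNONYMOUS
        assert ann.gene_id == "gene1"

    def test_non_synonymous_first_position(self, annotation_setup):
        db, genome = annotation_setup
        ann = bsa.annotate_mutation(_variant(1101, "G", "T"), db, genome)
        assert ann.coding_effect is bsa.CodingEffect.NON_SYNONYMOUS

    def test_splice_site_two_bases_into_intron(self, annotation_setup):
        db, genome = annotation_setup
        for pos in (1301, 1302, 1499, 1500):
            ann = bsa.annotate_mutation(_variant(pos, "A", "G"), db, genome)
            assert ann.feature_class is bsa.FeatureClass.SPLICE_SITE, pos

    def test_intron_interior(self, annotation_setup):
        db, genome = annotation_setup
        ann = bsa.annotate_mutation(_variant(1400, "A", "G"), db, genome)
        assert ann.feature_class is bsa.FeatureClass.INTRON

    def test_utrs(self, annotation_setup):
        db, genome = annotation_setup
        assert bsa.annotate_mutation(_variant(1050, "A", "G"), db, genome
                                     ).feature_class is bsa.FeatureClass.FIVE_UTR
        assert bsa.annotate_mutation(_variant(1800, "A", "G"), db, genome
                                     ).feature_class is bsa.FeatureClass.THREE_UTR

    def test_intergenic(self, annotation_setup):
        db, genome = annotation_setup
        ann = bsa.annotate_mutation(_variant(9000, "A", "G"), db, genome)
        assert ann.feature_class is bsa.FeatureClass.INTERGENIC
        assert ann.gene_id is None

    def test_minus_strand_translation(self, annotation_setup):
        db, genome = annotation_setup
        # gene2 coding strand reads GGA codons; genomic TCC. A third-codon
        # change on the coding strand is genomic first base of the triplet.
        ann = bsa.annotate_mutation(_variant(5001, "T", "C"), db, genome)
        assert ann.gene_id == "gene2"
        assert ann.coding_effect in (bsa.CodingEffect.SYNONYMOUS,
                                     bsa.CodingEffect.NON_SYNONYMOUS)
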