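"""Bulked-segregant localisation of causal mutations.

Pooled-progeny marker observations are summarised on a 200 kb / 100 kb
window grid, re-averaged on a 2 Mb / 500 kb grid, and the smoothed curve's
discrete first/second derivatives mark peaks and valleys — the candidate
regions.  Novel variants inside the regions then pass the EMS rules
(allelic ratio >= 0.75, absent from both parents, G>A or C>T transition),
or novel SV insertions are scanned for T-DNA screens; survivors are
annotated against gene models.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import gffutils
import numpy as np
from Bio.Seq import Seq

from .core import (Genotype, GenomeIndex, StructuralVariant, VariantCall,
                   VariantClass)
from .recomb import GenotypeWindow, MarkerObservation, call_windows

log = logging.getLogger(__name__)

WINDOW_DEFAULT = 200_000
STEP_DEFAULT = 100_000
SMOOTH_WINDOW_DEFAULT = 2_000_000
SMOOTH_STEP_DEFAULT = 500_000
CURVATURE_FLOOR_DEFAULT = 0.01   # lets a 0.5 -> 1.0 rise over ~5 Mb qualify
REGION_DROP_DEFAULT = 0.1
EMS_MIN_RATIO = 0.75

_TRANSITIONS = {("G", "A"), ("C", "T")}


@dataclass
class RatioTrack:
    chrom: str
    windows: List[GenotypeWindow]
    smoothed: Optional[List[GenotypeWindow]]
    smooth_ratio: Optional[np.ndarray] = None
    d1: Optional[np.ndarray] = None
    d2: Optional[np.ndarray] = None


class RegionKind(str, enum.Enum):
    PEAK = "peak"
    VALLEY = "valley"


@dataclass
class CandidateRegion:
    chrom: str
    start: int                    # 0-based half-open
    end: int
    kind: RegionKind
    extreme_value: float
    extreme_pos: int              # centre of the extremum window

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("candidate region must have positive length")

    def contains(self, pos: int) -> bool:
        return self.start <= pos - 1 < self.end


class FeatureClass(str, enum.Enum):
    EXON = "exon"
    INTRON = "intron"
    INTERGENIC = "intergenic"
    FIVE_UTR = "5'-UTR"
    THREE_UTR = "3'-UTR"
    SPLICE_SITE = "splice site"


class CodingEffect(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    NON_SYNONYMOUS = "non-synonymous"
    NOT_APPLICABLE = "not-applicable"


@dataclass
class MutationAnnotation:
    variant: VariantCall
    feature_class: FeatureClass
    coding_effect: CodingEffect
    gene_id: Optional[str]


# ---------------------------------------------------------------------------
# ratio track

def build_ratio_track(observations: Sequence[MarkerObservation],
                      window: int = WINDOW_DEFAULT,
                      step: int = STEP_DEFAULT,
                      smooth_window: int = SMOOTH_WINDOW_DEFAULT,
                      smooth_step: int = SMOOTH_STEP_DEFAULT,
                      chrom_lengths: Optional[Dict[str, int]] = None,
                      min_informative: int = 1) -> List[RatioTrack]:
    """Window ratios plus the smoothed track and its discrete derivatives."""
    if not observations:
        raise ValueError("empty marker observation set")
    wins = call_windows(observations, window, step, chrom_lengths,
                        min_informative=min_informative)
    by_chrom: Dict[str, List[GenotypeWindow]] = {}
    for win in wins:
        by_chrom.setdefault(win.chrom, []).append(win)
    tracks = []
    for chrom in sorted(by_chrom):
        length = (chrom_lengths or {}).get(
            chrom, max(w.end for w in by_chrom[chrom]))
        if length < smooth_window:
            warnings.warn(f"{chrom} shorter than one smoothing window; "
                          "smoothing skipped", stacklevel=2)
            tracks.append(RatioTrack(chrom, by_chrom[chrom], None))
            continue
        smooth = call_windows(
            [o for o in observations if o.marker.chrom == chrom],
            smooth_window, smooth_step, chrom_lengths,
            min_informative=min_informative)
        ratio = np.array([w.ratio_w if w.ratio_w is not None else np.nan
                          for w in smooth])
        d1 = np.zeros_like(ratio)
        d2 = np.zeros_like(ratio)
        if len(ratio) >= 3:
            d1[1:-1] = (ratio[2:] - ratio[:-2]) / 2.0
            d1[0] = ratio[1] - ratio[0]
            d1[-1] = ratio[-1] - ratio[-2]
            d2[1:-1] = ratio[2:] - 2 * ratio[1:-1] + ratio[:-2]
        tracks.append(RatioTrack(chrom, by_chrom[chrom], smooth, ratio, d1, d2))
    return tracks


def find_candidate_regions(track: RatioTrack,
                           mutant_parent: Optional[str] = "paternal",
                           curvature_floor: float = CURVATURE_FLOOR_DEFAULT,
                           drop: float = REGION_DROP_DEFAULT,
                           expected_ratio: float = EMS_MIN_RATIO
                           ) -> List[CandidateRegion]:
    """Peaks/valleys of the smoothed ratio via first-derivative sign changes,
    curvature-filtered, extended until the ratio recedes by ``drop``.

    ``mutant_parent`` selects the expected direction of the causal extremum
    (paternal -> peaks with ratio >= expected_ratio; maternal -> valleys with
    ratio <= 1 - expected_ratio); None keeps both without the ratio test.
    """
    if track.smoothed is None or track.smooth_ratio is None:
        return []
    r = track.smooth_ratio
    d1, d2 = track.d1, track.d2
    n = len(r)
    regions: List[CandidateRegion] = []
    for i in range(1, n - 1):
        if np.isnan(r[i - 1:i + 2]).any():
            continue
        is_peak = d1[i - 1] > 0 and d1[i + 1] < 0 and r[i] >= r[i - 1] and r[i] >= r[i + 1]
        is_valley = d1[i - 1] < 0 and d1[i + 1] > 0 and r[i] <= r[i - 1] and r[i] <= r[i + 1]
        if not (is_peak or is_valley):
            continue
        if abs(d2[i]) < curvature_floor:
            continue
        kind = RegionKind.PEAK if is_peak else RegionKind.VALLEY
        if mutant_parent == "paternal":
            if kind is not RegionKind.PEAK or r[i] < expected_ratio:
                continue
        elif mutant_parent == "maternal":
            if kind is not RegionKind.VALLEY or r[i] > 1.0 - expected_ratio:
                continue
        lo = hi = i
        if kind is RegionKind.PEAK:
            while lo > 0 and not np.isnan(r[lo - 1]) and r[lo - 1] > r[i] - drop:
                lo -= 1
            while hi < n - 1 and not np.isnan(r[hi + 1]) and r[hi + 1] > r[i] - drop:
                hi += 1
        else:
            while lo > 0 and not np.isnan(r[lo - 1]) and r[lo - 1] < r[i] + drop:
                lo -= 1
            while hi < n - 1 and not np.isnan(r[hi + 1]) and r[hi + 1] < r[i] + drop:
                hi += 1
        wins = track.smoothed
        regions.append(CandidateRegion(
            chrom=track.chrom, start=wins[lo].start, end=wins[hi].end,
            kind=kind, extreme_value=float(r[i]),
            extreme_pos=(wins[i].start + wins[i].end) // 2))
    return _dedupe_regions(regions)


def _dedupe_regions(regions: List[CandidateRegion]) -> List[CandidateRegion]:
    """Adjacent extremum windows of one summit produce overlapping regions;
    keep the most extreme representative of each overlap run."""
    out: List[CandidateRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        if out and reg.kind == out[-1].kind and reg.start < out[-1].end:
            keep = max((out[-1], reg), key=lambda x: (
                x.extreme_value if x.kind is RegionKind.PEAK else -x.extreme_value))
            keep = CandidateRegion(reg.chrom, min(out[-1].start, reg.start),
                                   max(out[-1].end, reg.end), reg.kind,
                                   keep.extreme_value, keep.extreme_pos)
            out[-1] = keep
        else:
            out.append(reg)
    return out


# ---------------------------------------------------------------------------
# EMS / T-DNA candidate filters

def ems_candidate_filter(novel: Sequence[VariantCall],
                         parental_alleles: Set[Tuple[str, int, str]],
                         min_ratio: float = EMS_MIN_RATIO
                         ) -> List[VariantCall]:
    """Apply the three EMS rules in order; rejects carry their rule in
    ``filter_detail['ems_reject']``.

    1. heterozygous SNPs with allelic ratio < ``min_ratio`` are dropped;
    2. alternate alleles matching either parental genome are dropped;
    3. only G>A / C>T transitions survive.
    ``parental_alleles`` holds (chrom, pos, alt) triples of both parents.
    """
    survivors = []
    for call in novel:
        if call.genotype is Genotype.HET and call.allele_ratio < min_ratio:
            call.filter_detail["ems_reject"] = "rule1:ratio"
            continue
        if (call.chrom, call.pos, call.alt) in parental_alleles:
            call.filter_detail["ems_reject"] = "rule2:parental"
            continue
        if call.variant_class is not VariantClass.SNP or \
                (call.ref, call.alt) not in _TRANSITIONS:
            call.filter_detail["ems_reject"] = "rule3:not-transition"
            continue
        survivors.append(call)
    return survivors


def tdna_candidate_scan(pool_svs: Sequence[StructuralVariant],
                        parental_svs: Sequence[StructuralVariant],
                        regions: Sequence[CandidateRegion]
                        ) -> List[StructuralVariant]:
    """Novel SVs (absent from the parental SV set) inside candidate regions,
    ranked by pair support."""
    hits = []
    for sv in pool_svs:
        in_region = any(r.chrom == sv.chrom and sv.start < r.end and r.start < sv.end
                        for r in regions)
        if not in_region:
            continue
        known = any(p.chrom == sv.chrom and sv.start < p.end and p.start < sv.end
                    for p in parental_svs)
        if not known:
            hits.append(sv)
    return sorted(hits, key=lambda s: -s.pair_support)


# ---------------------------------------------------------------------------
# annotation

def load_gene_db(gff_path: str) -> gffutils.FeatureDB:
    return gffutils.create_db(str(gff_path), ":memory:",
                              merge_strategy="create_unique", keep_order=True)


_UTR5 = {"five_prime_UTR", "five_prime_utr", "5_prime_UTR"}
_UTR3 = {"three_prime_UTR", "three_prime_utr", "3_prime_UTR"}


def annotate_mutation(variant: VariantCall, db: gffutils.FeatureDB,
                      genome: GenomeIndex) -> MutationAnnotation:
    """Feature class by containment with precedence splice-site > CDS >
    UTR > exon > intron > intergenic; CDS SNPs are translated on the
    feature strand to synonymous/non-synonymous."""
    pos = variant.pos             # 1-based, matching GFF3
    feats = list(db.region(region=(variant.chrom, pos - 1, pos)))
    genes = [f for f in feats if f.featuretype == "gene"]
    if not genes:
        return MutationAnnotation(variant, FeatureClass.INTERGENIC,
                                  CodingEffect.NOT_APPLICABLE, None)
    gene = genes[0]
    gene_id = gene.id
    mrnas = [f for f in db.children(gene, featuretype=("mRNA", "transcript"))]
    best = MutationAnnotation(variant, FeatureClass.INTRON,
                              CodingEffect.NOT_APPLICABLE, gene_id)
    for mrna in mrnas or [gene]:
        exons = sorted(db.children(mrna, featuretype="exon"),
                       key=lambda f: f.start)
        if not exons:
            continue
        in_exon = any(e.start <= pos <= e.end for e in exons)
        if not in_exon:
            for left, right in zip(exons, exons[1:]):
                intron_start, intron_end = left.end + 1, right.start - 1
                if intron_start <= pos <= intron_end:
                    if pos - intron_start < 2 or intron_end - pos < 2:
                        return MutationAnnotation(
                            variant, FeatureClass.SPLICE_SITE,
                            CodingEffect.NOT_APPLICABLE, gene_id)
            continue
        cdss = sorted(db.children(mrna, featuretype="CDS"),
                      key=lambda f: f.start)
        if any(c.start <= pos <= c.end for c in cdss):
            effect = _coding_effect(variant, cdss, genome)
            if effect is None:
                best = MutationAnnotation(variant, FeatureClass.EXON,
                                          CodingEffect.NOT_APPLICABLE, gene_id)
            else:
                return MutationAnnotation(variant, FeatureClass.EXON,
                                          effect, gene_id)
            continue
        for f in db.children(mrna):
            if f.start <= pos <= f.end:
                if f.featuretype in _UTR5:
                    return MutationAnnotation(variant, FeatureClass.FIVE_UTR,
                                              CodingEffect.NOT_APPLICABLE, gene_id)
                if f.featuretype in _UTR3:
                    return MutationAnnotation(variant, FeatureClass.THREE_UTR,
                                              CodingEffect.NOT_APPLICABLE, gene_id)
        best = MutationAnnotation(variant, FeatureClass.EXON,
                                  CodingEffect.NOT_APPLICABLE, gene_id)
    return best


def _coding_effect(variant: VariantCall, cdss, genome: GenomeIndex
                   ) -> Optional[CodingEffect]:
    if variant.variant_class is not VariantClass.SNP:
        return CodingEffect.NOT_APPLICABLE
    strand = cdss[0].strand
    coding = "".join(genome.fetch(c.seqid, c.start - 1, c.end) for c in cdss)
    if len(coding) % 3 != 0:
        warnings.warn(
            f"CDS length {len(coding)} of {cdss[0].id} not divisible by 3; "
            "annotation degraded to exon", stacklevel=2)
        return None
    offset = 0
    cds_offset = None
    for c in cdss:
        if c.start <= variant.pos <= c.end:
            cds_offset = offset + (variant.pos - c.start)
            break
        offset += c.end - c.start + 1
    if cds_offset is None:
        return CodingEffect.NOT_APPLICABLE
    ref_codon_seq = coding
    alt_coding = (coding[:cds_offset] + variant.alt + coding[cds_offset + 1:])
    if strand == "-":
        ref_codon_seq = str(Seq(ref_codon_seq).reverse_complement())
        alt_coding = str(Seq(alt_coding).reverse_complement())
        cds_offset = len(coding) - 1 - cds_offset
    codon_idx = cds_offset // 3
    ref_aa = str(Seq(ref_codon_seq[codon_idx * 3:codon_idx * 3 + 3]).translate())
    alt_aa = str(Seq(alt_coding[codon_idx * 3:codon_idx * 3 + 3]).translate())
    return (CodingEffect.SYNONYMOUS if ref_aa == alt_aa
            else CodingEffect.NON_SYNONYMOUS)
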