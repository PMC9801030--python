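"""Refinement of candidate variants: the artificial-variant filters.

Candidates are annotated, never silently dropped: each filter unions reason
codes into :attr:`VariantCall.filter_reasons`, so the cascade is
order-insensitive and idempotent, and the PASS set is the same under any
filter ordering.  Filters:

* SV overlap/adjacency — calls inside or within a margin of a structural
  variant are products of mis-mapped non-allelic reads.
* Tandem-repeat indel examination — unit gain/loss re-typing, and demotion
  of heterozygous evidence contributed only by reads that fail to span the
  repeat.
* Depth extremes — four-fold-plus-top-percentile coverage, or bottom-
  percentile coverage, over the candidate depth distribution.
* Allelic ratio — heterozygous calls outside the central ratio percentile
  of all heterozygous candidates.
* Low support — too few reads carrying the variant allele.
"""

from __future__ import annotations

import logging
import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .calling import genotype_posterior
from .core import (FilterReason, Genotype, StructuralVariant,
                   TandemRepeatRegion, VariantCall, VariantClass)

log = logging.getLogger(__name__)

MIN_CANDIDATES_FOR_TAILS = 100


@dataclass
class RefinementConfig:
    sv_margin: int = 500                 # bp around SV breakpoints
    depth_fold: float = 4.0              # x mean depth, upper trigger
    depth_tails: float = 0.01            # percentile tail on each side
    ratio_percentile: float = 0.99       # central acceptance mass for het ratio
    min_support: int = 3                 # reads carrying the variant allele
    # the stated depth rule is conjunctive ("meets two requirements"): the
    # fold trigger AND tail membership.  Setting this lets the bottom tail
    # flag on its own, which trades ~1% of true markers for extra caution.
    bottom_tail_independent: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.depth_tails < 0.5:
            raise ValueError("depth_tails must lie in (0, 0.5)")
        if self.depth_fold <= 1:
            raise ValueError("depth_fold must exceed 1")
        if not 0 < self.ratio_percentile <= 1:
            raise ValueError("ratio_percentile must lie in (0, 1]")


# ---------------------------------------------------------------------------
# SV filter

def filter_by_sv(candidates: List[VariantCall],
                 svs: Sequence[StructuralVariant],
                 margin: int = 500) -> List[VariantCall]:
    """SV_OVERLAP inside any SV interval; SV_ADJACENT within ``margin`` bp."""
    by_chrom: Dict[str, List[StructuralVariant]] = {}
    for sv in sorted(svs, key=lambda s: (s.chrom, s.start)):
        by_chrom.setdefault(sv.chrom, []).append(sv)
    starts = {c: [sv.start for sv in lst] for c, lst in by_chrom.items()}
    for call in candidates:
        lst = by_chrom.get(call.chrom)
        if not lst:
            continue
        pos0 = call.pos - 1
        idx = bisect_right(starts[call.chrom], pos0 + margin)
        for sv in lst[:idx]:
            if sv.start <= pos0 < sv.end:
                call.filter_reasons.add(FilterReason.SV_OVERLAP)
                call.filter_detail.setdefault(FilterReason.SV_OVERLAP.value,
                                              sv.sv_class.value)
            elif sv.start - margin <= pos0 < sv.end + margin:
                call.filter_reasons.add(FilterReason.SV_ADJACENT)
                call.filter_detail.setdefault(FilterReason.SV_ADJACENT.value,
                                              sv.sv_class.value)
    return candidates


# ---------------------------------------------------------------------------
# tandem-repeat indel filter

def filter_tandem_indels(candidates: List[VariantCall],
                         repeats: Sequence[TandemRepeatRegion],
                         evidence: Optional[Dict[tuple, dict]] = None
                         ) -> List[VariantCall]:
    """Examine indels overlapping filter-active tandem repeats.

    An indel whose length is an integer multiple of the repeat unit is
    re-typed as gain/loss of N units.  A heterozygous indel whose second
    allele is supported only by reads that do not span the repeat is either
    flagged TANDEM_NONSPAN (when the unsupported allele is the variant) or
    rewritten homozygous for the spanning-read consensus allele.
    """
    active = sorted((r for r in repeats if r.filter_active),
                    key=lambda r: (r.chrom, r.start))
    by_chrom: Dict[str, List[TandemRepeatRegion]] = {}
    for rep in active:
        by_chrom.setdefault(rep.chrom, []).append(rep)
    starts = {c: [r.start for r in lst] for c, lst in by_chrom.items()}
    for call in candidates:
        if call.variant_class is VariantClass.SNP:
            continue
        lst = by_chrom.get(call.chrom)
        if not lst:
            continue
        pos0 = call.pos - 1
        idx = bisect_right(starts[call.chrom], pos0 + 1)
        hit = None
        for rep in lst[max(0, idx - 8):idx]:
            if rep.start <= pos0 < rep.end or rep.start <= pos0 + 1 < rep.end:
                hit = rep
                break
        if hit is None:
            continue
        if call.indel_length % hit.unit_length == 0:
            units = call.indel_length // hit.unit_length
            call.tandem_units = units if call.variant_class is VariantClass.INSERTION else -units
        ev = call.tandem_evidence
        if ev is None and evidence is not None:
            ev = evidence.get(call.key())
        if ev is None or call.genotype is not Genotype.HET:
            continue
        ref_span, ref_nonspan = ev.get("ref", (0, 0))
        alt_span, alt_nonspan = ev.get("alt", (0, 0))
        if alt_span == 0 and alt_nonspan > 0 and ref_span > 0:
            # variant allele exists only in reads ending inside the repeat
            call.filter_reasons.add(FilterReason.TANDEM_NONSPAN)
        elif ref_span == 0 and ref_nonspan > 0 and alt_span > 0:
            # spanning reads unanimously carry the indel: the heterozygous
            # evidence is an artifact of reads terminating in the repeat
            call.genotype = Genotype.ALT_HOM
            call.ref_support = 0
            call.filter_detail.setdefault("TANDEM_RETYPED", "hom-alt")
    return candidates


# ---------------------------------------------------------------------------
# depth filter

def filter_by_depth(candidates: List[VariantCall], mean_depth: float,
                    config: RefinementConfig) -> List[VariantCall]:
    """DEPTH_EXTREME for fold-excess coverage that also sits in a percentile
    tail of the candidate depth distribution; LOW_SUPPORT for too few
    variant-allele reads."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    depths = np.array([c.depth for c in candidates], dtype=float)
    use_tails = len(candidates) >= MIN_CANDIDATES_FOR_TAILS
    if not use_tails and len(candidates):
        warnings.warn(
            f"only {len(candidates)} candidates; percentile tails disabled, "
            "fold rule still applies", stacklevel=2)
    if use_tails:
        low_cut = float(np.quantile(depths, config.depth_tails))
        high_cut = float(np.quantile(depths, 1.0 - config.depth_tails))
    for call in candidates:
        fold = call.depth >= config.depth_fold * mean_depth
        if use_tails:
            # strict bottom comparison: depth distributions are discrete and
            # <= would flag well over the nominal tail mass on a tied value
            in_tail = call.depth >= high_cut or call.depth < low_cut
            extreme = fold and in_tail
            if config.bottom_tail_independent:
                extreme = extreme or call.depth < low_cut
        else:
            extreme = fold
        if extreme:
            call.filter_reasons.add(FilterReason.DEPTH_EXTREME)
        if call.alt_support < config.min_support:
            call.filter_reasons.add(FilterReason.LOW_SUPPORT)
    return candidates


# ---------------------------------------------------------------------------
# allelic-ratio filter

def allele_ratio_bounds(candidates: Sequence[VariantCall],
                        percentile: float = 0.99) -> Tuple[float, float]:
    """Central acceptance bounds of the heterozygous allelic-ratio
    distribution (e.g. 0.99 -> the 0.5%..99.5% quantiles)."""
    ratios = np.array([c.allele_ratio for c in candidates
                       if c.genotype is Genotype.HET
                       and c.ref_support + c.alt_support > 0])
    if len(ratios) == 0:
        return 0.0, 1.0
    tail = (1.0 - percentile) / 2.0
    return (float(np.quantile(ratios, tail)),
            float(np.quantile(ratios, 1.0 - tail)))


def filter_by_allele_ratio(candidates: List[VariantCall],
                           config: RefinementConfig) -> List[VariantCall]:
    """Flag heterozygous candidates whose ratio falls outside the empirical
    central bounds; homozygous candidates are exempt."""
    lo, hi = allele_ratio_bounds(candidates, config.ratio_percentile)
    for call in candidates:
        if call.genotype is not Genotype.HET:
            continue
        total = call.ref_support + call.alt_support
        if total == 0:
            continue
        if not lo <= call.allele_ratio <= hi:
            call.filter_reasons.add(FilterReason.ALLELE_RATIO)
    return candidates


# ---------------------------------------------------------------------------
# cascade

def refine_candidates(candidates: List[VariantCall],
                      svs: Sequence[StructuralVariant] = (),
                      repeats: Sequence[TandemRepeatRegion] = (),
                      mean_depth: float = 0.0,
                      config: Optional[RefinementConfig] = None
                      ) -> List[VariantCall]:
    """Apply every refinement filter; reasons are unioned, nothing dropped."""
    config = config or RefinementConfig()
    refinable = [c for c in candidates if c.refinable]
    filter_by_sv(refinable, svs, config.sv_margin)
    filter_tandem_indels(refinable, repeats)
    if mean_depth > 0 and refinable:
        filter_by_depth(refinable, mean_depth, config)
    filter_by_allele_ratio(refinable, config)
    return candidates


def pass_calls(candidates: Sequence[VariantCall]) -> List[VariantCall]:
    return [c for c in candidates if c.is_pass]


def filter_summary(candidates: Sequence[VariantCall]) -> Dict[str, int]:
    """Per-reason counts plus totals; a removed candidate with several
    reasons contributes to each reason but once to ``removed``."""
    summary = {reason.value: 0 for reason in FilterReason}
    removed = 0
    for call in candidates:
        if call.filter_reasons:
            removed += 1
            for reason in call.filter_reasons:
                summary[reason.value] += 1
    summary["candidates"] = len(candidates)
    summary["removed"] = removed
    summary["pass"] = len(candidates) - removed
    return summary


# ---------------------------------------------------------------------------
# multi-sample merge

def merge_samples(per_sample: Dict[str, List[VariantCall]],
                  alignments: Optional[Dict[str, str]] = None,
                  genome=None,
                  base_error: float = 1e-3) -> List[dict]:
    """Union of PASS loci across samples with per-sample re-genotyping.

    Each record carries, per sample, a genotype re-evaluated from that
    sample's allele depths (re-piled from alignments when supplied and the
    sample has no stored call at the locus); samples with no coverage get a
    missing genotype.
    """
    if len(per_sample) < 2:
        raise ValueError("merge requires at least two samples")
    samples = list(per_sample)
    union: Dict[tuple, dict] = {}
    ref_at: Dict[Tuple[str, int], str] = {}
    for sample, calls in per_sample.items():
        for call in calls:
            if not call.is_pass:
                continue
            key = call.key()
            anchor = (call.chrom, call.pos)
            prev_ref = ref_at.get(anchor)
            if prev_ref is not None and prev_ref != call.ref and \
                    len(prev_ref) == len(call.ref):
                raise ValueError(
                    f"conflicting reference alleles at {call.chrom}:{call.pos}: "
                    f"{prev_ref!r} vs {call.ref!r}")
            ref_at.setdefault(anchor, call.ref)
            union.setdefault(key, {
                "chrom": call.chrom, "pos": call.pos, "ref": call.ref,
                "alt": call.alt, "variant_class": call.variant_class,
                "quality": call.quality, "filter_reasons": set(),
                "samples": {}})
    stored: Dict[str, Dict[tuple, VariantCall]] = {
        sample: {c.key(): c for c in calls}
        for sample, calls in per_sample.items()}
    records = sorted(union.values(), key=lambda r: (r["chrom"], r["pos"], r["alt"]))
    for rec in records:
        key = (rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
        for sample in samples:
            call = stored[sample].get(key)
            if call is not None:
                ad = (call.ref_support, call.alt_support)
                dp = call.depth
            elif alignments and sample in alignments and genome is not None:
                ad, dp = _count_alleles(alignments[sample], genome, rec)
            else:
                ad, dp = (0, 0), 0
            rec["samples"][sample] = (_regenotype(ad, base_error), ad, dp)
    return records


def _regenotype(ad: Tuple[int, int], base_error: float) -> Genotype:
    ref_n, alt_n = ad
    if ref_n + alt_n == 0:
        return Genotype.MISSING
    obs = [("ref", base_error)] * ref_n + [("alt", base_error)] * alt_n
    best, _, _ = genotype_posterior(obs)
    return best

def _count_alleles(alignment_path: str, genome, rec: dict) -> Tuple[Tuple[int, int], int]:
    """Re-pileup one locus from a sample's alignments (same read filters as
    calling: mapq >= 20)."""
    from . import io as mio
    from .calling import filter_reads

    chrom, pos0 = rec["chrom"], rec["pos"] - 1
    is_snp = rec["variant_class"] is VariantClass.SNP
    ref_n = alt_n = depth = 0
    reads = mio.read_alignments(alignment_path, (chrom, pos0, pos0 + 1))
    for read in filter_reads(reads, (), 20):
        base = _base_at(read, pos0)
        if base is None:
            continue
        depth += 1
        if is_snp:
            if base == rec["ref"]:
                ref_n += 1
            elif base == rec["alt"]:
                alt_n += 1
        else:
            indel = _indel_at(read, pos0)
            if rec["variant_class"] is VariantClass.INSERTION:
                want = ("I", rec["alt"][1:])
            else:
                want = ("D", len(rec["ref"]) - 1)
            if indel == want:
                alt_n += 1
            elif indel is None:
                ref_n += 1
    return (ref_n, alt_n), depth


def _base_at(read, pos0: int):
    if read.sequence is None or read.cigartuples is None:
        return None
    rpos, qpos = read.start, 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):
            if rpos <= pos0 < rpos + ln:
                return read.sequence[qpos + (pos0 - rpos)]
            rpos += ln
            qpos += ln
        elif op == 1:
            qpos += ln
        elif op in (2, 3):
            if rpos <= pos0 < rpos + ln:
                return None
            rpos += ln
        elif op == 4:
            qpos += ln
    return None


def _indel_at(read, pos0: int):
    """("I", seq) or ("D", length) for an indel anchored at pos0, else None."""
    rpos, qpos = read.start, 0
    prev_ref_base_pos = None
    for op, ln in read.cigartuples or ():
        if op in (0, 7, 8):
            rpos += ln
            qpos += ln
            prev_ref_base_pos = rpos - 1
        elif op == 1:
            if prev_ref_base_pos == pos0 and read.sequence is not None:
                return ("I", read.sequence[qpos:qpos + ln])
            qpos += ln
        elif op == 2:
            if prev_ref_base_pos == pos0:
                return ("D", ln)
            rpos += ln
        elif op == 4:
            qpos += ln
    return None
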