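"""Candidate SNP/small-indel discovery from pileups.

The caller is a standard diallelic genotype-likelihood model: per-observation
error from base quality (uniform over the three alternative bases), a
configurable heterozygous prior, and a phred-scaled posterior quality floor.
Mapping quality acts as a hard pre-filter (reads below the threshold never
enter a pileup), not as a likelihood term.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from . import io as mio
from .core import (AlignedRead, Genotype, GenomeIndex, TandemRepeatRegion,
                   VariantCall, VariantClass)

log = logging.getLogger(__name__)

MIN_MAPQ_DEFAULT = 20
BASEQ_FLOOR = 13          # observations below this base quality are ignored
HET_PRIOR_DEFAULT = 1e-3
QUAL_FLOOR_DEFAULT = 20.0
MAX_INDEL_LEN = 10
_MAX_QUAL = 1000.0


@dataclass
class Observation:
    """One read's evidence at a pileup column."""

    allele: str               # base, or "+SEQ" (insertion) / "-SEQ" (deletion)
    baseq: int
    mapq: int
    end_in_repeat: bool = False
    spans_repeat: bool = False


@dataclass
class PileupColumn:
    chrom: str
    pos: int                  # 1-based anchor (base before an indel)
    ref: str                  # reference base at the anchor
    observations: List[Observation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


class _RepeatIndex:
    """Per-chromosome interval lookup for filter-active tandem repeats."""

    def __init__(self, repeats: Sequence[TandemRepeatRegion]) -> None:
        self.by_chrom: Dict[str, List[TandemRepeatRegion]] = {}
        for rep in repeats:
            if rep.filter_active:
                self.by_chrom.setdefault(rep.chrom, []).append(rep)
        self.starts: Dict[str, List[int]] = {}
        for chrom, reps in self.by_chrom.items():
            reps.sort(key=lambda r: (r.start, r.end))
            self.starts[chrom] = [r.start for r in reps]

    def containing(self, chrom: str, pos0: int) -> List[int]:
        reps = self.by_chrom.get(chrom)
        if not reps:
            return []
        idx = bisect_right(self.starts[chrom], pos0)
        hits = []
        for i in range(max(0, idx - 8), idx):   # repeats are short; 8 is ample
            if reps[i].contains(pos0):
                hits.append(i)
        return hits

    def get(self, chrom: str, index: int) -> TandemRepeatRegion:
        return self.by_chrom[chrom][index]


def filter_reads(reads: Iterable[AlignedRead],
                 repeats: Sequence[TandemRepeatRegion] = (),
                 min_mapq: int = MIN_MAPQ_DEFAULT) -> Iterator[AlignedRead]:
    """Drop low-mapq reads and flag reads relative to tandem repeats.

    A read whose alignment start or end sits inside a filter-active repeat is
    flagged non-spanning for that repeat (its indel evidence there is
    discounted during refinement); a read covering a repeat with both ends
    outside gets the spans flag.
    """
    index = _RepeatIndex(repeats)
    for read in reads:
        if read.mapping_quality < min_mapq:
            continue
        chrom = read.reference_name
        nonspan = set(index.containing(chrom, read.start))
        nonspan |= set(index.containing(chrom, read.end - 1))
        spans: List[int] = []
        reps = index.by_chrom.get(chrom)
        if reps:
            lo = bisect_right(index.starts[chrom], read.end - 1)
            for i in range(max(0, lo - 32), lo):
                rep = reps[i]
                if rep.end <= read.start:
                    continue
                if rep.spanned_by(read.start, read.end):
                    spans.append(i)
        read.nonspan_repeats = tuple(sorted(nonspan))
        read.spans_repeats = tuple(spans)
        yield read


# ---------------------------------------------------------------------------
# genotype likelihood

def genotype_posterior(obs: Sequence[Tuple[str, float]],
                       het_prior: float = HET_PRIOR_DEFAULT
                       ) -> Tuple[Genotype, float, Dict[Genotype, float]]:
    """Posterior over {ref-hom, het, alt-hom} from (kind, error-prob) pairs.

    ``kind`` is "ref", "alt", or "other".  Returns the maximum-posterior
    genotype, its phred-scaled quality, and the full posterior.
    """
    log_l = {Genotype.REF_HOM: 0.0, Genotype.HET: 0.0, Genotype.ALT_HOM: 0.0}
    for kind, err in obs:
        e3 = err / 3.0
        if kind == "ref":
            log_l[Genotype.REF_HOM] += math.log(1.0 - err)
            log_l[Genotype.HET] += math.log(0.5 * (1.0 - err) + 0.5 * e3)
            log_l[Genotype.ALT_HOM] += math.log(e3)
        elif kind == "alt":
            log_l[Genotype.REF_HOM] += math.log(e3)
            log_l[Genotype.HET] += math.log(0.5 * (1.0 - err) + 0.5 * e3)
            log_l[Genotype.ALT_HOM] += math.log(1.0 - err)
        else:
            for g in log_l:
                log_l[g] += math.log(e3)
    prior = {Genotype.REF_HOM: 1.0 - 1.5 * het_prior,
             Genotype.HET: het_prior,
             Genotype.ALT_HOM: 0.5 * het_prior}
    log_post = {g: log_l[g] + math.log(prior[g]) for g in log_l}
    shift = max(log_post.values())
    unnorm = {g: math.exp(lp - shift) for g, lp in log_post.items()}
    total = sum(unnorm.values())
    post = {g: p / total for g, p in unnorm.items()}
    best = max(post, key=post.get)
    residual = 1.0 - post[best]
    qual = _MAX_QUAL if residual <= 10 ** (-_MAX_QUAL / 10) else -10.0 * math.log10(residual)
    return best, qual, post


def call_column(column: PileupColumn,
                het_prior: float = HET_PRIOR_DEFAULT,
                qual_floor: float = QUAL_FLOOR_DEFAULT,
                repeat_index: Optional[_RepeatIndex] = None
                ) -> Optional[VariantCall]:
    """Call the best diallelic genotype at one column; None when ref-hom."""
    usable = [o for o in column.observations if o.baseq >= BASEQ_FLOOR]
    if not usable:
        return None
    counts: Dict[str, int] = {}
    for o in usable:
        if o.allele != column.ref:
            counts[o.allele] = counts.get(o.allele, 0) + 1
    if not counts:
        return None
    alt_allele = max(counts, key=lambda a: (counts[a], a))
    is_indel = alt_allele[0] in "+-"
    if is_indel and len(alt_allele) - 1 > MAX_INDEL_LEN:
        return None
    obs = []
    for o in usable:
        if o.allele == column.ref:
            kind = "ref"
        elif o.allele == alt_allele:
            kind = "alt"
        else:
            kind = "other"
        obs.append((kind, 10 ** (-o.baseq / 10.0)))
    best, _, post = genotype_posterior(obs, het_prior)
    # site quality is the evidence against ref-hom (VCF QUAL semantics),
    # not the confidence in the winning genotype
    p_ref = post[Genotype.REF_HOM]
    qual = _MAX_QUAL if p_ref <= 10 ** (-_MAX_QUAL / 10) else -10.0 * math.log10(p_ref)
    if best is Genotype.REF_HOM or qual < qual_floor:
        return None
    ref_sup = sum(1 for o in usable if o.allele == column.ref)
    alt_sup = counts[alt_allele]
    if is_indel:
        seq = alt_allele[1:]
        if alt_allele[0] == "+":
            ref, alt = column.ref, column.ref + seq
            vclass = VariantClass.INSERTION
        else:
            ref, alt = column.ref + seq, column.ref
            vclass = VariantClass.DELETION
    else:
        ref, alt = column.ref, alt_allele
        vclass = VariantClass.SNP
    call = VariantCall(
        chrom=column.chrom, pos=column.pos, ref=ref, alt=alt,
        variant_class=vclass, depth=column.depth,
        ref_support=ref_sup, alt_support=alt_sup,
        genotype=best, quality=round(qual, 2))
    if is_indel and repeat_index is not None:
        hits = repeat_index.containing(column.chrom, column.pos - 1) or \
            repeat_index.containing(column.chrom, column.pos)
        if hits:
            ev = {"ref": [0, 0], "alt": [0, 0]}
            for o in usable:
                key = "alt" if o.allele == alt_allele else (
                    "ref" if o.allele == column.ref else None)
                if key is None:
                    continue
                ev[key][0 if o.spans_repeat else 1] += 1
            call.tandem_evidence = {k: tuple(v) for k, v in ev.items()}
    return call


def call_candidates(columns: Iterable[PileupColumn],
                    het_prior: float = HET_PRIOR_DEFAULT,
                    qual_floor: float = QUAL_FLOOR_DEFAULT,
                    repeats: Sequence[TandemRepeatRegion] = ()
                    ) -> List[VariantCall]:
    """Emit a call per column whose maximum-posterior genotype is non-ref."""
    index = _RepeatIndex(repeats) if repeats else None
    calls = []
    for column in columns:
        call = call_column(column, het_prior, qual_floor, index)
        if call is not None:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# pileup construction from alignments

class _Read:
    """Minimal per-read view for pileup collection (cheaper than the full
    :class:`AlignedRead` on multi-million-read inputs)."""

    __slots__ = ("start", "end", "sequence", "qualities", "cigartuples",
                 "mapping_quality")

    def __init__(self, rec) -> None:
        self.start = rec.reference_start
        self.end = rec.reference_end or rec.reference_start
        self.sequence = rec.query_sequence
        self.qualities = rec.query_qualities
        self.cigartuples = rec.cigartuples
        self.mapping_quality = rec.mapping_quality


def build_pileup(alignment_path: str, genome: GenomeIndex, chrom: str,
                 repeats: Sequence[TandemRepeatRegion] = (),
                 min_mapq: int = MIN_MAPQ_DEFAULT
                 ) -> Tuple[List[PileupColumn], np.ndarray]:
    """Pileup columns at every position with non-reference evidence.

    Two streaming passes over the alignments: the first collects non-ref
    observations and the coverage track, the second back-fills reference
    observations at candidate positions only.  Returns (columns, per-base
    depth) for ``chrom``.
    """
    import pysam

    length = genome.lengths[chrom]
    refseq = genome.fetch(chrom, 0, length)
    repeat_index = _RepeatIndex(repeats)
    delta = np.zeros(length + 1, dtype=np.int64)
    nonref: Dict[int, List[Observation]] = {}

    def repeat_flags(read, pos0: int) -> Tuple[bool, bool]:
        # indel anchors sit one base left of the repeat: check both columns
        hits = repeat_index.containing(chrom, pos0) or \
            repeat_index.containing(chrom, pos0 + 1)
        if not hits:
            return False, False
        spans = True
        end_in = False
        for i in hits:
            rep = repeat_index.get(chrom, i)
            spans = spans and rep.spanned_by(read.start, read.end)
            end_in = end_in or rep.contains(read.start) or rep.contains(read.end - 1)
        return end_in, spans

    def stream():
        with pysam.AlignmentFile(str(alignment_path)) as af:
            if chrom not in af.references:
                raise ValueError(f"unknown sequence name {chrom!r} in {alignment_path}")
            for rec in af:
                if rec.is_unmapped or rec.mapping_quality < min_mapq:
                    continue
                if rec.reference_name != chrom:
                    continue
                yield _Read(rec)

    for read in stream():
        if read.cigartuples and len(read.cigartuples) == 1:
            delta[max(read.start, 0)] += 1
            delta[min(read.end, length)] -= 1
        else:
            rpos = read.start
            for op, ln in read.cigartuples or ():
                if op in (0, 7, 8):
                    delta[max(rpos, 0)] += 1
                    delta[min(rpos + ln, length)] -= 1
                    rpos += ln
                elif op in (2, 3):
                    rpos += ln
        _collect_nonref(read, refseq, nonref, repeat_flags)
    depth = np.cumsum(delta[:-1])
    if not nonref:
        return [], depth

    cand = np.array(sorted(nonref), dtype=np.int64)
    for read in stream():
        _collect_ref(read, refseq, nonref, cand, repeat_flags)

    columns = []
    for pos0 in cand:
        columns.append(PileupColumn(
            chrom=chrom, pos=int(pos0) + 1, ref=refseq[pos0],
            observations=nonref[int(pos0)]))
    return columns, depth


def _collect_nonref(read: AlignedRead, refseq: str,
                    nonref: Dict[int, List[Observation]], repeat_flags) -> None:
    seq = read.sequence
    quals = read.qualities
    if seq is None or read.cigartuples is None:
        return
    rpos, qpos = read.start, 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):                       # M/=/X
            ref_chunk = refseq[rpos:rpos + ln]
            chunk = seq[qpos:qpos + ln]
            if chunk != ref_chunk:
                for i in range(ln):
                    if chunk[i] != ref_chunk[i] and chunk[i] != "N":
                        pos0 = rpos + i
                        end_in, spans = repeat_flags(read, pos0)
                        nonref.setdefault(pos0, []).append(Observation(
                            chunk[i], int(quals[qpos + i]) if quals is not None else 30,
                            read.mapping_quality, end_in, spans))
            rpos += ln
            qpos += ln
        elif op == 1:                             # I
            anchor = rpos - 1
            if anchor >= 0:
                end_in, spans = repeat_flags(read, anchor)
                q = int(quals[qpos]) if quals is not None else 30
                nonref.setdefault(anchor, []).append(Observation(
                    "+" + seq[qpos:qpos + ln], q, read.mapping_quality,
                    end_in, spans))
            qpos += ln
        elif op == 2:                             # D
            anchor = rpos - 1
            if anchor >= 0:
                end_in, spans = repeat_flags(read, anchor)
                q = int(quals[qpos - 1]) if quals is not None and qpos > 0 else 30
                nonref.setdefault(anchor, []).append(Observation(
                    "-" + refseq[rpos:rpos + ln], q, read.mapping_quality,
                    end_in, spans))
            rpos += ln
        elif op == 4:                             # S
            qpos += ln
        elif op == 3:                             # N
            rpos += ln


def _collect_ref(read: AlignedRead, refseq: str,
                 nonref: Dict[int, List[Observation]],
                 cand: np.ndarray, repeat_flags) -> None:
    seq = read.sequence
    quals = read.qualities
    if seq is None or read.cigartuples is None:
        return
    rpos, qpos = read.start, 0
    n_ops = len(read.cigartuples)
    for op_idx, (op, ln) in enumerate(read.cigartuples):
        if op in (0, 7, 8):
            lo = int(np.searchsorted(cand, rpos))
            # the last base of a non-final M block anchors a following
            # indel op: that read already contributed the indel observation
            block_end = rpos + ln if op_idx == n_ops - 1 else rpos + ln - 1
            hi = int(np.searchsorted(cand, block_end))
            for pos0 in cand[lo:hi]:
                i = int(pos0) - rpos
                if seq[qpos + i] == refseq[pos0]:
                    end_in, spans = repeat_flags(read, int(pos0))
                    nonref[int(pos0)].append(Observation(
                        refseq[pos0],
                        int(quals[qpos + i]) if quals is not None else 30,
                        read.mapping_quality, end_in, spans))
            rpos += ln
            qpos += ln
        elif op == 1:
            qpos += ln
        elif op in (2, 3):
            rpos += ln
        elif op == 4:
            qpos += ln


def call_sample(alignment_path: str, genome: GenomeIndex,
                repeats: Sequence[TandemRepeatRegion] = (),
                min_mapq: int = MIN_MAPQ_DEFAULT,
                het_prior: float = HET_PRIOR_DEFAULT,
                qual_floor: float = QUAL_FLOOR_DEFAULT,
                chroms: Optional[Sequence[str]] = None
                ) -> Tuple[List[VariantCall], float]:
    """Run the full caller over a coordinate-sorted alignment file.

    Returns (candidate calls, genome-wide mean depth of mapq-passing reads).
    """
    calls: List[VariantCall] = []
    depth_sum = 0.0
    base_total = 0
    for chrom in (chroms or genome.names):
        columns, depth = build_pileup(alignment_path, genome, chrom,
                                      repeats, min_mapq)
        calls.extend(call_candidates(columns, het_prior, qual_floor, repeats))
        depth_sum += float(depth.sum())
        base_total += genome.lengths[chrom]
    mean_depth = depth_sum / base_total if base_total else 0.0
    return calls, mean_depth


def import_vcf(path: str) -> List[VariantCall]:
    """Ingest third-party calls; multi-allelics are split, symbolic alts skipped."""
    calls = mio.read_vcf(path)
    for call in calls:
        call.provenance = "imported"
        if call.ref_support + call.alt_support == 0 and call.genotype is not Genotype.REF_HOM:
            call.refinable = False
            warnings.warn(
                f"record {call.chrom}:{call.pos} lacks allele depths; "
                "marked unrefinable", stacklevel=2)
    return calls
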