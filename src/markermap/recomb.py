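"""Genotyping meiotic progeny against refined parental markers.

Per-marker allelic ratios are smoothed over sliding windows; runs of
same-genotype windows become blocks, block junctions become crossovers
(refined to the flanking informative markers), and markers contradicting
their surrounding block are grouped into gene-conversion events.

Ratio conventions follow the window-genotype definition: the per-marker
ratio is maternal-over-total, the per-window ratio paternal-over-total, and
a window is paternal-homozygous at ratio >= 0.8, maternal-homozygous at
<= 0.2, heterozygous in between.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .core import Genotype, VariantCall, VariantClass

log = logging.getLogger(__name__)

WINDOW_DEFAULT = 20_000
STEP_DEFAULT = 10_000
HOM_RATIO = 0.8                 # >= paternal-hom ; <= 1-HOM_RATIO maternal-hom
MIN_INFORMATIVE_DEFAULT = 5
GC_GROUP_DISTANCE = 1_000       # bp between adjacent converted markers
GC_MIN_READS_DEFAULT = 5
CO_SEARCH_SPAN = 50_000


class WindowGenotype(str, enum.Enum):
    PATERNAL = "paternal-hom"
    HET = "heterozygous"
    MATERNAL = "maternal-hom"
    UNCALLED = "uncalled"


@dataclass
class Marker:
    """A refined parental polymorphism with its parent-of-origin alleles."""

    chrom: str
    pos: int                     # 1-based
    ref: str
    alt: str
    paternal: str                # allele carried by the paternal genome
    maternal: str
    variant_class: VariantClass = VariantClass.SNP


def markers_from_calls(calls: Sequence[VariantCall],
                       alt_parent: str = "maternal") -> List[Marker]:
    """Designate parental alleles on PASS calls: the alternate allele belongs
    to ``alt_parent`` (the resequenced ecotype), the reference allele to the
    other parent.  The reference genome need not be either parent; the
    designation is the caller's responsibility."""
    if alt_parent not in ("maternal", "paternal"):
        raise ValueError("alt_parent must be 'maternal' or 'paternal'")
    markers = []
    for call in calls:
        if not call.is_pass:
            continue
        if alt_parent == "maternal":
            pat, mat = call.ref, call.alt
        else:
            pat, mat = call.alt, call.ref
        markers.append(Marker(call.chrom, call.pos, call.ref, call.alt,
                              pat, mat, call.variant_class))
    markers.sort(key=lambda m: (m.chrom, m.pos))
    return markers


@dataclass
class MarkerObservation:
    marker: Marker
    p_supp: int                  # paternal-allele reads
    m_supp: int                  # maternal-allele reads

    @property
    def informative(self) -> int:
        return self.p_supp + self.m_supp

    @property
    def ratio_s(self) -> Optional[float]:
        """Maternal fraction; None (masked) at zero coverage."""
        total = self.p_supp + self.m_supp
        return self.m_supp / total if total else None


@dataclass
class GenotypeWindow:
    chrom: str
    start: int                   # 0-based half-open
    end: int
    p_sum: int
    m_sum: int
    n_informative: int

    @property
    def ratio_w(self) -> Optional[float]:
        total = self.p_sum + self.m_sum
        return self.p_sum / total if total else None

    call: WindowGenotype = WindowGenotype.UNCALLED


@dataclass
class GenotypeBlock:
    chrom: str
    start: int
    end: int
    genotype: WindowGenotype
    n_windows: int = 0


@dataclass
class CrossoverEvent:
    chrom: str
    left: int                    # boundary interval, 1-based inclusive bounds
    right: int
    left_genotype: WindowGenotype
    right_genotype: WindowGenotype
    low_resolution: bool = False

    def __post_init__(self) -> None:
        if self.left_genotype == self.right_genotype:
            raise ValueError("crossover flanks share a genotype")
        if self.right <= self.left:
            raise ValueError("crossover boundary interval must have positive length")


@dataclass
class GeneConversionEvent:
    chrom: str
    positions: List[int]         # converted marker positions, 1-based
    background: WindowGenotype
    converted_to: WindowGenotype

    @property
    def span(self) -> int:
        return self.positions[-1] - self.positions[0] + 1


# ---------------------------------------------------------------------------

def window_size(depth: float, genome_size: float, snp_number: float) -> int:
    """Empirical window size: (2x10^3 / depth) x (genome size / SNP count),
    rounded to the nearest kb and floored at 1 kb."""
    if depth <= 0 or genome_size <= 0 or snp_number <= 0:
        raise ValueError("window_size arguments must all be positive")
    raw = 2e3 / depth * genome_size / snp_number
    return max(1_000, int(round(raw / 1_000)) * 1_000)


# ---------------------------------------------------------------------------
# marker genotyping from progeny alignments

def genotype_markers(alignment_path: str, markers: Sequence[Marker],
                     min_mapq: int = 20) -> List[MarkerObservation]:
    """Count paternal/maternal-allele reads per marker.

    Reads below ``min_mapq`` are ignored; read bases matching neither
    parental allele are counted as neither (other).  Zero-coverage markers
    stay in the output with a masked ratio.
    """
    order = sorted(range(len(markers)), key=lambda i: (markers[i].chrom, markers[i].pos))
    by_chrom: Dict[str, Tuple[np.ndarray, List[int]]] = {}
    for i in order:
        m = markers[i]
        by_chrom.setdefault(m.chrom, ([], []))  # type: ignore[arg-type]
    tmp_pos: Dict[str, List[int]] = {c: [] for c in by_chrom}
    tmp_idx: Dict[str, List[int]] = {c: [] for c in by_chrom}
    for i in order:
        m = markers[i]
        tmp_pos[m.chrom].append(m.pos - 1)
        tmp_idx[m.chrom].append(i)
    pos_arr = {c: np.asarray(v, dtype=np.int64) for c, v in tmp_pos.items()}
    idx_arr = {c: v for c, v in tmp_idx.items()}

    p_counts = np.zeros(len(markers), dtype=np.int64)
    m_counts = np.zeros(len(markers), dtype=np.int64)

    with pysam.AlignmentFile(str(alignment_path)) as af:
        for rec in af:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            positions = pos_arr.get(chrom)
            if positions is None:
                continue
            start = rec.reference_start
            end = rec.reference_end or start
            lo = int(np.searchsorted(positions, start))
            hi = int(np.searchsorted(positions, end))
            if lo == hi:
                continue
            seq = rec.query_sequence
            cig = rec.cigartuples
            simple = cig is not None and len(cig) == 1 and cig[0][0] == 0
            pairs = None
            for j in range(lo, hi):
                marker = markers[idx_arr[chrom][j]]
                pos0 = int(positions[j])
                if marker.variant_class is VariantClass.SNP:
                    if simple:
                        base = seq[pos0 - start]
                    else:
                        if pairs is None:
                            pairs = {rp: qp for qp, rp in rec.get_aligned_pairs(matches_only=True)}
                        qp = pairs.get(pos0)
                        base = seq[qp] if qp is not None else None
                    if base == marker.paternal:
                        p_counts[idx_arr[chrom][j]] += 1
                    elif base == marker.maternal:
                        m_counts[idx_arr[chrom][j]] += 1
                else:
                    allele = _read_indel_allele(rec, marker, pos0)
                    if allele == "ref":
                        which = marker.paternal == marker.ref
                        (p_counts if which else m_counts)[idx_arr[chrom][j]] += 1
                    elif allele == "alt":
                        which = marker.paternal == marker.alt
                        (p_counts if which else m_counts)[idx_arr[chrom][j]] += 1
    return [MarkerObservation(markers[i], int(p_counts[i]), int(m_counts[i]))
            for i in range(len(markers))]


def _read_indel_allele(rec, marker: Marker, pos0: int) -> Optional[str]:
    """'ref'/'alt'/None for an indel marker, requiring the read to span the
    anchor with at least one base on each side."""
    if rec.reference_start >= pos0 or (rec.reference_end or 0) <= pos0 + 1:
        return None
    rpos = rec.reference_start
    qpos = 0
    expect_del = len(marker.ref) > len(marker.alt)
    indel_len = abs(len(marker.ref) - len(marker.alt))
    for op, ln in rec.cigartuples or ():
        if op in (0, 7, 8):
            rpos += ln
            qpos += ln
            if rpos - 1 == pos0:
                continue
        elif op == 1:
            if rpos - 1 == pos0:
                return "alt" if (not expect_del and ln == indel_len) else None
            qpos += ln
        elif op == 2:
            if rpos - 1 == pos0:
                return "alt" if (expect_del and ln == indel_len) else None
            rpos += ln
        elif op == 4:
            qpos += ln
    return "ref"


# ---------------------------------------------------------------------------
# sliding windows

def call_windows(observations: Sequence[MarkerObservation], window: int,
                 step: int, chrom_lengths: Optional[Dict[str, int]] = None,
                 min_informative: int = MIN_INFORMATIVE_DEFAULT,
                 hom_ratio: float = HOM_RATIO) -> List[GenotypeWindow]:
    """Fixed sliding-window grid per chromosome, anchored at 0, trailing
    partial window included."""
    if window < step:
        raise ValueError("window must be >= step")
    by_chrom: Dict[str, List[MarkerObservation]] = {}
    for obs in observations:
        by_chrom.setdefault(obs.marker.chrom, []).append(obs)
    windows: List[GenotypeWindow] = []
    for chrom in sorted(by_chrom):
        obs_list = sorted(by_chrom[chrom], key=lambda o: o.marker.pos)
        length = (chrom_lengths or {}).get(chrom, obs_list[-1].marker.pos)
        n_win = max(1, -(-max(length - window, 0) // step) + 1)
        pos0 = np.array([o.marker.pos - 1 for o in obs_list], dtype=np.int64)
        p = np.array([o.p_supp for o in obs_list], dtype=np.int64)
        m = np.array([o.m_supp for o in obs_list], dtype=np.int64)
        informative = (p + m) > 0
        p_sum = np.zeros(n_win, dtype=np.int64)
        m_sum = np.zeros(n_win, dtype=np.int64)
        n_inf = np.zeros(n_win, dtype=np.int64)
        max_offsets = -(-window // step)
        base_idx = pos0 // step
        for j in range(max_offsets):
            idx = base_idx - j
            valid = (idx >= 0) & (idx < n_win) & (pos0 < idx * step + window)
            np.add.at(p_sum, idx[valid], p[valid])
            np.add.at(m_sum, idx[valid], m[valid])
            np.add.at(n_inf, idx[valid], informative[valid].astype(np.int64))
        for k in range(n_win):
            start = k * step
            end = min(start + window, max(length, start + 1))
            win = GenotypeWindow(chrom, start, end, int(p_sum[k]),
                                 int(m_sum[k]), int(n_inf[k]))
            win.call = _window_genotype(win, min_informative, hom_ratio)
            windows.append(win)
    return windows


def _window_genotype(win: GenotypeWindow, min_informative: int,
                     hom_ratio: float) -> WindowGenotype:
    if win.n_informative < min_informative or win.ratio_w is None:
        return WindowGenotype.UNCALLED
    if win.ratio_w >= hom_ratio:
        return WindowGenotype.PATERNAL
    # compare the maternal fraction against the same threshold rather than
    # ratio_w against 1 - threshold, which is not float-exact
    if win.m_sum / (win.p_sum + win.m_sum) >= hom_ratio:
        return WindowGenotype.MATERNAL
    return WindowGenotype.HET


# ---------------------------------------------------------------------------
# blocks and crossovers

def merge_blocks(windows: Sequence[GenotypeWindow],
                 observations: Sequence[MarkerObservation] = (),
                 marker_min_reads: int = 3,
                 search_span: int = CO_SEARCH_SPAN
                 ) -> Tuple[List[GenotypeBlock], List[CrossoverEvent]]:
    """Group same-genotype window runs into blocks and call a crossover at
    every genotype switch, refining its boundary to the flanking informative
    markers."""
    by_chrom: Dict[str, List[GenotypeWindow]] = {}
    for win in windows:
        by_chrom.setdefault(win.chrom, []).append(win)
    obs_by_chrom: Dict[str, List[MarkerObservation]] = {}
    for obs in observations:
        obs_by_chrom.setdefault(obs.marker.chrom, []).append(obs)

    blocks: List[GenotypeBlock] = []
    events: List[CrossoverEvent] = []
    for chrom in sorted(by_chrom):
        wins = sorted(by_chrom[chrom], key=lambda w: w.start)
        chrom_blocks = _blocks_one_chrom(wins)
        blocks.extend(chrom_blocks)
        obs_list = sorted(obs_by_chrom.get(chrom, []), key=lambda o: o.marker.pos)
        for left, right in zip(chrom_blocks, chrom_blocks[1:]):
            events.append(_refine_junction(left, right, obs_list,
                                           marker_min_reads, search_span))
    return blocks, events


def _blocks_one_chrom(wins: List[GenotypeWindow]) -> List[GenotypeBlock]:
    blocks: List[GenotypeBlock] = []
    for win in wins:
        gt = win.call
        if gt is WindowGenotype.UNCALLED:
            continue                 # absorbed: uncalled windows carry no vote
        if blocks and blocks[-1].genotype == gt:
            blocks[-1].end = win.end
            blocks[-1].n_windows += 1
        else:
            blocks.append(GenotypeBlock(win.chrom, win.start, win.end, gt, 1))
    return blocks


_GT_TO_MARKER = {WindowGenotype.PATERNAL: "P", WindowGenotype.MATERNAL: "M",
                 WindowGenotype.HET: "H"}


def _marker_class(obs: MarkerObservation, min_reads: int,
                  hom_ratio: float = HOM_RATIO) -> Optional[str]:
    total = obs.informative
    if total < min_reads or obs.ratio_s is None:
        return None
    if obs.ratio_s >= hom_ratio:
        return "M"
    if obs.ratio_s <= 1.0 - hom_ratio:
        return "P"
    return "H"


def _refine_junction(left: GenotypeBlock, right: GenotypeBlock,
                     obs_list: List[MarkerObservation],
                     min_reads: int, search_span: int) -> CrossoverEvent:
    junction = (left.end + right.start) // 2
    lo = junction - max(search_span, left.end - left.start)
    hi = junction + max(search_span, right.end - right.start)
    lo = max(lo, left.start)
    hi = min(hi, right.end)
    want_left = _GT_TO_MARKER[left.genotype]
    want_right = _GT_TO_MARKER[right.genotype]
    flank = [(o.marker.pos, _marker_class(o, min_reads))
             for o in obs_list if lo <= o.marker.pos <= hi]
    flank = [(pos, cls) for pos, cls in flank if cls in (want_left, want_right)]
    gap_lo = min(left.end, right.start)
    gap_hi = max(left.end, right.start) + 1
    if not flank or all(c == flank[0][1] for _, c in flank):
        return CrossoverEvent(left.chrom, gap_lo, gap_hi,
                              left.genotype, right.genotype, low_resolution=True)
    # optimal changepoint: maximise left-consistent before + right-consistent after
    n = len(flank)
    left_cum = np.cumsum([1 if c == want_left else 0 for _, c in flank])
    right_cum = np.cumsum([1 if c == want_right else 0 for _, c in flank][::-1])[::-1]
    scores = [
        (left_cum[i - 1] if i > 0 else 0) + (right_cum[i] if i < n else 0)
        for i in range(n + 1)]
    cut = int(np.argmax(scores))
    left_pos = next((flank[i][0] for i in range(cut - 1, -1, -1)
                     if flank[i][1] == want_left), None)
    right_pos = next((flank[i][0] for i in range(cut, n)
                      if flank[i][1] == want_right), None)
    if left_pos is None or right_pos is None or right_pos <= left_pos:
        return CrossoverEvent(left.chrom, gap_lo, gap_hi,
                              left.genotype, right.genotype, low_resolution=True)
    return CrossoverEvent(left.chrom, left_pos, right_pos,
                          left.genotype, right.genotype)


# ---------------------------------------------------------------------------
# gene conversions

def detect_gc(observations: Sequence[MarkerObservation],
              blocks: Sequence[GenotypeBlock],
              window: int = WINDOW_DEFAULT,
              min_reads: int = GC_MIN_READS_DEFAULT,
              group_distance: int = GC_GROUP_DISTANCE,
              include_het_background: bool = False
              ) -> List[GeneConversionEvent]:
    """Markers contradicting their homozygous block are converted loci;
    converted markers closer than ``group_distance`` merge into one event.
    Block edges abutting a crossover junction are excluded by one window."""
    obs_by_chrom: Dict[str, List[MarkerObservation]] = {}
    for obs in observations:
        obs_by_chrom.setdefault(obs.marker.chrom, []).append(obs)
    blocks_by_chrom: Dict[str, List[GenotypeBlock]] = {}
    for block in blocks:
        blocks_by_chrom.setdefault(block.chrom, []).append(block)

    events: List[GeneConversionEvent] = []
    for chrom, chrom_blocks in sorted(blocks_by_chrom.items()):
        chrom_blocks = sorted(chrom_blocks, key=lambda b: b.start)
        obs_list = sorted(obs_by_chrom.get(chrom, []), key=lambda o: o.marker.pos)
        for bi, block in enumerate(chrom_blocks):
            if block.genotype is WindowGenotype.HET and not include_het_background:
                continue
            lo = block.start + (window if bi > 0 else 0)
            hi = block.end - (window if bi < len(chrom_blocks) - 1 else 0)
            converted: List[Tuple[int, str]] = []
            for obs in obs_list:
                pos = obs.marker.pos
                if not lo <= pos - 1 < hi:
                    continue
                cls = _converted_class(obs, block.genotype, min_reads)
                if cls is not None:
                    converted.append((pos, cls))
            events.extend(_group_converted(chrom, converted, block.genotype,
                                           group_distance))
    return events


def _converted_class(obs: MarkerObservation, background: WindowGenotype,
                     min_reads: int) -> Optional[str]:
    """'full' or 'het' when this marker contradicts the background genotype."""
    if obs.ratio_s is None:
        return None
    if background is WindowGenotype.PATERNAL:
        opposite = obs.m_supp
    elif background is WindowGenotype.MATERNAL:
        opposite = obs.p_supp
    else:                                    # het background: hom either way
        opposite = max(obs.p_supp, obs.m_supp)
        if min(obs.p_supp, obs.m_supp) > 0:
            return None
        return "full" if opposite >= min_reads and obs.informative >= min_reads else None
    if opposite < min_reads:
        return None
    toward_other = opposite / obs.informative
    if toward_other >= HOM_RATIO:
        return "full"
    if toward_other > 1.0 - HOM_RATIO:
        return "het"
    return None


def _group_converted(chrom: str, converted: List[Tuple[int, str]],
                     background: WindowGenotype,
                     group_distance: int) -> List[GeneConversionEvent]:
    events: List[GeneConversionEvent] = []
    group: List[Tuple[int, str]] = []

    other = (WindowGenotype.MATERNAL if background is WindowGenotype.PATERNAL
             else WindowGenotype.PATERNAL)

    def flush() -> None:
        if not group:
            return
        full = all(cls == "full" for _, cls in group)
        to = other if (full and background is not WindowGenotype.HET) else WindowGenotype.HET
        if background is WindowGenotype.HET:
            to = WindowGenotype.UNCALLED     # hom direction unresolved here
        events.append(GeneConversionEvent(
            chrom, [pos for pos, _ in group], background, to))

    for pos, cls in converted:
        if group and pos - group[-1][0] >= group_distance:
            flush()
            group = []
        group.append((pos, cls))
    if group:
        flush()
    return events
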