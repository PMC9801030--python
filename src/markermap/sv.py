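"""Structural-variant signatures from paired-end distance/orientation,
read-depth windows, and split reads.

This is deliberately a signature detector, not a breakpoint-precise SV
caller: downstream refinement only needs reliable SV intervals to flag
candidate variants sitting in or near them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from . import io as mio
from .core import AlignedRead, GenomeIndex, StructuralVariant, SVClass

log = logging.getLogger(__name__)

DISCORDANCE_K = 3.0          # k standard deviations for LONG/SHORT
MIN_SUPPORT_DEFAULT = 3
DUP_DEPTH_RATIO = 2.0
DEL_DEPTH_RATIO = 0.25
CNV_WINDOW_DEFAULT = 500
DISTANT_FACTOR = 10          # mates > 10x insert mean apart
MIN_CLIP = 20                # soft-clip length counting as split-read evidence

LONG, SHORT, INVERTED, DISTANT, NORMAL = "LONG", "SHORT", "INVERTED", "DISTANT", "NORMAL"

_SIG_CLASS = {LONG: SVClass.DELETION, SHORT: SVClass.INSERTION,
              INVERTED: SVClass.INVERSION, DISTANT: SVClass.TRANSPOSITION}


@dataclass
class PairSignature:
    chrom: str
    start: int               # pair-implied interval, 0-based half-open
    end: int
    signature: str
    query_name: str
    remote: Optional[Tuple[str, int]] = None   # DISTANT mate anchor


def estimate_insert_stats(reads: Iterable[AlignedRead],
                          max_pairs: int = 10000) -> Tuple[float, float]:
    """Mean/sd of template length over proper pairs (leftmost mate only)."""
    tlens = []
    for read in reads:
        if read.is_proper_pair and read.template_length > 0:
            tlens.append(read.template_length)
            if len(tlens) >= max_pairs:
                break
    if len(tlens) < 100:
        raise ValueError(
            f"only {len(tlens)} proper pairs found; supply insert statistics")
    arr = np.asarray(tlens, dtype=float)
    return float(arr.mean()), float(arr.std())


def classify_pair(read: AlignedRead, insert_mean: float, insert_sd: float,
                  k: float = DISCORDANCE_K) -> Optional[PairSignature]:
    """Signature of one pair, reported from its leftmost mate; None for
    unpaired reads or the rightmost mate."""
    if not read.is_paired or read.mate_start is None:
        return None
    if read.mate_reference_name != read.reference_name:
        return PairSignature(read.reference_name,
                             read.end, read.end + 1, DISTANT, read.query_name,
                             remote=(read.mate_reference_name, read.mate_start))
    if read.template_length < 0:
        return None                      # counted at the leftmost mate
    if read.template_length == 0 and read.start > read.mate_start:
        return None
    tlen = read.template_length
    if tlen > DISTANT_FACTOR * insert_mean:
        return PairSignature(read.reference_name, read.end, read.mate_start,
                             DISTANT, read.query_name,
                             remote=(read.mate_reference_name, read.mate_start))
    if read.mate_is_reverse is not None and read.is_reverse == read.mate_is_reverse:
        inner = sorted((read.start, read.mate_start))
        return PairSignature(read.reference_name, inner[0], inner[1] + 1,
                             INVERTED, read.query_name)
    if tlen > insert_mean + k * insert_sd:
        # implied deletion sits between the inner ends of the two mates
        return PairSignature(read.reference_name, read.end,
                             max(read.end + 1, read.mate_start),
                             LONG, read.query_name)
    if 0 < tlen < insert_mean - k * insert_sd:
        return PairSignature(read.reference_name, read.end,
                             max(read.end + 1, read.mate_start),
                             SHORT, read.query_name)
    return PairSignature(read.reference_name, read.start,
                         read.start + max(tlen, 1), NORMAL, read.query_name)


def classify_pairs(reads: Iterable[AlignedRead], insert_mean: float,
                   insert_sd: float, k: float = DISCORDANCE_K
                   ) -> List[PairSignature]:
    out = []
    for read in reads:
        sig = classify_pair(read, insert_mean, insert_sd, k)
        if sig is not None:
            out.append(sig)
    return out


def _cluster_one_class(sigs: List[PairSignature], min_support: int
                       ) -> List[StructuralVariant]:
    """Merge overlapping same-signature intervals; breakpoint interval is the
    intersection of the pair-implied intervals in the cluster."""
    sigs = sorted(sigs, key=lambda s: (s.chrom, s.start, s.end))
    svs: List[StructuralVariant] = []
    cluster: List[PairSignature] = []

    def flush() -> None:
        if len(cluster) >= min_support:
            istart = max(s.start for s in cluster)
            iend = min(s.end for s in cluster)
            if iend <= istart:           # degenerate intersection
                istart = min(s.start for s in cluster)
                iend = max(s.end for s in cluster)
            sv = StructuralVariant(
                sv_class=_SIG_CLASS[cluster[0].signature],
                chrom=cluster[0].chrom, start=istart, end=iend,
                pair_support=len(cluster))
            sv._remotes = [s.remote for s in cluster if s.remote]  # type: ignore[attr-defined]
            svs.append(sv)

    cur_end = -1
    cur_chrom = None
    # DISTANT evidence is a breakend, not an interval: allow a join gap
    gap = 500 if (sigs and sigs[0].signature == DISTANT) else 0
    for sig in sigs:
        if cluster and (sig.chrom != cur_chrom or sig.start >= cur_end + gap):
            flush()
            cluster = []
        cluster.append(sig)
        cur_chrom = sig.chrom
        cur_end = max(cur_end if cluster[:-1] else -1, sig.end)
    if cluster:
        flush()
    return svs


def cluster_signatures(signatures: Iterable[PairSignature],
                       min_support: int = MIN_SUPPORT_DEFAULT
                       ) -> List[StructuralVariant]:
    """Cluster discordant signatures into SV calls.

    Loci supported by two or more distinct signature classes collapse into a
    single ``complex`` SV — except a deletion co-located with DISTANT mates
    anchoring to one remote locus, which is the read-pair pattern of a
    transposed element and is labelled ``transposition``.
    """
    by_class: Dict[str, List[PairSignature]] = {}
    for sig in signatures:
        if sig.signature == NORMAL:
            continue
        by_class.setdefault(sig.signature, []).append(sig)
    raw: List[StructuralVariant] = []
    for cls_sigs in by_class.values():
        raw.extend(_cluster_one_class(cls_sigs, min_support))
    raw.sort(key=lambda s: (s.chrom, s.start, s.end))

    merged: List[StructuralVariant] = []
    for sv in raw:
        if merged and sv.chrom == merged[-1].chrom and sv.start < merged[-1].end:
            prev = merged[-1]
            combined_class = _combine_classes(prev, sv)
            prev.sv_class = combined_class
            prev.start = min(prev.start, sv.start)
            prev.end = max(prev.end, sv.end)
            prev.pair_support += sv.pair_support
            prev._remotes = getattr(prev, "_remotes", []) + getattr(sv, "_remotes", [])  # type: ignore[attr-defined]
        else:
            merged.append(sv)
    return merged


def _combine_classes(a: StructuralVariant, b: StructuralVariant) -> SVClass:
    classes = {a.sv_class, b.sv_class}
    if classes == {SVClass.DELETION, SVClass.TRANSPOSITION}:
        remotes = getattr(a, "_remotes", []) + getattr(b, "_remotes", [])
        if remotes and _one_remote_locus(remotes):
            return SVClass.TRANSPOSITION
    if len(classes) == 1:
        return a.sv_class
    return SVClass.COMPLEX


def _one_remote_locus(remotes: List[Tuple[str, int]], window: int = 10000,
                      fraction: float = 0.8) -> bool:
    chroms = [r[0] for r in remotes]
    top_chrom = max(set(chroms), key=chroms.count)
    positions = sorted(r[1] for r in remotes if r[0] == top_chrom)
    if not positions:
        return False
    best = 0
    j = 0
    for i in range(len(positions)):
        while positions[i] - positions[j] > window:
            j += 1
        best = max(best, i - j + 1)
    return best >= fraction * len(remotes)


def add_split_support(svs: List[StructuralVariant],
                      clip_positions: Dict[str, np.ndarray],
                      margin: int = 50) -> None:
    """Count soft-clip breakends near each SV edge (corroborating evidence
    only; never required for a call)."""
    for sv in svs:
        pos = clip_positions.get(sv.chrom)
        if pos is None or len(pos) == 0:
            continue
        near_start = np.sum(np.abs(pos - sv.start) <= margin)
        near_end = np.sum(np.abs(pos - sv.end) <= margin)
        sv.split_support = int(near_start + near_end)


def detect_cnv_by_depth(depth_windows: Dict[str, np.ndarray], window: int,
                        genome_mean_depth: float,
                        dup_ratio: float = DUP_DEPTH_RATIO,
                        del_ratio: float = DEL_DEPTH_RATIO
                        ) -> List[StructuralVariant]:
    """Duplications (>= dup_ratio x mean) and depth-supported deletions
    (<= del_ratio x mean) from fixed-window depth; qualifying runs merged."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    svs: List[StructuralVariant] = []
    for chrom in sorted(depth_windows):
        track = np.asarray(depth_windows[chrom], dtype=float)
        ratios = track / genome_mean_depth
        for mask, sv_class in ((ratios >= dup_ratio, SVClass.DUPLICATION),
                               (ratios <= del_ratio, SVClass.DELETION)):
            for start_w, end_w in _runs(mask):
                run_ratio = float(ratios[start_w:end_w].mean())
                svs.append(StructuralVariant(
                    sv_class=sv_class, chrom=chrom,
                    start=start_w * window, end=end_w * window,
                    depth_ratio=round(run_ratio, 3)))
    svs.sort(key=lambda s: (s.chrom, s.start, s.end))
    return svs


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def window_depth(alignment_path: str, genome: GenomeIndex, window: int,
                 min_mapq: int = 20) -> Tuple[Dict[str, np.ndarray], float]:
    """Per-window mean depth of mapq-passing reads, plus the genome mean."""
    tracks = {}
    covered = 0.0
    for chrom in genome.names:
        n_windows = max(1, -(-genome.lengths[chrom] // window))
        tracks[chrom] = np.zeros(n_windows, dtype=float)
    for read in mio.read_alignments(alignment_path):
        if read.mapping_quality < min_mapq:
            continue
        span = read.end - read.start
        covered += span
        tracks[read.reference_name][read.start // window] += span
    total_len = genome.total_length
    for chrom in tracks:
        length = genome.lengths[chrom]
        sizes = np.full(len(tracks[chrom]), window, dtype=float)
        if length % window:
            sizes[-1] = length % window
        tracks[chrom] /= sizes
    return tracks, covered / total_len if total_len else 0.0


def detect_svs(alignment_path: str, genome: GenomeIndex,
               insert_mean: Optional[float] = None,
               insert_sd: Optional[float] = None,
               min_support: int = MIN_SUPPORT_DEFAULT,
               min_mapq: int = 20,
               cnv_window: int = CNV_WINDOW_DEFAULT,
               k: float = DISCORDANCE_K) -> List[StructuralVariant]:
    """One-pass SV scan: pair signatures + split reads, then depth CNVs."""
    if insert_mean is None or insert_sd is None:
        insert_mean, insert_sd = estimate_insert_stats(
            mio.read_alignments(alignment_path))
    signatures: List[PairSignature] = []
    clip_positions: Dict[str, list] = {}
    for read in mio.read_alignments(alignment_path):
        if read.mapping_quality < min_mapq:
            continue
        sig = classify_pair(read, insert_mean, insert_sd, k)
        if sig is not None and sig.signature != NORMAL:
            signatures.append(sig)
        if read.cigartuples:
            first_op, first_len = read.cigartuples[0]
            last_op, last_len = read.cigartuples[-1]
            if first_op == 4 and first_len >= MIN_CLIP:
                clip_positions.setdefault(read.reference_name, []).append(read.start)
            if last_op == 4 and last_len >= MIN_CLIP:
                clip_positions.setdefault(read.reference_name, []).append(read.end)
    svs = cluster_signatures(signatures, min_support)
    add_split_support(svs, {c: np.asarray(p) for c, p in clip_positions.items()})

    tracks, mean_depth = window_depth(alignment_path, genome, cnv_window, min_mapq)
    if mean_depth > 0:
        cnvs = detect_cnv_by_depth(tracks, cnv_window, mean_depth)
        svs = _merge_cnv(svs, cnvs)
    for sv in svs:
        sv.end = min(sv.end, genome.lengths[sv.chrom])
        sv.start = max(0, sv.start)
    svs.sort(key=lambda s: (s.chrom, s.start, s.end))
    return svs


def _merge_cnv(pair_svs: List[StructuralVariant],
               cnvs: List[StructuralVariant]) -> List[StructuralVariant]:
    """Depth CNVs confirm or extend pair-based calls; depth-only calls are
    appended as their own records."""
    out = list(pair_svs)
    for cnv in cnvs:
        absorbed = False
        for sv in out:
            if sv.chrom == cnv.chrom and sv.start < cnv.end and cnv.start < sv.end:
                sv.depth_ratio = cnv.depth_ratio
                absorbed = True
                break
        if not absorbed:
            out.append(cnv)
    return out
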