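"""Fixture generator: parental genomes, artifact-bearing alignments, meiotic
progenies, and pooled F2 populations, each with complete ground truth.

Alignments are synthesized directly in reference coordinates (no external
aligner), so every artifact pattern — paralog mis-mapping inside deletions,
collapsed duplications, reads terminating inside tandem repeats — has
exactly controlled geometry.  Every generator is a pure function of
(spec, seed).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import TandemRepeatRegion

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
DEFAULT_ERROR_RATE = 0.001
DEFAULT_BASEQ = 30
_QCHAR = chr(DEFAULT_BASEQ + 33)


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class SvSpec:
    kind: str                    # deletion | duplication | inversion
    pos: int                     # 0-based ref start
    size: int
    artifact: bool = True        # emit the mis-mapping artifact pattern
    divergence_spacing: int = 120  # bp between artificial-SNP positions


@dataclass(frozen=True)
class RepeatSpec:
    pos: int
    unit: str
    copies: int
    alt_copies: Optional[int] = None   # copy number on the alternate haplotype


@dataclass
class IndelEdit:
    anchor0: int                 # 0-based position of the base before the event
    kind: str                    # 'ins' | 'del'
    seq: str
    repeat: Optional[Tuple[int, int]] = None   # enclosing repeat interval


@dataclass
class DupArtifact:
    start: int
    end: int
    div_pos: np.ndarray
    div_base: np.ndarray


@dataclass
class Haplotype:
    """Edits of one haplotype relative to the reference, plus the SV payload
    driving artifact read generation."""

    name: str
    snp_pos: np.ndarray
    snp_base: np.ndarray
    indels: List[IndelEdit] = field(default_factory=list)
    deletions: List[Tuple[int, int]] = field(default_factory=list)
    del_div: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    duplications: List[DupArtifact] = field(default_factory=list)
    inversions: List[Tuple[int, int]] = field(default_factory=list)
    weight: float = 1.0

    def subset(self, keep: np.ndarray, name: str) -> "Haplotype":
        return Haplotype(name, self.snp_pos[keep], self.snp_base[keep],
                         list(self.indels), list(self.deletions),
                         dict(self.del_div), list(self.duplications),
                         list(self.inversions), self.weight)


@dataclass
class Parents:
    chrom: str
    length: int
    ref_seq: str
    hap_alt: Haplotype           # the non-reference parent's haplotype
    repeats: List[TandemRepeatRegion]
    truth: Dict[str, pd.DataFrame]
    sv_specs: List[SvSpec] = field(default_factory=list)

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as out:
            out.write(f">{self.chrom}\n")
            for i in range(0, self.length, 70):
                out.write(self.ref_seq[i:i + 70] + "\n")

    def write_repeats_bed(self, path: str) -> None:
        from .io import write_repeats_bed
        write_repeats_bed(self.repeats, path)

    @property
    def hap_ref(self) -> Haplotype:
        return Haplotype("hapA", np.empty(0, dtype=np.int64),
                         np.empty(0, dtype="<U1"))


# ---------------------------------------------------------------------------
# make_parents

def make_parents(length: int, snp_rate: float, indel_rate: float,
                 sv_specs: Sequence[SvSpec] = (),
                 repeat_specs: Sequence[RepeatSpec] = (),
                 seed: int = 0, chrom: str = "chr1") -> Parents:
    """Reference sequence plus an alternate haplotype diverging by SNPs,
    small indels, SVs, and tandem-repeat copy changes, with truth tables."""
    if not (0 <= snp_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    _check_sv_placement(sv_specs, length)
    rng = np.random.default_rng(seed)
    seq = rng.choice(BASES, size=length)

    repeats: List[TandemRepeatRegion] = []
    repeat_iv: List[Tuple[int, int]] = []
    indels: List[IndelEdit] = []
    indel_truth = []
    for spec in repeat_specs:
        unit_arr = np.array(list(spec.unit))
        span = len(spec.unit) * spec.copies
        seq[spec.pos:spec.pos + span] = np.tile(unit_arr, spec.copies)
        # avoid accidental extra units flanking the implanted repeat
        if spec.pos > 0:
            while seq[spec.pos - 1] == spec.unit[-1]:
                seq[spec.pos - 1] = rng.choice(BASES)
        if spec.pos + span < length:
            while seq[spec.pos + span] == spec.unit[0]:
                seq[spec.pos + span] = rng.choice(BASES)
        repeats.append(TandemRepeatRegion(
            chrom, spec.pos, spec.pos + span, len(spec.unit),
            float(spec.copies), 2 * span))
        repeat_iv.append((spec.pos, spec.pos + span))
        if spec.alt_copies is not None and spec.alt_copies != spec.copies:
            delta = spec.copies - spec.alt_copies
            if delta <= 0:
                raise ValueError("only unit loss on the alternate haplotype is supported")
            del_len = delta * len(spec.unit)
            if del_len > 10:
                raise ValueError("tandem unit loss exceeds the small-indel limit")
            anchor0 = spec.pos - 1           # left-aligned, VCF-anchored
            indels.append(IndelEdit(anchor0, "del", spec.unit * delta,
                                    repeat=(spec.pos, spec.pos + span)))
            indel_truth.append((chrom, anchor0 + 1, "del", del_len, True))

    blocked = _blocked_intervals(sv_specs, repeat_iv, length, margin=600)
    allowed = _allowed_positions(length, blocked)
    n_snp = rng.binomial(len(allowed), snp_rate)
    snp_pos = np.sort(rng.choice(allowed, size=n_snp, replace=False))
    # a collapsed duplication exhibits one true allelic SNP alongside its
    # artificial divergence columns: implant it at the interval centre
    dup_centres = np.array([s.pos + s.size // 2 for s in sv_specs
                            if s.kind == "duplication"], dtype=np.int64)
    if len(dup_centres):
        snp_pos = np.unique(np.concatenate([snp_pos, dup_centres]))
    ref_bases = seq[snp_pos]
    offsets = rng.integers(1, 4, size=len(snp_pos))
    base_idx = np.searchsorted(BASES, ref_bases)
    snp_base = BASES[(base_idx + offsets) % 4]

    n_indel = rng.binomial(len(allowed), indel_rate)
    taken = set(snp_pos.tolist())
    pool = np.array([p for p in allowed if p not in taken], dtype=np.int64)
    indel_pos = np.sort(rng.choice(pool, size=min(n_indel, len(pool)), replace=False))
    kept_indel_pos = []
    prev = -100
    for pos in indel_pos:
        if pos - prev < 20:                 # keep indels well separated
            continue
        prev = pos
        kept_indel_pos.append(int(pos))
    for pos in kept_indel_pos:
        ln = int(rng.integers(1, 11))
        if rng.random() < 0.5:
            ins = "".join(rng.choice(BASES, size=ln))
            indels.append(IndelEdit(pos, "ins", ins))
            indel_truth.append((chrom, pos + 1, "ins", ln, False))
        else:
            if pos + 1 + ln >= length:
                continue
            indels.append(IndelEdit(pos, "del", "".join(seq[pos + 1:pos + 1 + ln])))
            indel_truth.append((chrom, pos + 1, "del", ln, False))
    indels.sort(key=lambda e: e.anchor0)

    ref_seq = "".join(seq)
    hap = Haplotype("hapB", snp_pos, snp_base, indels)
    sv_truth = []
    art_truth = []
    for spec in sv_specs:
        start, end = spec.pos, spec.pos + spec.size
        sv_truth.append((chrom, start, end, spec.kind, spec.artifact))
        if spec.kind == "deletion":
            hap.deletions.append((start, end))
            if spec.artifact:
                div_pos = np.arange(start + 60, end - 60, spec.divergence_spacing)
                div_base = _mutate(seq, div_pos, rng)
                hap.del_div[(start, end)] = (div_pos, div_base)
                for p, b in zip(div_pos, div_base):
                    art_truth.append((chrom, int(p) + 1, str(seq[p]), str(b), "deletion"))
        elif spec.kind == "duplication":
            div_pos = np.arange(start + 60, end - 60, spec.divergence_spacing)
            div_base = _mutate(seq, div_pos, rng)
            if spec.artifact:
                hap.duplications.append(DupArtifact(start, end, div_pos, div_base))
                for p, b in zip(div_pos, div_base):
                    art_truth.append((chrom, int(p) + 1, str(seq[p]), str(b), "duplication"))
        elif spec.kind == "inversion":
            hap.inversions.append((start, end))
        else:
            raise ValueError(f"unknown SV kind {spec.kind!r}")
    hap.deletions.sort()

    truth = {
        "snps": pd.DataFrame({
            "chrom": chrom, "pos": snp_pos + 1,
            "ref": ref_bases, "alt": snp_base}),
        "indels": pd.DataFrame(
            indel_truth, columns=["chrom", "pos", "kind", "length", "in_repeat"]),
        "svs": pd.DataFrame(
            sv_truth, columns=["chrom", "start", "end", "kind", "artifact"]),
        "repeats": pd.DataFrame(
            [(chrom, r.start, r.end, r.unit_length, r.copy_number) for r in repeats],
            columns=["chrom", "start", "end", "unit", "copies"]),
        "artificial": pd.DataFrame(
            art_truth, columns=["chrom", "pos", "ref", "alt", "source"]),
    }
    return Parents(chrom, length, ref_seq, hap, repeats, truth, list(sv_specs))


def _mutate(seq: np.ndarray, positions: np.ndarray, rng) -> np.ndarray:
    idx = np.searchsorted(BASES, seq[positions])
    return BASES[(idx + rng.integers(1, 4, size=len(positions))) % 4]


def _check_sv_placement(sv_specs: Sequence[SvSpec], length: int) -> None:
    iv = sorted((s.pos, s.pos + s.size) for s in sv_specs)
    prev_end = -1
    for start, end in iv:
        if start < 0 or end > length:
            raise ValueError("SV outside the sequence")
        if start < prev_end:
            raise ValueError("overlapping SV placements")
        prev_end = end


def _blocked_intervals(sv_specs, repeat_iv, length, margin) -> List[Tuple[int, int]]:
    iv = [(max(0, s.pos - margin), min(length, s.pos + s.size + margin))
          for s in sv_specs]
    iv += [(max(0, a - 30), min(length, b + 30)) for a, b in repeat_iv]
    iv.append((0, 200))
    iv.append((length - 200, length))
    return sorted(iv)


def _allowed_positions(length: int, blocked: List[Tuple[int, int]]) -> np.ndarray:
    mask = np.ones(length, dtype=bool)
    for a, b in blocked:
        mask[a:b] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# alignment synthesis

def write_alignments(parents: Parents, haplotypes: Sequence[Haplotype],
                     depth: float, read_len: int = 100,
                     insert_mean: float = 500.0, insert_sd: float = 50.0,
                     seed: int = 0, path: str = "reads.sam",
                     artifacts: bool = True,
                     error_rate: float = DEFAULT_ERROR_RATE,
                     sample: str = "sim") -> Dict[str, int]:
    """Emit a coordinate-sorted SAM with the requested artifact patterns.

    Haplotype weights are normalised to 1; ``depth`` is total fold-coverage.
    Returns counters (pairs per haplotype, artifact reads per class).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    L = parents.length
    chrom = parents.chrom
    refseq = parents.ref_seq
    total_w = sum(h.weight for h in haplotypes)
    stats: Dict[str, int] = {}

    starts: List[np.ndarray] = []
    mate_starts: List[np.ndarray] = []
    tlens: List[np.ndarray] = []
    flags: List[np.ndarray] = []
    hap_ids: List[np.ndarray] = []
    kinds: List[np.ndarray] = []    # 0 normal, 1 paralog-art, 2 dup-art, 3 inverted
    mapqs: List[np.ndarray] = []

    for hap_id, hap in enumerate(haplotypes):
        frac = hap.weight / total_w
        n_pairs = int(round(frac * depth * L / (2 * read_len)))
        stats[f"pairs_{hap.name}"] = n_pairs
        frag = np.clip(rng.normal(insert_mean, insert_sd, size=n_pairs),
                       2 * read_len, None).astype(np.int64)
        s = rng.integers(0, np.maximum(L - frag, 1))
        s, r2, tlen = _pair_geometry(s, frag, read_len, hap.deletions, L, rng)
        f1 = np.full(n_pairs, 99, dtype=np.int32)
        f2 = np.full(n_pairs, 147, dtype=np.int32)
        discord = tlen > insert_mean + 3 * insert_sd
        f1[discord] = 97
        f2[discord] = 145
        starts += [s, r2]
        mate_starts += [r2, s]
        tlens += [tlen, -tlen]
        flags += [f1, f2]
        hap_ids += [np.full(n_pairs, hap_id, dtype=np.int32)] * 2
        kinds += [np.zeros(n_pairs, dtype=np.int8)] * 2
        mapqs += [np.full(n_pairs, 60, dtype=np.int16)] * 2

        if not artifacts:
            continue
        frac_cov = frac * depth
        for (ds, de) in hap.deletions:
            if (ds, de) not in hap.del_div:
                continue
            n_art = max(4, int(round(0.7 * frac_cov * (de - ds) / read_len)))
            a = rng.integers(ds, max(ds + 1, de - read_len), size=n_art)
            remote = (ds + L // 2) % max(1, L - 2000)
            starts.append(a)
            mate_starts.append(np.full(n_art, remote, dtype=np.int64))
            tlens.append(np.zeros(n_art, dtype=np.int64))
            flags.append(np.full(n_art, 97, dtype=np.int32))
            hap_ids.append(np.full(n_art, hap_id, dtype=np.int32))
            kinds.append(np.full(n_art, 1, dtype=np.int8))
            mapqs.append(np.full(n_art, 40, dtype=np.int16))
            stats["paralog_reads"] = stats.get("paralog_reads", 0) + n_art
        for dup in hap.duplications:
            # collapsed copy: pairs fall entirely inside the interval, so the
            # local depth doubles and divergence columns become het-like
            span = dup.end - dup.start
            n_art = max(4, int(round(frac_cov * span / (2 * read_len))))
            frag_a = np.clip(rng.normal(insert_mean, insert_sd, size=n_art),
                             2 * read_len, max(2 * read_len, span)).astype(np.int64)
            a = rng.integers(dup.start, np.maximum(dup.start + 1, dup.end - frag_a))
            r2a = a + frag_a - read_len
            starts += [a, r2a]
            mate_starts += [r2a, a]
            tlens += [frag_a, -frag_a]
            flags += [np.full(n_art, 99, dtype=np.int32),
                      np.full(n_art, 147, dtype=np.int32)]
            hap_ids += [np.full(n_art, hap_id, dtype=np.int32)] * 2
            kinds += [np.full(n_art, 2, dtype=np.int8)] * 2
            mapqs += [np.full(n_art, 60, dtype=np.int16)] * 2
            stats["dup_reads"] = stats.get("dup_reads", 0) + 2 * n_art
        for (istart, iend) in hap.inversions:
            n_inv = max(6, int(round(frac_cov / 3)))
            a = np.clip(istart - rng.integers(read_len, int(insert_mean),
                                              size=n_inv), 0, None)
            b = np.clip(iend - (a + int(insert_mean) - istart), 0, L - read_len)
            starts += [a, b]
            mate_starts += [b, a]
            tlens += [b + read_len - a, -(b + read_len - a)]
            flags += [np.full(n_inv, 65, dtype=np.int32),
                      np.full(n_inv, 129, dtype=np.int32)]
            hap_ids += [np.full(n_inv, hap_id, dtype=np.int32)] * 2
            kinds += [np.full(n_inv, 3, dtype=np.int8)] * 2
            mapqs += [np.full(n_inv, 60, dtype=np.int16)] * 2
            stats["inv_reads"] = stats.get("inv_reads", 0) + 2 * n_inv

    start_all = np.concatenate(starts)
    mate_all = np.concatenate(mate_starts)
    tlen_all = np.concatenate(tlens)
    flag_all = np.concatenate(flags)
    hap_all = np.concatenate(hap_ids)
    kind_all = np.concatenate(kinds)
    mapq_all = np.concatenate(mapqs)
    start_all = np.clip(start_all, 0, L - read_len)
    mate_all = np.clip(mate_all, 0, L - read_len)
    order = np.argsort(start_all, kind="stable")

    # batch-precomputed SNP slice bounds and indel proximity per read
    n_all = len(start_all)
    snp_lo = np.zeros(n_all, dtype=np.int64)
    snp_hi = np.zeros(n_all, dtype=np.int64)
    near_indel = np.zeros(n_all, dtype=bool)
    for hap_id, hap in enumerate(haplotypes):
        mask = hap_all == hap_id
        if not mask.any():
            continue
        ss = start_all[mask]
        snp_lo[mask] = np.searchsorted(hap.snp_pos, ss)
        snp_hi[mask] = np.searchsorted(hap.snp_pos, ss + read_len)
        if hap.indels:
            anchors = np.array([e.anchor0 for e in hap.indels], dtype=np.int64)
            ilo = np.searchsorted(anchors, ss - 12)
            ihi = np.searchsorted(anchors, ss + read_len + 12)
            near_indel[mask] = ihi > ilo

    n_err = rng.binomial(read_len, error_rate, size=len(start_all))
    err_pos_pool = rng.integers(0, read_len, size=int(n_err.sum()) + 1)
    err_off_pool = rng.integers(1, 4, size=int(n_err.sum()) + 1)

    qual = _QCHAR * read_len
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        out.write(f"@SQ\tSN:{chrom}\tLN:{L}\n")
        out.write(f"@RG\tID:{sample}\tSM:{sample}\n")
        buf: List[str] = []
        err_cursor = 0
        for rank, i in enumerate(order):
            hap = haplotypes[hap_all[i]]
            s = int(start_all[i])
            kind = int(kind_all[i])
            if kind == 0:
                if not near_indel[i]:
                    cigar = f"{read_len}M"
                    lo, hi = int(snp_lo[i]), int(snp_hi[i])
                    if lo == hi:
                        seq = refseq[s:s + read_len]
                    else:
                        chars = list(refseq[s:s + read_len])
                        for j in range(lo, hi):
                            chars[int(hap.snp_pos[j]) - s] = str(hap.snp_base[j])
                        seq = "".join(chars)
                else:
                    cigar, seq = _build_read(hap, refseq, s, read_len)
            elif kind == 1:
                cigar, seq = _artifact_read(hap, refseq, s, read_len, which="del")
            elif kind == 2:
                cigar, seq = _artifact_read(hap, refseq, s, read_len, which="dup")
            else:
                cigar, seq = f"{read_len}M", refseq[s:s + read_len]
            ne = int(n_err[i])
            if ne:
                seq_l = list(seq)
                for _ in range(ne):
                    p = int(err_pos_pool[err_cursor]) % len(seq_l)
                    off = int(err_off_pool[err_cursor])
                    err_cursor += 1
                    cur = seq_l[p]
                    j = "ACGT".find(cur)
                    if j >= 0:
                        seq_l[p] = "ACGT"[(j + off) % 4]
                seq = "".join(seq_l)
            qname = f"{sample}.{hap_all[i]}.k{kind}.{i // 1}"
            buf.append(
                f"{qname}\t{flag_all[i]}\t{chrom}\t{s + 1}\t{mapq_all[i]}\t"
                f"{cigar}\t=\t{int(mate_all[i]) + 1}\t{int(tlen_all[i])}\t"
                f"{seq}\t{qual[:len(seq)]}\n")
            if len(buf) >= 200_000:
                out.write("".join(buf))
                buf = []
        out.write("".join(buf))
    return stats


def _pair_geometry(s: np.ndarray, frag: np.ndarray, read_len: int,
                   deletions: List[Tuple[int, int]], L: int, rng
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map alt-haplotype fragments into reference coordinates: a fragment
    whose interior straddles a deleted interval gets a stretched template."""
    s = s.copy()
    # fragments starting inside (or whose left read would cross into) a
    # deleted interval cannot exist on this haplotype: resample elsewhere
    for _ in range(4):
        bad = np.zeros(len(s), dtype=bool)
        for (ds, de) in deletions:
            bad |= (s >= ds - read_len) & (s < de)
        if not bad.any():
            break
        s[bad] = rng.integers(0, max(1, L - int(frag.mean()) - read_len),
                              size=int(bad.sum()))
    tlen = frag.copy()
    for (ds, de) in deletions:
        size = de - ds
        straddle = (s + read_len <= ds) & (s + frag > ds)
        tlen[straddle] += size
        # the right read must clear the deleted interval entirely
        r2 = s + tlen - read_len
        crosses = (r2 > ds - read_len) & (r2 < de) & straddle
        tlen[crosses] = de + read_len - s[crosses] + (s[crosses] % 40)
    r2 = s + tlen - read_len
    r2 = np.clip(r2, s, L - read_len)
    tlen = r2 + read_len - s
    return s, r2, tlen


def _build_read(hap: Haplotype, refseq: str, s: int, read_len: int
                ) -> Tuple[str, str]:
    """Sequence/CIGAR of a read starting at ref position ``s`` on ``hap``.

    Fast path: no indel in span -> single-M with SNP substitutions.  Reads
    overlapping a tandem-repeat indel without fully spanning the repeat are
    emitted reference-matching and ungapped (the aligner cannot see the
    missing unit), which is precisely the artifact the refinement corrects.
    """
    indels = hap.indels
    lo = bisect_left(indels, s - 12, key=lambda e: e.anchor0) if indels else 0
    active: List[IndelEdit] = []
    end_guess = s + read_len + 12
    for e in indels[lo:lo + 6]:
        if s <= e.anchor0 < end_guess - 1:
            active.append(e)
    if not active:
        return f"{read_len}M", _snp_chunk(hap, refseq, s, read_len)
    cig: List[str] = []
    parts: List[str] = []
    rpos = s
    remaining = read_len
    for e in active:
        if remaining <= 0:
            break
        if e.kind == "del" and e.repeat is not None:
            rep_start, rep_end = e.repeat
            spans = s < rep_start and s + read_len + len(e.seq) > rep_end + 1
            if not spans:
                # terminates inside the repeat: ungapped, reference-matching
                return f"{read_len}M", _snp_chunk(hap, refseq, s, read_len)
        take = e.anchor0 - rpos + 1
        if take > remaining:
            break
        if take > 0:
            parts.append(_snp_chunk(hap, refseq, rpos, take))
            cig.append(f"{take}M")
            remaining -= take
            rpos += take
        if e.kind == "ins":
            k = min(remaining, len(e.seq))
            if k > 0:
                parts.append(e.seq[:k])
                cig.append(f"{k}I")
                remaining -= k
        else:
            cig.append(f"{len(e.seq)}D")
            rpos += len(e.seq)
    if remaining > 0:
        parts.append(_snp_chunk(hap, refseq, rpos, remaining))
        cig.append(f"{remaining}M")
    cigar = _merge_cigar(cig)
    seq = "".join(parts)
    if len(seq) != read_len:                  # ran off the sequence end
        seq = refseq[s:s + read_len]
        return f"{len(seq)}M", seq
    return cigar, seq


def _snp_chunk(hap: Haplotype, refseq: str, start: int, ln: int) -> str:
    chunk = refseq[start:start + ln]
    pos = hap.snp_pos
    lo = int(np.searchsorted(pos, start))
    hi = int(np.searchsorted(pos, start + ln))
    if lo == hi:
        return chunk
    chars = list(chunk)
    for j in range(lo, hi):
        chars[int(pos[j]) - start] = str(hap.snp_base[j])
    return "".join(chars)


def _merge_cigar(ops: List[str]) -> str:
    merged: List[Tuple[int, str]] = []
    for op in ops:
        ln, ch = int(op[:-1]), op[-1]
        if ln == 0:
            continue
        if merged and merged[-1][1] == ch:
            merged[-1] = (merged[-1][0] + ln, ch)
        else:
            merged.append((ln, ch))
    while merged and merged[-1][1] == "D":
        merged.pop()
    return "".join(f"{ln}{ch}" for ln, ch in merged)


def _artifact_read(hap: Haplotype, refseq: str, s: int, read_len: int,
                   which: str) -> Tuple[str, str]:
    """Mis-mapped non-allelic read: reference sequence plus the divergence
    substitutions of the paralogous copy (and, for collapsed duplications,
    the haplotype's own true SNPs)."""
    chunk = list(refseq[s:s + read_len])
    if which == "dup":
        chunk = list(_snp_chunk(hap, refseq, s, read_len))
        sources = [d for d in hap.duplications if d.start < s + read_len and s < d.end]
        for d in sources:
            lo = int(np.searchsorted(d.div_pos, s))
            hi = int(np.searchsorted(d.div_pos, s + read_len))
            for j in range(lo, hi):
                chunk[int(d.div_pos[j]) - s] = str(d.div_base[j])
    else:
        for (iv, (div_pos, div_base)) in hap.del_div.items():
            if not (iv[0] < s + read_len and s < iv[1]):
                continue
            lo = int(np.searchsorted(div_pos, s))
            hi = int(np.searchsorted(div_pos, s + read_len))
            for j in range(lo, hi):
                chunk[int(div_pos[j]) - s] = str(div_base[j])
    return f"{read_len}M", "".join(chunk)


# ---------------------------------------------------------------------------
# progeny construction

def mosaic(parents: Parents, co_positions: Sequence[int],
           start_parent: str = "A", name: str = "gamete",
           gc_tracts: Sequence[Tuple[int, int]] = ()) -> Haplotype:
    """One recombinant gamete: parental origin switches at each crossover;
    gene-conversion tracts flip origin locally.  ``start_parent`` 'A' means
    the reference-parent allele left of the first crossover."""
    co = np.asarray(sorted(co_positions), dtype=np.int64)
    if len(co) != len(set(co.tolist())):
        raise ValueError("crossover positions must be strictly increasing")
    for (gs, ge) in gc_tracts:
        if any(gs <= c < ge for c in co):
            raise ValueError("gene-conversion tract overlaps a crossover boundary")
    hap = parents.hap_alt
    parity0 = 0 if start_parent == "A" else 1

    def from_B(pos: np.ndarray) -> np.ndarray:
        par = (np.searchsorted(co, pos, side="right") + parity0) % 2 == 1
        for (gs, ge) in gc_tracts:
            in_tract = (pos >= gs) & (pos < ge)
            par = np.where(in_tract, ~par, par)
        return par

    keep = from_B(hap.snp_pos)
    out = Haplotype(name, hap.snp_pos[keep], hap.snp_base[keep])
    ind_pos = np.array([e.anchor0 for e in hap.indels], dtype=np.int64)
    if len(ind_pos):
        ikeep = from_B(ind_pos)
        out.indels = [e for e, k in zip(hap.indels, ikeep) if k]
    for iv in hap.deletions:
        if from_B(np.array([iv[0]]))[0]:
            out.deletions.append(iv)
            if iv in hap.del_div:
                out.del_div[iv] = hap.del_div[iv]
    for d in hap.duplications:
        if from_B(np.array([d.start]))[0]:
            out.duplications.append(d)
    for iv in hap.inversions:
        if from_B(np.array([iv[0]]))[0]:
            out.inversions.append(iv)
    return out


def make_progeny(parents: Parents,
                 co_chromatid1: Sequence[int],
                 co_chromatid2: Sequence[int],
                 gc_tracts: Sequence[Tuple[int, int, int]] = (),
                 seed: int = 0) -> Tuple[List[Haplotype], pd.DataFrame]:
    """A diploid progeny: two recombinant chromatids (each switching parental
    origin at its crossover list) plus gene-conversion tracts given as
    (chromatid index, start, end).  Returns (chromatids, truth blocks)."""
    gc1 = [(s, e) for (c, s, e) in gc_tracts if c == 0]
    gc2 = [(s, e) for (c, s, e) in gc_tracts if c == 1]
    c1 = mosaic(parents, co_chromatid1, "A", "chromatid1", gc1)
    c2 = mosaic(parents, co_chromatid2, "A", "chromatid2", gc2)
    c1.weight = c2.weight = 0.5
    bounds = sorted(set([0, parents.length] + list(co_chromatid1) + list(co_chromatid2)))
    rows = []
    for a, b in zip(bounds, bounds[1:]):
        par1 = (np.searchsorted(np.asarray(co_chromatid1), a, side="right")) % 2
        par2 = (np.searchsorted(np.asarray(co_chromatid2), a, side="right")) % 2
        n_b = par1 + par2
        genotype = {0: "A-hom", 1: "het", 2: "B-hom"}[n_b]
        rows.append((parents.chrom, a, b, genotype))
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "genotype"])
    return [c1, c2], truth


# ---------------------------------------------------------------------------
# pooled F2 population

@dataclass
class PoolTruth:
    causal_pos: int              # 1-based
    causal_ref: str
    causal_alt: str
    n_progeny: int
    marker_pos: np.ndarray       # 1-based
    mutant_freq: np.ndarray      # pooled mutant-parent allele frequency/marker


def make_f2_pool(parents: Parents, n_progeny: int,
                 causal: Tuple[int, str, str],
                 pooled_depth: float, mean_co: float = 1.0,
                 seed: int = 0, error_rate: float = DEFAULT_ERROR_RATE,
                 mutant_parent: str = "A"
                 ) -> Tuple[List, List, PoolTruth]:
    """Recessive-screen pooled F2: only progenies homozygous for the causal
    allele (fixed on the mutant parent) enter the pool.

    Returns (marker observations, novel-variant pool calls, truth).  The
    observation counts are drawn per marker as Poisson(depth) reads split by
    the exact pooled allele frequency — statistically equivalent to uniform
    read sampling over the pooled genomes, at any genome size.
    """
    from .core import Genotype, VariantCall, VariantClass
    from .recomb import Marker, MarkerObservation

    rng = np.random.default_rng(seed)
    causal_pos1, causal_ref, causal_alt = causal
    causal0 = causal_pos1 - 1
    snp_pos0 = parents.hap_alt.snp_pos
    marker_pos1 = snp_pos0 + 1
    n_markers = len(snp_pos0)
    L = parents.length

    # gamete construction: crossovers Poisson per meiosis, uniform positions;
    # condition each gamete on carrying the mutant parent at the causal locus
    carrier_is_A = mutant_parent == "A"
    from_mutant = np.zeros(n_markers, dtype=np.int64)
    for _ in range(2 * n_progeny):
        n_co = rng.poisson(mean_co)
        co = np.sort(rng.integers(0, L, size=n_co))
        parity0 = int(rng.integers(0, 2))
        par_at_causal = (np.searchsorted(co, causal0, side="right") + parity0) % 2
        want = 0 if carrier_is_A else 1          # 0 -> parent A origin
        if par_at_causal != want:
            parity0 ^= 1                          # relabel: same meiosis, sister gamete
        par = (np.searchsorted(co, snp_pos0, side="right") + parity0) % 2
        from_mutant += (par == want)
    mutant_freq = from_mutant / (2.0 * n_progeny)

    depth = rng.poisson(pooled_depth, size=n_markers)
    # mutant parent A carries the reference allele at every marker
    alt_is_mutant = not carrier_is_A
    p_alt = mutant_freq if alt_is_mutant else 1.0 - mutant_freq
    p_alt = p_alt * (1 - error_rate) + (1 - p_alt) * error_rate
    alt_n = rng.binomial(depth, p_alt)
    ref_n = depth - alt_n

    observations = []
    for i in range(n_markers):
        marker = Marker(parents.chrom, int(marker_pos1[i]),
                        str(parents.ref_seq[snp_pos0[i]]),
                        str(parents.hap_alt.snp_base[i]),
                        paternal=str(parents.ref_seq[snp_pos0[i]]),
                        maternal=str(parents.hap_alt.snp_base[i]))
        observations.append(MarkerObservation(marker, int(ref_n[i]), int(alt_n[i])))

    # novel variants seen by the pool: the causal mutation (homozygous in
    # every selected progeny) plus EMS-background decoys segregating at ~50%
    novel: List[VariantCall] = []
    cdp = max(1, int(rng.poisson(pooled_depth)))
    c_alt = int(rng.binomial(cdp, 1.0 - error_rate))
    novel.append(VariantCall(
        chrom=parents.chrom, pos=causal_pos1, ref=causal_ref, alt=causal_alt,
        variant_class=VariantClass.SNP, depth=cdp, ref_support=cdp - c_alt,
        alt_support=c_alt, genotype=Genotype.ALT_HOM if c_alt > 0.9 * cdp else Genotype.HET,
        quality=60.0, provenance="pool"))
    decoy_specs = [
        (0.25, "G", "A", 0.5),   # unselected EMS background: ratio ~0.5
        (0.55, "A", "C", 0.95),  # non-transition near-fixed variant
        (0.75, "C", "T", 0.5),   # transition but unlinked het
        (0.31, "G", "A", 0.93),  # high-ratio transition shared with a parent
    ]
    for frac, ref, alt, p in decoy_specs:
        pos = int(frac * L)
        dp = max(1, int(rng.poisson(pooled_depth)))
        a = int(rng.binomial(dp, p))
        gt = Genotype.ALT_HOM if a > 0.9 * dp else Genotype.HET
        novel.append(VariantCall(
            chrom=parents.chrom, pos=pos, ref=ref, alt=alt,
            variant_class=VariantClass.SNP, depth=dp, ref_support=dp - a,
            alt_support=a, genotype=gt, quality=60.0, provenance="pool"))

    truth = PoolTruth(causal_pos1, causal_ref, causal_alt, n_progeny,
                      marker_pos1, mutant_freq)
    return observations, novel, truth
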