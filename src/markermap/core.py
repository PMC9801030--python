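"""Domain types shared by every pipeline stage.

Coordinate conventions
----------------------
Intervals (structural variants, tandem repeats, windows, blocks) are stored
0-based half-open.  Single-locus anchors (:class:`VariantCall.pos`) are
1-based, matching VCF.  Conversions happen only at format boundaries
(VCF/GFF3/TRF .dat are 1-based; BED is 0-based half-open).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pyfaidx


class VariantClass(str, enum.Enum):
    SNP = "SNP"
    INSERTION = "insertion"
    DELETION = "deletion"


class Genotype(str, enum.Enum):
    REF_HOM = "ref-hom"
    HET = "het"
    ALT_HOM = "alt-hom"
    MISSING = "missing"


class FilterReason(str, enum.Enum):
    """Reasons a candidate variant is removed from the marker set.

    Written verbatim to the VCF FILTER column; an empty reason set means PASS.
    """

    MQ_LOW = "MQ_LOW"
    SV_OVERLAP = "SV_OVERLAP"
    SV_ADJACENT = "SV_ADJACENT"
    TANDEM_NONSPAN = "TANDEM_NONSPAN"
    DEPTH_EXTREME = "DEPTH_EXTREME"
    ALLELE_RATIO = "ALLELE_RATIO"
    LOW_SUPPORT = "LOW_SUPPORT"


class SVClass(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"
    INSERTION = "insertion"
    TRANSPOSITION = "transposition"
    INVERSION = "inversion"
    COMPLEX = "complex"


class GenomeIndex:
    """Random access to a reference genome with clipped interval queries."""

    def __init__(self, names: Sequence[str], lengths: Sequence[int],
                 fasta: Optional[pyfaidx.Fasta] = None) -> None:
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in size")
        for name, length in zip(names, lengths):
            if length <= 0:
                raise ValueError(f"non-positive length for sequence {name!r}")
        self.names = list(names)
        self.lengths = dict(zip(names, (int(x) for x in lengths)))
        self._fasta = fasta

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        names = list(fasta.keys())
        lengths = [len(fasta[name]) for name in names]
        return cls(names, lengths, fasta)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def fetch(self, name: str, start: int, end: int) -> str:
        """Sequence of ``name[start:end)`` (0-based), clipped to the sequence."""
        if name not in self.lengths:
            raise KeyError(f"unknown sequence {name!r}")
        length = self.lengths[name]
        start = max(0, min(int(start), length))
        end = max(start, min(int(end), length))
        if self._fasta is None:
            raise ValueError("GenomeIndex built without sequence data")
        return str(self._fasta[name][start:end])


@dataclass
class AlignedRead:
    """One aligned segment, decoupled from the pysam record that produced it."""

    query_name: str
    reference_name: str
    start: int                       # 0-based leftmost aligned position
    end: int                         # past-the-end aligned reference position
    blocks: tuple                    # CIGAR-derived (start, end) aligned blocks
    mapping_quality: int
    is_reverse: bool
    mate_reference_name: Optional[str]
    mate_start: Optional[int]
    mate_is_reverse: Optional[bool]
    template_length: int
    is_paired: bool
    is_proper_pair: bool
    sequence: Optional[str] = None
    qualities: Optional[np.ndarray] = None
    cigartuples: Optional[tuple] = None
    # set by variant_calling.filter_reads
    spans_repeats: tuple = ()        # indices of repeats fully spanned
    nonspan_repeats: tuple = ()      # indices of repeats an alignment end sits in

    def __post_init__(self) -> None:
        if not 0 <= self.mapping_quality <= 60:
            raise ValueError(
                f"mapping quality {self.mapping_quality} outside [0, 60] "
                f"for read {self.query_name!r}")
        prev_end = -1
        for bstart, bend in self.blocks:
            if bstart < prev_end:
                raise ValueError(
                    f"aligned blocks overlap or are unsorted for read {self.query_name!r}")
            prev_end = bend

    @classmethod
    def from_pysam(cls, rec) -> "AlignedRead":
        quals = rec.query_qualities
        return cls(
            query_name=rec.query_name,
            reference_name=rec.reference_name,
            start=rec.reference_start,
            end=rec.reference_end if rec.reference_end is not None else rec.reference_start,
            blocks=tuple(rec.get_blocks()),
            mapping_quality=min(rec.mapping_quality, 60),
            is_reverse=rec.is_reverse,
            mate_reference_name=rec.next_reference_name if rec.is_paired else None,
            mate_start=rec.next_reference_start if rec.is_paired else None,
            mate_is_reverse=rec.mate_is_reverse if rec.is_paired else None,
            template_length=rec.template_length,
            is_paired=rec.is_paired,
            is_proper_pair=rec.is_proper_pair,
            sequence=rec.query_sequence,
            qualities=None if quals is None else np.asarray(quals, dtype=np.int16),
            cigartuples=tuple(rec.cigartuples) if rec.cigartuples else None,
        )

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and self.end > start


@dataclass
class VariantCall:
    """One candidate or refined SNP/indel.

    ``pos`` is the 1-based anchor base, VCF-style: for indels the base before
    the inserted/deleted sequence, with ``ref``/``alt`` carrying the anchor.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    depth: int
    ref_support: int
    alt_support: int
    genotype: Genotype
    quality: float
    filter_reasons: set = field(default_factory=set)
    sample: Optional[str] = None
    provenance: str = "called"
    refinable: bool = True
    # per-allele (spanning, non-spanning) support inside a tandem repeat,
    # keyed "ref"/"alt"; populated only for indels overlapping active repeats
    tandem_evidence: Optional[dict] = None
    # free-form context per filter reason (e.g. the SV class that triggered it)
    filter_detail: dict = field(default_factory=dict)
    # +N/-N when an indel is re-typed as gain/loss of N tandem units
    tandem_units: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_support + self.alt_support > self.depth:
            raise ValueError(
                f"allele support exceeds depth at {self.chrom}:{self.pos}")
        if self.variant_class is not VariantClass.SNP:
            if not 1 <= self.indel_length <= 10:
                raise ValueError(
                    f"small indel at {self.chrom}:{self.pos} has length "
                    f"{self.indel_length}, outside 1-10 bp")

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def primary_support(self) -> int:
        """Reads carrying the variant (primary) allele."""
        return self.alt_support

    @property
    def alternative_support(self) -> int:
        return self.ref_support

    @property
    def allele_ratio(self) -> float:
        """Primary-allele fraction among reads carrying either allele."""
        total = self.ref_support + self.alt_support
        return self.alt_support / total if total else float("nan")

    # alias used by the causal-mapping filters
    alt_fraction = allele_ratio

    @property
    def is_pass(self) -> bool:
        return not self.filter_reasons

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class StructuralVariant:
    """An SV interval (0-based half-open) with its supporting evidence."""

    sv_class: SVClass
    chrom: str
    start: int
    end: int
    pair_support: int = 0
    depth_ratio: float = float("nan")
    split_support: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"SV {self.chrom}:{self.start}-{self.end} has start > end")
        if self.pair_support < 0 or self.split_support < 0:
            raise ValueError("negative SV support count")

    def overlaps_pos(self, pos0: int, margin: int = 0) -> bool:
        return self.start - margin <= pos0 < self.end + margin


@dataclass
class TandemRepeatRegion:
    """A tandem repeat (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    score: int

    def __post_init__(self) -> None:
        if self.unit_length < 1:
            raise ValueError("tandem repeat unit length must be >= 1")
        if self.end - self.start < self.unit_length:
            raise ValueError(
                f"repeat {self.chrom}:{self.start}-{self.end} shorter than its unit")

    @property
    def filter_active(self) -> bool:
        """Repeats the read/indel filters act on: score >= 10, unit <= 20 bp."""
        return self.score >= 10 and self.unit_length <= 20

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def spanned_by(self, read_start: int, read_end: int) -> bool:
        return read_start < self.start and read_end > self.end


def sort_calls(calls: list) -> list:
    return sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))


def coverage_array(intervals: Iterator, length: int) -> np.ndarray:
    """Per-base coverage from (start, end) half-open intervals via diff/cumsum."""
    delta = np.zeros(length + 1, dtype=np.int64)
    for start, end in intervals:
        start = max(0, min(start, length))
        end = max(0, min(end, length))
        if end > start:
            delta[start] += 1
            delta[end] -= 1
    return np.cumsum(delta[:-1])
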