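"""Readers and writers for the standard formats the pipeline touches.

SAM/BAM via pysam, FASTA via pyfaidx (see :class:`markermap.core.GenomeIndex`),
Tandem Repeats Finder ``.dat`` or BED for repeats, BED for SVs, and VCF 4.2
for variants.  VCF FILTER carries the refinement reason codes; FORMAT is
``GT:AD:DP`` per sample.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterator, List, Optional, Sequence, Tuple

import pysam

from .core import (AlignedRead, FilterReason, Genotype, StructuralVariant,
                   SVClass, TandemRepeatRegion, VariantCall, VariantClass,
                   sort_calls)


# ---------------------------------------------------------------------------
# alignments

def open_alignment(path: str) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path))


def read_alignments(path: str, region: Optional[Tuple[str, int, int]] = None
                    ) -> Iterator[AlignedRead]:
    """Stream mapped reads, optionally restricted to ``(chrom, start, end)``.

    The file must be coordinate-sorted.  BAM with an index uses random
    access; plain SAM is streamed and filtered, stopping once past the
    region (valid because of the sort order).
    """
    af = pysam.AlignmentFile(str(path))
    try:
        if region is None:
            for rec in af:
                if not rec.is_unmapped:
                    yield AlignedRead.from_pysam(rec)
            return
        chrom, start, end = region
        if chrom not in af.references:
            raise ValueError(f"unknown sequence name {chrom!r} in {path}")
        if af.is_bam and af.has_index():
            for rec in af.fetch(chrom, start, end):
                if not rec.is_unmapped:
                    yield AlignedRead.from_pysam(rec)
            return
        tid = af.get_tid(chrom)
        for rec in af:
            if rec.is_unmapped:
                continue
            if rec.reference_id < tid:
                continue
            if rec.reference_id > tid or rec.reference_start >= end:
                break
            if (rec.reference_end or rec.reference_start) > start:
                yield AlignedRead.from_pysam(rec)
    finally:
        af.close()


# ---------------------------------------------------------------------------
# tandem repeats

_TRF_DATA_RE = re.compile(r"^\d+ \d+ \d+ ")


def read_trf_dat(path: str) -> List[TandemRepeatRegion]:
    """Parse Tandem Repeats Finder ``.dat`` output or a 4+-column BED.

    All records are retained; :attr:`TandemRepeatRegion.filter_active`
    (score >= 10, unit length <= 20) marks the ones the filters act on.
    """
    regions: List[TandemRepeatRegion] = []
    with open(path) as handle:
        first = handle.read(4096)
        handle.seek(0)
        is_bed = bool(first) and "\t" in first.splitlines()[0] if first.strip() else False
        if is_bed:
            for lineno, line in enumerate(handle, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                try:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    unit = int(fields[3])
                    copies = float(fields[4]) if len(fields) > 4 else (end - start) / unit
                    score = int(fields[5]) if len(fields) > 5 else 2 * (end - start)
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable BED repeat line") from exc
                regions.append(TandemRepeatRegion(chrom, start, end, unit, copies, score))
        else:
            chrom = None
            for lineno, line in enumerate(handle, 1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("Sequence:"):
                    chrom = line.split(None, 1)[1].split()[0]
                    continue
                if line.startswith("@"):        # ngs-dialect sequence header
                    chrom = line[1:].split()[0]
                    continue
                if not _TRF_DATA_RE.match(line):
                    continue                    # banner / parameter lines
                fields = line.split()
                if chrom is None:
                    raise ValueError(f"{path}:{lineno}: repeat record before any Sequence header")
                try:
                    start1, end1 = int(fields[0]), int(fields[1])
                    unit = int(fields[2])
                    copies = float(fields[3])
                    score = int(fields[7])
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}:{lineno}: unparseable TRF record") from exc
                regions.append(
                    TandemRepeatRegion(chrom, start1 - 1, end1, unit, copies, score))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def write_repeats_bed(regions: Sequence[TandemRepeatRegion], path: str) -> None:
    with open(path, "w") as out:
        for r in regions:
            out.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.unit_length}\t"
                      f"{r.copy_number:g}\t{r.score}\n")


# ---------------------------------------------------------------------------
# structural variants (BED)

def write_sv_bed(svs: Sequence[StructuralVariant], path: str) -> None:
    with open(path, "w") as out:
        for sv in svs:
            out.write(f"{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_class.value}\t"
                      f"{sv.pair_support}\t{sv.depth_ratio:g}\t{sv.split_support}\n")


def read_sv_bed(path: str) -> List[StructuralVariant]:
    svs: List[StructuralVariant] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                sv = StructuralVariant(
                    sv_class=SVClass(fields[3]),
                    chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                    pair_support=int(fields[4]) if len(fields) > 4 else 0,
                    depth_ratio=float(fields[5]) if len(fields) > 5 else float("nan"),
                    split_support=int(fields[6]) if len(fields) > 6 else 0)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable SV BED line") from exc
            svs.append(sv)
    return svs


# ---------------------------------------------------------------------------
# VCF

_GT_CODE = {Genotype.REF_HOM: "0/0", Genotype.HET: "0/1",
            Genotype.ALT_HOM: "1/1", Genotype.MISSING: "./."}
_CODE_GT = {v: k for k, v in _GT_CODE.items()}
_CODE_GT.update({"0|0": Genotype.REF_HOM, "0|1": Genotype.HET,
                 "1|0": Genotype.HET, "1|1": Genotype.ALT_HOM,
                 ".": Genotype.MISSING})


def _vcf_header(samples: Sequence[str], contigs=None) -> str:
    lines = ["##fileformat=VCFv4.2",
             "##source=markermap",
             '##FILTER=<ID=PASS,Description="All filters passed">']
    for reason in FilterReason:
        lines.append(f'##FILTER=<ID={reason.value},Description="Refinement filter {reason.value}">')
    lines += [
        '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=PROV,Number=1,Type=String,Description="Provenance (called/imported)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    if contigs:
        for name, length in contigs:
            lines.append(f"##contig=<ID={name},length={length}>")
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    for sample in samples:
        header += f"\t{sample}"
    lines.append(header)
    return "\n".join(lines) + "\n"


def write_vcf(calls: Sequence[VariantCall], samples: Sequence[str], path: str,
              contigs=None) -> None:
    """Write single-sample-per-record calls as VCF 4.2.

    ``calls`` must be sorted by (chrom, pos); multi-sample output goes
    through :func:`write_multisample_vcf`.
    """
    if len(samples) != 1:
        raise ValueError("write_vcf emits one-sample VCFs; use write_multisample_vcf")
    ordered = sort_calls(list(calls))
    if [c.key() for c in ordered] != [c.key() for c in calls]:
        raise ValueError("calls must be sorted by (chrom, pos) before writing")
    with open(path, "w") as out:
        out.write(_vcf_header(samples, contigs))
        for call in calls:
            filt = ";".join(sorted(r.value for r in call.filter_reasons)) or "PASS"
            info = f"VC={call.variant_class.value};PROV={call.provenance}"
            gt = _GT_CODE[call.genotype]
            out.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t"
                f"{call.quality:g}\t{filt}\t{info}\t"
                f"GT:AD:DP\t{gt}:{call.ref_support},{call.alt_support}:{call.depth}\n")


def write_multisample_vcf(records: Sequence[dict], samples: Sequence[str],
                          path: str, contigs=None) -> None:
    """Write merged records: each a dict with keys chrom,pos,ref,alt,
    variant_class,quality,filter_reasons and per-sample (genotype, ad, dp)."""
    with open(path, "w") as out:
        out.write(_vcf_header(samples, contigs))
        for rec in records:
            filt = ";".join(sorted(r.value for r in rec.get("filter_reasons", set()))) or "PASS"
            info = f"VC={rec['variant_class'].value}"
            cols = [rec["chrom"], str(rec["pos"]), ".", rec["ref"], rec["alt"],
                    f"{rec.get('quality', 0.0):g}", filt, info, "GT:AD:DP"]
            for sample in samples:
                gt, ad, dp = rec["samples"][sample]
                cols.append(f"{_GT_CODE[gt]}:{ad[0]},{ad[1]}:{dp}")
            out.write("\t".join(cols) + "\n")


def read_vcf(path: str, sample: Optional[str] = None) -> List[VariantCall]:
    """Read a VCF written by this package (or any GT:AD:DP VCF) back into calls."""
    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        use = sample or (sample_names[0] if sample_names else None)
        for rec in vcf:
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                if alt.startswith("<"):
                    warnings.warn(
                        f"skipping symbolic allele {alt} at {rec.chrom}:{rec.pos}",
                        stacklevel=2)
                    continue
                reasons = {FilterReason(f) for f in rec.filter.keys() if f != "PASS"}
                vclass = _infer_class(rec.ref, alt, _info_get(rec, "VC"))
                depth = 0
                ref_sup = alt_sup = 0
                genotype = Genotype.MISSING
                if use is not None:
                    fmt = rec.samples[use]
                    depth = fmt.get("DP") or 0
                    ad = fmt.get("AD")
                    if ad is not None and len(ad) > alt_idx and ad[0] is not None:
                        ref_sup = int(ad[0] or 0)
                        alt_sup = int(ad[alt_idx] or 0)
                    gt = fmt.get("GT")
                    genotype = _genotype_from_tuple(gt, alt_idx)
                depth = max(depth, ref_sup + alt_sup)
                calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    variant_class=vclass, depth=depth, ref_support=ref_sup,
                    alt_support=alt_sup, genotype=genotype,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    filter_reasons=reasons, sample=use,
                    provenance=str(_info_get(rec, "PROV") or "imported")))
    return calls


def _info_get(rec, key):
    """INFO lookup tolerant of keys absent from third-party headers."""
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _infer_class(ref: str, alt: str, declared: Optional[str]) -> VariantClass:
    if declared:
        return VariantClass(declared)
    if len(ref) == len(alt) == 1:
        return VariantClass.SNP
    return VariantClass.INSERTION if len(alt) > len(ref) else VariantClass.DELETION


def _genotype_from_tuple(gt, alt_idx: int) -> Genotype:
    if gt is None or all(a is None for a in gt):
        return Genotype.MISSING
    alleles = [a for a in gt if a is not None]
    n_alt = sum(1 for a in alleles if a == alt_idx)
    if n_alt == 0:
        return Genotype.REF_HOM
    if n_alt == len(alleles):
        return Genotype.ALT_HOM
    return Genotype.HET
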