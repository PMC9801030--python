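"""Single entry point wiring the stages: call -> sv -> refine -> merge ->
recomb | bsa, with per-stage provenance and a machine-readable run summary."""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from . import bsa as bsa_mod
from . import io as mio
from . import recomb as recomb_mod
from . import refine as refine_mod
from . import sv as sv_mod
from .calling import call_sample, import_vcf
from .core import GenomeIndex

log = logging.getLogger(__name__)

STAGE_ORDER = ["call", "sv", "refine", "merge", "recomb", "bsa"]


class DependencyError(RuntimeError):
    """A stage is missing an upstream output."""

    def __init__(self, stage: str, missing: str) -> None:
        super().__init__(f"stage {stage!r} requires {missing}")
        self.stage = stage


def load_config(path: str) -> dict:
    with open(path, "rb") as handle:
        return tomllib.load(handle)


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: Optional[str] = None) -> dict:
    """Execute the configured stages in dependency order; returns the run
    summary (also written to ``summary.json`` in the run directory)."""
    run_cfg = config.get("run", {})
    outdir = Path(outdir or run_cfg.get("outdir", "markermap_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", STAGE_ORDER[:4])
    stages = sorted(set(stages), key=STAGE_ORDER.index)
    inputs = config.get("inputs", {})
    params = config.get("params", {})
    seed = run_cfg.get("seed", 0)

    summary: dict = {
        "tool": "markermap", "version": __version__,
        "config_hash": config_hash(config), "seed": seed, "stages": {},
    }
    state: dict = {}
    genome = GenomeIndex.from_fasta(inputs["ref"]) if "ref" in inputs else None
    repeats = mio.read_trf_dat(inputs["repeats"]) if inputs.get("repeats") else []
    samples = inputs.get("samples", [])

    for stage in stages:
        if stage == "call":
            _require(stage, genome is not None, "inputs.ref")
            _require(stage, bool(samples) or inputs.get("vcf"),
                     "inputs.samples or inputs.vcf")
            stage_sum = {}
            for s in samples:
                calls, mean_depth = call_sample(
                    s["bam"], genome, repeats,
                    min_mapq=params.get("min_mapq", 20),
                    het_prior=params.get("het_prior", 1e-3))
                state.setdefault("candidates", {})[s["name"]] = calls
                state.setdefault("mean_depth", {})[s["name"]] = mean_depth
                path = outdir / f"candidates_{s['name']}.vcf"
                mio.write_vcf(calls, [s["name"]], str(path),
                              contigs=[(c, genome.lengths[c]) for c in genome.names])
                stage_sum[s["name"]] = {"candidates": len(calls),
                                        "mean_depth": round(mean_depth, 3)}
            if inputs.get("vcf"):
                calls = import_vcf(inputs["vcf"])
                state.setdefault("candidates", {})["imported"] = calls
                stage_sum["imported"] = {"candidates": len(calls)}
            summary["stages"]["call"] = stage_sum
        elif stage == "sv":
            _require(stage, genome is not None, "inputs.ref")
            _require(stage, bool(samples), "inputs.samples")
            stage_sum = {}
            for s in samples:
                svs = sv_mod.detect_svs(
                    s["bam"], genome,
                    min_support=params.get("sv_min_support", 3))
                state.setdefault("svs", {})[s["name"]] = svs
                mio.write_sv_bed(svs, str(outdir / f"sv_{s['name']}.bed"))
                stage_sum[s["name"]] = {"svs": len(svs)}
            summary["stages"]["sv"] = stage_sum
        elif stage == "refine":
            _require(stage, "candidates" in state, "stage 'call' output")
            config_obj = refine_mod.RefinementConfig(
                sv_margin=params.get("sv_margin", 500),
                depth_fold=params.get("depth_fold", 4.0),
                depth_tails=params.get("depth_tails", 0.01),
                ratio_percentile=params.get("ratio_percentile", 0.99),
                min_support=params.get("min_support", 3))
            stage_sum = {}
            for name, calls in state["candidates"].items():
                svs = state.get("svs", {}).get(name, [])
                mean_depth = state.get("mean_depth", {}).get(name, 0.0)
                refine_mod.refine_candidates(calls, svs, repeats, mean_depth,
                                             config_obj)
                state.setdefault("refined", {})[name] = calls
                if genome is not None:
                    from .core import sort_calls
                    mio.write_vcf(sort_calls(calls), [name],
                                  str(outdir / f"refined_{name}.vcf"),
                                  contigs=[(c, genome.lengths[c]) for c in genome.names])
                stage_sum[name] = refine_mod.filter_summary(calls)
            summary["stages"]["refine"] = stage_sum
        elif stage == "merge":
            _require(stage, len(state.get("refined", {})) >= 2,
                     "refined calls for >= 2 samples")
            records = refine_mod.merge_samples(state["refined"])
            state["merged"] = records
            names = list(state["refined"])
            mio.write_multisample_vcf(records, names, str(outdir / "merged.vcf"))
            summary["stages"]["merge"] = {"loci": len(records)}
        elif stage == "recomb":
            markers = _markers(state, inputs, stage)
            _require(stage, inputs.get("progeny_bam"), "inputs.progeny_bam")
            obs = recomb_mod.genotype_markers(inputs["progeny_bam"], markers,
                                              min_mapq=params.get("min_mapq", 20))
            window = params.get("window", recomb_mod.WINDOW_DEFAULT)
            step = params.get("step", window // 2)
            lengths = genome.lengths if genome else None
            windows = recomb_mod.call_windows(obs, window, step, lengths)
            blocks, cos = recomb_mod.merge_blocks(windows, obs)
            gcs = recomb_mod.detect_gc(obs, blocks, window)
            _write_recomb(outdir, blocks, cos, gcs)
            summary["stages"]["recomb"] = {
                "blocks": len(blocks), "crossovers": len(cos),
                "gene_conversions": len(gcs)}
        elif stage == "bsa":
            markers = _markers(state, inputs, stage)
            _require(stage, inputs.get("pool_bam"), "inputs.pool_bam")
            obs = recomb_mod.genotype_markers(inputs["pool_bam"], markers,
                                              min_mapq=params.get("min_mapq", 20))
            lengths = genome.lengths if genome else None
            tracks = bsa_mod.build_ratio_track(obs, chrom_lengths=lengths)
            regions = []
            for track in tracks:
                regions.extend(bsa_mod.find_candidate_regions(
                    track, mutant_parent=params.get("mutant_parent", "paternal")))
            with open(outdir / "candidate_regions.bed", "w") as out:
                for reg in regions:
                    out.write(f"{reg.chrom}\t{reg.start}\t{reg.end}\t"
                              f"{reg.kind.value}\t{reg.extreme_value:.4f}\n")
            summary["stages"]["bsa"] = {"regions": len(regions)}
        else:
            raise ValueError(f"unknown stage {stage!r}")

    with open(outdir / "summary.json", "w") as out:
        json.dump(summary, out, indent=2)
    return summary


def _markers(state: dict, inputs: dict, stage: str) -> List:
    if "merged" in state:
        calls = []
        for rec in state["merged"]:
            from .core import Genotype, VariantCall
            calls.append(VariantCall(
                chrom=rec["chrom"], pos=rec["pos"], ref=rec["ref"],
                alt=rec["alt"], variant_class=rec["variant_class"],
                depth=0, ref_support=0, alt_support=0,
                genotype=Genotype.MISSING, quality=rec.get("quality", 0.0),
                filter_reasons=set(rec.get("filter_reasons", set()))))
        return recomb_mod.markers_from_calls(calls)
    if inputs.get("markers"):
        return recomb_mod.markers_from_calls(mio.read_vcf(inputs["markers"]))
    raise DependencyError(stage, "markers (merged VCF or inputs.markers)")


def _write_recomb(outdir: Path, blocks, cos, gcs) -> None:
    with open(outdir / "blocks.tsv", "w") as out:
        out.write("chrom\tstart\tend\tgenotype\n")
        for b in blocks:
            out.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.genotype.value}\n")
    with open(outdir / "crossovers.tsv", "w") as out:
        out.write("chrom\tleft\tright\tleft_genotype\tright_genotype\tlow_resolution\n")
        for c in cos:
            out.write(f"{c.chrom}\t{c.left}\t{c.right}\t{c.left_genotype.value}\t"
                      f"{c.right_genotype.value}\t{int(c.low_resolution)}\n")
    with open(outdir / "gene_conversions.tsv", "w") as out:
        out.write("chrom\tmembers\tspan\tbackground\tconverted_to\n")
        for g in gcs:
            members = ",".join(str(p) for p in g.positions)
            out.write(f"{g.chrom}\t{members}\t{g.span}\t{g.background.value}\t"
                      f"{g.converted_to.value}\n")


def _require(stage: str, condition, missing: str) -> None:
    if not condition:
        raise DependencyError(stage, missing)
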