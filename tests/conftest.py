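"""Shared fixtures: tiny hand-written SAM/FASTA builders and a small
simulated artifact scenario reused across module tests."""

from __future__ import annotations

import random
from pathlib import Path

import pytest

from markermap import simulate as sim
from markermap.core import GenomeIndex


def write_sam(path, reads, contigs=(("chr1", 10_000),)):
    """Write a minimal coordinate-sorted SAM.  Each read is a dict with keys
    qname, flag, pos (0-based), mapq, cigar, seq; optional mate_pos, tlen,
    rnext, qual."""
    with open(path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contigs:
            out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in sorted(reads, key=lambda r: (r.get("rname", "chr1"), r["pos"])):
            seq = r["seq"]
            qual = r.get("qual", "I" * len(seq))
            out.write(
                f"{r['qname']}\t{r.get('flag', 0)}\t{r.get('rname', 'chr1')}\t"
                f"{r['pos'] + 1}\t{r.get('mapq', 60)}\t{r['cigar']}\t"
                f"{r.get('rnext', '*' if 'mate_pos' not in r else '=')}\t"
                f"{r.get('mate_pos', -1) + 1}\t{r.get('tlen', 0)}\t{seq}\t{qual}\n")
    return str(path)


def write_fasta(path, seqs):
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i:i + 70] + "\n")
    return str(path)


def random_seq(n, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture
def sam_builder(tmp_path):
    def build(reads, name="reads.sam", contigs=(("chr1", 10_000),)):
        return write_sam(tmp_path / name, reads, contigs)
    return build


@pytest.fixture
def fasta_builder(tmp_path):
    def build(seqs, name="ref.fa"):
        return write_fasta(tmp_path / name, seqs)
    return build


@pytest.fixture(scope="session")
def artifact_scenario(tmp_path_factory):
    """200 kb genome with one deletion (paralog mis-mapping), one collapsed
    duplication, and an (AG)10 -> (AG)9 tandem repeat, sequenced at 20x."""
    outdir = tmp_path_factory.mktemp("artifact200k")
    parents = sim.make_parents(
        200_000, 1 / 200, 1 / 2000,
        sv_specs=[sim.SvSpec("deletion", 50_000, 1_500),
                  sim.SvSpec("duplication", 120_000, 2_000)],
        repeat_specs=[sim.RepeatSpec(80_000, "AG", 10, alt_copies=9)],
        seed=11)
    ref = outdir / "ref.fa"
    sam = outdir / "reads.sam"
    parents.write_fasta(str(ref))
    sim.write_alignments(parents, [parents.hap_alt], depth=20, seed=12,
                         path=str(sam))
    return {
        "parents": parents,
        "ref": str(ref),
        "sam": str(sam),
        "genome": GenomeIndex.from_fasta(str(ref)),
    }
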