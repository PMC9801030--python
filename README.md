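# markermap

High-confidence molecular markers from short-read alignments, and what you
can do with them.

`markermap` implements a three-stage toolkit for polymorphism-driven
genetics:

1. **Call & filter.** Candidate SNPs and small indels (1–10 bp) are called
   from pileups with a diallelic genotype-likelihood model (or imported from
   a third-party VCF). Structural variants are detected from discordant
   read-pair distance/orientation, window depth, and split reads. The
   refinement stage then removes *artificial* variants — calls created by
   mis-mapped non-allelic reads in and around SVs, collapsed CNVs, and
   reads that fail to span tandem repeats — and annotates every removed
   candidate with a machine-readable reason code in the VCF FILTER column
   (`SV_OVERLAP`, `SV_ADJACENT`, `TANDEM_NONSPAN`, `DEPTH_EXTREME`,
   `ALLELE_RATIO`, `LOW_SUPPORT`).
2. **Meiotic recombination.** Progeny reads are genotyped against the
   refined parental markers; sliding-window allelic ratios (default
   20 kb / 10 kb, thresholds 0.8 / 0.2) give genotype blocks, crossovers at
   block switches (boundaries refined to the flanking informative markers),
   and gene conversions at markers contradicting their block (< 1 kb
   grouping).
3. **Causal-mutation mapping.** Pooled phenotype-selected F2 reads give a
   200 kb / 100 kb allelic-ratio track, smoothed on a 2 Mb / 500 kb grid;
   derivative extrema mark candidate regions, EMS candidates pass the
   ratio ≥ 0.75 / not-parental / G→A-or-C→T rules, T-DNA screens scan for
   novel insertions, and survivors are annotated against GFF3 gene models
   (splice site / CDS with synonymous vs non-synonymous / UTR / intron /
   intergenic).

A fully seeded simulator (`markermap.simulate`) generates parental genomes,
artifact-bearing alignments (paralog mis-mapping inside deletions, collapsed
duplications, reads terminating inside tandem repeats), recombinant
progenies, and pooled F2 populations with complete ground truth, so the
whole pipeline is testable without external data.

## Command line

```sh
markermap call    --bam sample.bam --ref ref.fa --repeats trf.dat --out candidates.vcf
markermap import  --vcf thirdparty.vcf --out candidates.vcf
markermap sv      --bam sample.bam --ref ref.fa --out sv.bed
markermap refine  --vcf candidates.vcf --sv sv.bed --repeats trf.dat \
                  --mean-depth 20 --out refined.vcf
markermap merge   --vcfs a.vcf --vcfs b.vcf --out merged.vcf
markermap recomb  --bam f2.bam --markers merged.vcf --ref ref.fa \
                  --window auto --out-prefix events/
markermap bsa     --bam pool.bam --markers merged.vcf --ref ref.fa \
                  --mutant-parent paternal --out regions.bed
markermap pipeline --config run.toml
markermap simulate --length 1000000 --depth 20 --seed 1 --outdir fixture/
```

Alignments may be plain SAM or BAM; repeats come from Tandem Repeats Finder
`.dat` output or BED. `pipeline` runs a declarative TOML stage list
(`call → sv → refine → merge → recomb|bsa`) and writes a run summary with
per-reason filter counts.

## Library

Each stage is an importable module: `markermap.calling`, `markermap.sv`,
`markermap.refine`, `markermap.recomb`, `markermap.bsa`,
`markermap.simulate`, with shared types in `markermap.core` and format I/O
in `markermap.io`.

## Tests

```sh
python -m pytest -q tests/
```

Unit and property tests per module plus `tests/test_acceptance.py`, which
rebuilds the simulation scenarios (artifact truth table, crossover
recovery, gene-conversion inflation with refinement disabled, pooled BSA
recovery, brute-force oracle equivalence) from fixed seeds. The full suite
takes several minutes because it simulates and re-analyses multi-megabase
genomes.

The acceptance report:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the analytic acceptance target (window-size formula) and writes
it as JSON.
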