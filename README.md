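# chromdiv

Chromosome-level conservation-genomics toolkit: windowed heterozygosity
landscapes from single-sample VCFs, coverage-based X-chromosome and
pseudoautosomal-region (PAR) detection, region-level rank-sum
comparisons, draft-vs-chromosome assembly metrics, and in silico PCR
localization of STR marker panels — all runnable end to end on seeded
synthetic data.

## What it does

- **`assembly_metrics`** — FASTA parsing, total/gap (N) length, scaffold
  N50, and draft vs chromosome-level comparison (fold N50 improvement
  with display rounding, signed gap change dN).
- **`variant_filtering`** — hard site filter (drop when QUAL < 20,
  SP > 60, DP < 5 or GQ < 20), a 50–250%-of-median coverage retention
  mask from per-base depth, and the SNP/indel split (heterozygosity
  downstream uses SNPs only).
- **`het_windows`** — heterozygous-SNP counts in non-overlapping 100-kbp
  and 1-Mbp windows scaled to SNPs/kbp, with pooled summaries.
- **`coverage_sexchrom`** — X identification from half-coverage windows
  in male samples and the three-stage PAR caller on 10-kbp window
  medians (70% threshold merge, 100-kbp run retention, gap bridging).
- **`region_stats`** — the five window subsets (all / noX / onlyX /
  noPAR / PAR) and one-sided Mann–Whitney tests ("PAR more heterozygous
  than autosomes", "autosomes more heterozygous than noPAR"), exact for
  small samples, tie-corrected normal approximation otherwise,
  Bonferroni-adjusted over the tests run.
- **`str_localization`** — Hamming primer-site search on both strands
  (≤ 4 mismatches, IUPAC-aware), 50–1000 bp amplicon pairing, MM/TM
  scoring, (MM, TM, length) ranking, and NA/D/L classification with the
  ΔMM ≥ 2 / ΔTM ≥ 3 separation rules; per-assembly panel summaries and
  marker densities.
- **`synthetic_data`** — seeded generators: multi-chromosome genome with
  het hot/cold spots and a terminal PAR on X, fragmented draft with a
  target N50, VCF records spanning the filter thresholds, male/female
  depth tracks (Poisson noise), and primer panels with planted
  target/decoy scenarios covering the whole classification space.
- **`viz`** — density heatmaps, subset boxplots, coverage band tracks,
  and marker ideograms (matplotlib, PNG/SVG).

## CLI

All stages are exposed under a single `chromdiv` entry point:

```sh
chromdiv simulate --out-dir fixtures/ --seed 42
chromdiv asm-stats --draft fixtures/draft.fa --chrom fixtures/chrom.fa --out asm.tsv
chromdiv filter-vcf --vcf fixtures/variants.vcf --depth fixtures/depth.bedgraph \
    --out filtered.vcf --bed-out retained.bed
chromdiv het-windows --vcf filtered.vcf --fasta fixtures/chrom.fa \
    --window 100000 --window 1000000 --out-prefix sample
chromdiv find-x-par --depth fixtures/depth.bedgraph --fasta fixtures/chrom.fa \
    --sex male --out-prefix sample
chromdiv region-test --windows sample.win100000.tsv --x-scaffold chrX \
    --par sample.par.bed --sex female --alpha 0.01 --out tests.tsv
chromdiv str-map --panel fixtures/panel.tsv --fasta fixtures/chrom.fa \
    --n-chromosomes 3 --out-prefix species
chromdiv plot --kind het-heatmap --windows sample.win1000000.tsv --out fig.png
```

`chromdiv simulate` accepts a YAML config (`--config sim.yaml`) mirroring
the fields of `synthetic_data.SimulationConfig`; outputs are
byte-identical under a fixed seed.

## Formats

Plain text throughout: FASTA, VCF 4.2 (single sample with DP/GQ/SP),
4-column bedGraph depth, BED intervals (0-based half-open), TSV tables,
and YAML simulation configs.
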