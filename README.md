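# ssrkit

A genome-survey SSR marker development and evaluation toolkit. It covers the
whole desk-side arc of a survey-sequencing marker study:

* **simdata** — synthetic inputs with exact ground truth: scaffolds with
  planted perfect SSRs on a rejection-sampled background, uniform-coverage
  paired-end reads with a two-state quality/error model, and structured
  diploid genotype panels (Balding–Nichols island model targeting a chosen
  Fst) plus dominant 0/1 band matrices.
* **kmer_survey** — clean-read filtering (N fraction, adapter overlap,
  low-quality fraction, duplicate removal), canonical k-mer depth spectra,
  genome-size estimation (`k-mer num / peak depth`), heterozygosity and
  repeat-content window heuristics, assembly N50/N90/GC statistics and
  per-library sequencing depth.
* **ssr_mining** — maximal perfect microsatellite detection (1–6 nt
  primitive motifs, per-length repeat thresholds, N-splitting), canonical
  strand/rotation motif classes, motif-class and repeat-number summaries,
  and the single-SSR scaffold screen by flank uniqueness.
* **primer_screen** — primer candidate enumeration under size / GC /
  nearest-neighbor Tm / product-length constraints, exhaustive in-silico PCR
  with a 3'-anchor rule, and single-/multi-locus classification (by
  amplification site count or by gel band count).
* **popgen** — codominant diversity statistics (Na, Ne, Shannon I, Ho, He,
  PIC), dominant-marker indices (PIC, BI, Rp, MI), per-group diversity with
  % polymorphic loci, Nei (1972) / Dice distances, UPGMA with locus-bootstrap
  support, PCoA, distance-based AMOVA with permutation tests, island-model
  gene flow, and an exact/asymptotic Mann–Whitney test.
* **cli** — `ssrkit` with subcommands `simulate`, `filter`, `survey`,
  `mine`, `primers`, `epcr`, `evaluate`; deterministic under fixed seeds,
  JSON run manifests, self-describing TSV outputs.

## CLI quick start

```sh
# synthetic genome with planted SSRs + reads + genotype panel
ssrkit simulate --outdir demo --seed 7 --n-scaffolds 10 --scaffold-length 2000 \
    --plant AG:10:0:500 --depth 10 --group-sizes 8,6,13

# read QC, k-mer survey, SSR mining
ssrkit filter demo/reads_1.fastq demo/reads_2.fastq --outdir demo/clean
ssrkit survey demo/clean/clean_1.fastq demo/clean/clean_2.fastq --k 25 \
    --outdir demo/survey --assembly demo/genome.fasta
ssrkit mine demo/genome.fasta --outdir demo/mine --min-mono 8 --min-rep 5

# primer design and electronic PCR classification
ssrkit primers demo/genome.fasta demo/mine/ssr_loci.tsv --outdir demo/primers \
    --size 18:27 --tm 55:65 --gc 30:70 --product 100:300
ssrkit epcr demo/primers/primers.tsv demo/genome.fasta --outdir demo/epcr --max-mismatch 0

# marker evaluation: diversity tables, AMOVA, UPGMA tree, PCoA
ssrkit evaluate demo/genotypes.tsv --groups demo/groups.tsv --bands demo/bands.tsv \
    --outdir demo/eval --permutations 999 --bootstrap 100 --seed 7
```

## File formats

All I/O is plain text: FASTA scaffolds, paired FASTQ (`/1`, `/2` suffixes),
and TSV tables whose first line is a `# columns:` schema comment. Genotype
matrices use `a1/a2` cells with `.` for missing; band matrices are 0/1;
coordinates are 1-based inclusive throughout.
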