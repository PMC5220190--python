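# peakscape

Analysis toolkit for the genomic distribution of transcription-factor
binding regions (ChIP-seq peak tracks) relative to gene structure and
chromatin states:

- **genome_io** — GFF3 / BED / MACS-style peak table / FASTA readers and
  writers normalised to an internal 0-based half-open coordinate model
  (`GenomicInterval`, `Track`, `TranscriptModel`, `Peak`,
  `ChromatinStateMap`), including the height ≥ 7 peak filter.
- **interval_engine** — location classification (TSS / GENE / INTERGENIC
  with TSS precedence), track intersection/subtraction, fraction-of-overlap,
  strand-aware upstream windows, the eight filtered upstream-region
  datasets (seven 500-bp bins spanning [−3500, 0) plus the 5′UTRs) and
  gene linkage through [−3500, +1] windows.
- **perm_test** — Monte-Carlo permutation tests (uniform per-chromosome
  re-placement, lengths preserved): per-location-class enrichment/depletion
  and track-overlap significance, reporting empirical and
  normal-approximation p-values with direction.
- **profile_model** — TSS-relative occurrence profiles (fraction of genes
  hit per offset, default window [−1500, +100]), the explicit
  `C + A·Norm(x; m, σ)` two-component model, a multi-start least-squares
  fitter, and chromatin-state-stratified profiles whose per-state values
  sum positionwise to the total.
- **motif** — PWM built from a count matrix (log-odds with
  background-proportional pseudocounts, pluggable weight function), min-max
  normalised scoring with a 0.91 default threshold, both-strand scanning,
  genome-normalised densities, per-interval Fisher comparison with
  Bonferroni 0.05/8 and 0.01/8 flags, and a threshold-calibration curve.
  The shipped octamer matrix is reconstructed from the consensus
  `AYGWAYCT` (Y = C/T, W = A/T).
- **enrichment_stats** — exact Fisher tests (with an exhaustive-enumeration
  oracle in the test suite), the EASE one-gene-jackknife variant,
  Benjamini–Hochberg adjustment, chromatin-state gene-list compilation
  (proximal-states-only vs distal-state-only, exclusivity enforced), and
  the two-list robust-GO-term comparison (fraction > 3 %, FDR < 0.05).
- **synthetic_data** — seed-deterministic generators for every input the
  pipeline ingests: packed gene annotations (GFF3), 9-state genome
  partitions (BED), peaks drawn from background + two TSS-relative
  Gaussians (with optional state-4 biasing), motif planting at per-state
  rates (FASTA), and GO annotation tables with controlled per-term
  fractions — each with a JSON ground-truth sidecar.
- **cli** — `peakscape synth | ingest | classify | permtest | profile |
  fit-bimodal | upstream-sets | scan | go-compare | run-all`.

## Quick start

```bash
# generate a synthetic input bundle (FASTA + GFF3 + states BED + peaks + truth)
peakscape synth --seed 1 --outdir synth/

# classify peak locations against the annotation
peakscape classify --gff synth/genome.gff3 --peaks synth/peaks.bed

# location-class permutation test
peakscape permtest --gff synth/genome.gff3 --peaks synth/peaks.bed \
    --chrom-lengths synth/chrom_lengths.json --n-perm 10000 --seed 1

# TSS-relative profile and bimodal fit
peakscape profile --gff synth/genome.gff3 --peaks synth/peaks.bed \
    --states synth/states.bed --window -1500:100 --out profile.tsv
peakscape fit-bimodal --profile-tsv profile.tsv

# the eight upstream-region datasets
peakscape upstream-sets --gff synth/genome.gff3

# PWM scan at the normalised 0.91 threshold
peakscape scan --fasta synth/genome.fa --threshold 0.91

# everything end to end on a synthetic bundle
peakscape run-all --seed 1 --outdir results/
```

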