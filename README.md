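# nadscape

Mapping and comparative analysis of **nucleolus-associated chromosomal
domains (NADs)** — the genomic regions that co-purify with isolated
nucleoli — in the style of tiling-array NAD studies of human fibroblasts
(proliferating vs. replicative-senescent cells).

The package implements the full downstream analysis as a tested,
reusable library plus CLI, and ships a synthetic-data layer that
generates every input with known ground truth, so each stage is
validated by parameter recovery rather than by eye:

- **`nadscape.caller`** — from raw nucleolar/background probe
  intensities to scored NAD/iNAD segmentations: quantile normalization,
  per-probe log2 enrichment *E* = log2(nucleolar) − log2(background),
  sliding-median smoothing in 100 kb windows, replicate averaging, a
  two-state Gaussian-emission hidden Markov model fitted by Baum–Welch
  (the genome-wide *E* distribution is bimodal), Viterbi decoding with a
  10 kb minimum NAD length, per-domain NAD scores (mean *E*), and
  bp-level differential domains between two conditions (young-only ¬S,
  senescent-only ¬Y, constitutive Y∧S).
- **`nadscape.genomics`** — interval comparative genomics: complements,
  overlap statistics and the Jaccard index (intersecting bp / union bp),
  chromatin-state composition of NADs vs iNADs, feature densities per
  Mb, per-segment signal means, border-aligned replication-timing
  metaprofiles, and boxplot class summaries with the notch
  1.58·IQR/√n.
- **`nadscape.hic`** — intrachromosomal Hi-C contacts (sparse triplets +
  per-bin normalization vectors, GSE63525 dialect) classified by domain
  pair (NAD-NAD / iNAD-iNAD / mixed) and chromosome arm (pp/qq/pq), with
  distance profiles, band summaries (10–50 Mb and >100 Mb) and masked
  heatmap matrices.
- **`nadscape.imaging`** — immunofluorescence quantification in shell
  ROIs of fixed physical depth (240 nm at 80.25 nm pixels → 3 px) inside
  the nuclear border and around nucleoli: intensity fractions, C.V.
  (sd/mean), brightest-pixel shares, and 3D object counts/volumes.
- **`nadscape.simulate`** — ground-truth generators for all of the
  above (domain tilings, bimodal array signals, annotation tracks, Hi-C
  matrices with a homotypic NAD-NAD boost, nucleus images).

## Worked example

Simulate a small genome, call NADs and compare against a second
condition:

```sh
$ printf 'n_chromosomes: 2\nchrom_length: 5000000\n' > cfg.yaml
$ nadscape simulate tracks --seed 1 --config cfg.yaml --out-prefix sim
wrote truth + 2 replicate tracks to sim.*
$ nadscape call \
    --nucleolar sim.nucleolar.rep1.bedGraph --nucleolar sim.nucleolar.rep2.bedGraph \
    --background sim.background.rep1.bedGraph --background sim.background.rep2.bedGraph \
    --out-prefix young
called 9 NADs covering 5,876,000 bp (median width 416,000 bp; 0 probes masked)
$ nadscape compare --set-a young.nads.bed --set-b sim.truth.nads.bed
intersection_bp 5869843
a_only_bp       6157
b_only_bp       62801
union_bp        5938801
jaccard         0.9883885653013125
```

`called 9 NADs covering 5,876,000 bp` means the Viterbi segmentation of
the smoothed, replicate-averaged enrichment found nine intervals
assigned to the high-enrichment state; the Jaccard index of 0.988
against the generating truth says the called and true NAD sets share
98.8% of their union at base-pair resolution.  The `.domains.bed` score
column carries each domain's NAD score (mean log2 enrichment × 1000),
with full-precision scores in the `.scores.tsv` sidecar.

The same workflow scales to genome-sized simulations: on ten 10 Mb
chromosomes with 1 kb probes and state means ±1 (σ = 0.3), the caller
recovers the true segmentation to ~99% of base pairs and the emission
means within ±0.05 (see below for reproducing these numbers).

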