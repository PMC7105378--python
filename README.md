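# crisprcolony

Analysis pipeline for type II CRISPR-Cas spacer acquisition in structured
(solid-media) bacterial communities challenged with phage:

- **`synthetic_data`** — seeded generators for every input the pipeline
  consumes: phage genomes, clonal colonies sharing one founder spacer plus
  priming-biased additional spacers, amplicon reads with
  `barcode + leader + repeat + (spacer + repeat)×n` structure, phage
  populations containing escaper mutants, Poisson spot-assay counts, and
  ordinal time-shift resistance matrices.
- **`array_parser`** — ordered spacer-array and barcode extraction from
  CRISPR-locus amplicon reads by fuzzy repeat detection; per-colony read
  profiles and the mono/multi colony call (2% multi-read threshold, strict
  inequality); barcode × founder-spacer concordance.
- **`spacer_mapper`** — spacer-to-protospacer mapping on both strands
  (Hamming, 0-based half-open coordinates), IUPAC PAM validation (default
  `NGG`, configurable), and seed/PAM/distal classification of escaper
  target mutations.
- **`priming`** — chronological first-to-second spacer target distances
  ("first" = leader-distal, since new spacers insert at the leader), 1-kb
  distance histograms counting distinct second spacers, and the 500-bp
  local-enrichment statistic against a uniform null.
- **`escape_assay`** — titers from dilution series with Poisson intervals,
  efficiency of plaquing (EOP) with below-detection bounds, escaper
  spike-in arithmetic, MOI.
- **`timeshift`** — ordinal resistance scoring (1 / 0.5 / 0), per-host
  means against phage populations of each time point, and co-evolution
  trajectories.

## CLI

```sh
crisprcolony simulate  --seed 1 --out-dir sim/            # genome + reads + truth
crisprcolony parse     --reads sim/reads.fastq --repeat GTTTTAGAGC... \
                       --barcode-window 10 36 --out-dir parsed/
crisprcolony map       --genome sim/genome.fasta --arrays parsed/arrays.tsv \
                       --out hits.tsv
crisprcolony priming   --arrays parsed/arrays.tsv --hits hits.tsv \
                       --genome-length 30000 --out-dir priming/
crisprcolony eop       --assays assays.tsv --out eop.tsv
crisprcolony timeshift --scores scores.tsv --out-dir ts/
```

All outputs are plain-text (FASTA/FASTQ/TSV); see module docstrings for
column schemas and coordinate conventions.

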