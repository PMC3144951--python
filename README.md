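# ferricnv

Quantitative-PCR copy-number genotyping and growth-association analysis for a
ferritin-type gene, plus annotation of the transcript's structural features,
driven end to end by a seeded synthetic-data generator.

## What it does

- **`ferricnv.qpcr`** — comparative-Ct quantification: aggregates replicate
  Ct wells, calibrates amplification efficiency from genomic-DNA dilution
  series (`E = (10^(-1/slope) - 1) * 100`), converts mean Ct differences to
  raw diploid copy estimates (`2 * 2^(-(Ct_target - Ct_control))`, with an
  optional `(1+E)`-based efficiency correction) and calls integer genotypes
  with a 0.3 / 0.7 fractional-part rule (ambiguous estimates are no-called).
- **`ferricnv.assoc`** — genotype-frequency tables (no-calls excluded from
  the denominator) and two-sided two-sample t-tests (Welch default, Student
  available) between copy-number classes, from raw values or from
  (n, mean, SE) summaries.
- **`ferricnv.seqfeat`** — longest-ORF/UTR partitioning, polyadenylation
  signal scanning (ATTAAA / AATAAA), protein mass and isoelectric point
  (EMBOSS pKa set), consensus iron-responsive-element stem-loop detection
  (CAGUGA loop, 5 upper-stem pairs, bulged C, lower stem; G·U wobble
  allowed) and cDNA→genomic exon/intron mapping with GT/AG-constrained
  spliced anchoring.
- **`ferricnv.simulate`** — reproducible generators for copy-number
  populations, triplicate Ct tables (built by inverting the copy-number
  equation plus Gaussian cycle noise), dilution series with a configurable
  per-cycle amplification factor, growth phenotypes, and random gene models
  for round-trip testing.

## CLI

All commands are under a single `ferricnv` entry point:

```sh
# efficiency calibration from a dilution table (log10_quantity,replicate,ct)
ferricnv calibrate dilution.tsv

# genotype calling from a Ct well table (sample_id,assay,replicate,ct)
ferricnv genotype wells.tsv --out calls.tsv \
    [--low-cutoff 0.3 --high-cutoff 0.7 --efficiency-correction \
     --eff-target 0.98 --eff-control 0.97]

# genotype frequencies and class association
ferricnv freq calls.tsv --population JH
ferricnv assoc calls.tsv phenotypes.tsv --class-a 3 --class-b 4 --method welch

# sequence feature annotation (FASTA in, GFF3-style TSV out)
ferricnv annotate --cdna cdna.fa --genomic gene.fa --ire --polya --protein-stats

# synthetic data with known ground truth
ferricnv simulate population --preset JH --n 100 --seed 1 --out genotypes.tsv
ferricnv simulate ct genotypes.tsv --seed 2 --out wells.tsv
ferricnv simulate phenotypes genotypes.tsv --seed 3 --out phenotypes.tsv
ferricnv simulate dilution --factor 1.97 --out dilution.tsv
ferricnv simulate cohort --config scenario.yaml --seed 4 --out-dir cohort/
```

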