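# paleopair

Reference-free pair analyses for low-coverage ancient genomes, built around
pseudohaploid genotype representations:

- **Pseudohaploid calling** — one random quality-filtered read allele per
  SNP, with optional transition masking against post-mortem deamination.
- **Pseudo-twin kinship test** — two distinct reads per site yield two
  pseudohaploid "twins" of one individual; the between-individual mismatch
  distance divided by the mean within-individual twin distance estimates
  2(1 − θ): 2.0 for unrelated pairs, 1.5 for first-degree relatives, 1.0
  for identical genomes. No allele-frequency reference required.
- **Conditional nucleotide diversity (CND)** — pairwise mismatch restricted
  to transversions polymorphic in a reference genotype panel.
- **f-statistics** — outgroup f3 (shared-drift affinity ranking),
  Patterson's D and f4, all with weighted block-jackknife standard errors.
- **qpAdm-style admixture modelling** — constrained GLS on an f4 equation
  system: mixture weights summing to 1, block-jackknife SEs, chi-square fit
  p-value, nested-model search, and infeasibility flagging (any negative
  weight).
- **Screening** — Ry-based chromosomal sex inference from X/Y read counts,
  and pileup genotyping of configured phenotype variants (the five
  lactase-persistence enhancer SNPs ship as the default set).
- **Synthetic data** — Balding–Nichols drift populations on a star
  phylogeny, optional admixture, diploid genotype panels, and low-coverage
  read simulation with configurable relatedness, Poisson depth, sequencing
  error, C→T/G→A damage and contamination — with ground truth recorded.

## File formats

- **EIGENSTRAT trio** `prefix.{geno,snp,ind}` (ASCII dialect; `9` = missing).
- **Pileup TSV**: `chrom  pos  base  base_quality  mapping_quality`, one row
  per read observation, `#` header lines. Reads below the (inclusive)
  quality thresholds — default `q ≥ 30`, `Q ≥ 30` — are dropped on ingestion
  and counted.

## CLI

One entry point, `paleopair`, with subcommands
`simulate | pseudohaploid | kin | cnd | f3 | dstat | qpadm | screen | sex`:

```sh
# generate a panel + two unrelated 5x individuals with ground truth
paleopair simulate --config sim.yaml --out sim

# kinship: between/within pseudo-twin mismatch ratio
paleopair kin --pileup1 sim.ind_a.pileup.tsv --pileup2 sim.ind_b.pileup.tsv \
              --panel sim --seed 1 --out kin.json

# conditional nucleotide diversity on panel-polymorphic transversions
paleopair cnd --pileup1 sim.ind_a.pileup.tsv --pileup2 sim.ind_b.pileup.tsv \
              --panel sim --out cnd.json

# f3 affinity ranking / D statistic / admixture proportions
paleopair f3 --panel sim --test P --candidates Q,R --outgroup O
paleopair dstat --panel sim --pops W,X,Y,Z
paleopair qpadm --panel sim --target T --sources S1,S2 \
                --rights R1,R2,R3,R4,R5,R6 --nested --out qpadm.json

# phenotype screening and sex inference
paleopair screen --pileup reads.tsv --out screen.json
paleopair sex --nx 9000 --ny 1000
```

A `simulate` config YAML mirrors `SimulationConfig` field-for-field
(`n_snps`, `pop_specs`, `admixture_specs`, `pair_spec`,
`ancestral_freq_range`, `seed`); every output JSON embeds the resolved
configuration and seed, and a fixed seed makes whole pipelines byte-for-byte
reproducible.

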