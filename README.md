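# popflux

Molecular population genetics of codon-structured loci, built for studies
that combine within-species polymorphism with between-species divergence
in small groups of related species (the classic *Drosophila* three-taxon
design: one population sample plus one or two outgroup sequences).

The package implements, as one tested pipeline:

- **Per-class diversity and divergence** — Watterson's θ_W = S/(a_n·L),
  nucleotide diversity π, and uncorrected divergence, computed separately
  for synonymous, nonsynonymous and intron sites with Nei–Gojobori
  fractional site counting for the coding classes.
- **Site-frequency-spectrum tests** — Tajima's D and the unnormalized
  Fay & Wu's H = θ_π − θ_H, with derived alleles polarized against
  outgroup sequences.
- **Demography-aware null distributions** — an exact back-in-time
  ancestral-recombination-graph (Hudson) coalescent simulator with
  recombination (R = 3N_e rL for X-linked loci), equilibrium /
  exponential-growth / three-epoch-bottleneck demographies and uniform
  parameter priors, turning observed statistics into empirical,
  Bonferroni-adjusted p-values.
- **McDonald–Kreitman tests** — 2×2 tables of
  {polymorphic, fixed divergent} × {synonymous, nonsynonymous}, including
  the combined-polymorphism variant (pooling two sister species) and the
  low-frequency-variant (FWW, < 15%) filter, tested with a two-tailed
  Fisher exact test (point-probability rule).
- **The codon-flux (CF) test** — fixed synonymous substitutions toward
  preferred vs unpreferred codons on a lineage (assigned by two-outgroup
  parsimony), compared against the counts of sites available for each
  direction in a 2×2 contingency test.
- **Parsimony substitution mapping** — Fitch-parsimony amino-acid
  substitution counts per codon on a species tree, multiple-hit
  summaries, and chi-square tests of regional substitution heterogeneity
  (e.g. N-terminal vs C-terminal domains).
- **Synthetic data with truth logs** — coalescent population samples
  threaded onto codon-structured sequences and Markov codon evolution
  along trees, every planted event logged, so each stage of the pipeline
  is validated against known truth.

## Worked example

Generate a synthetic population sample (12 sequences, two exons flanking
an intron, θ = 0.012/site, 8 fixed differences to the outgroup) and run
the summary-statistics and MK stages:

```
popflux fixtures --out demo/data --seed 42 --n 12 --theta 0.012 \
    --outgroup-divergence 8
popflux sumstats --alignment demo/data/alignment.fasta \
    --samples demo/data/samples.tsv --annotation demo/data/annotation.tsv \
    --species popA --outgroups out1 --divergence-to out1 --out demo/stats
```

`demo/stats/sumstats.tsv` then contains (this exact seed):

```
class          S  singletons  theta     pi        div       L_eff
synonymous     3  2           0.014754  0.012826  0.023506  67.3
nonsynonymous  1  0           0.001918  0.003071  0.008206  172.7
intron         2  0           0.011038  0.017929  0.115278  60.0
```

Reading the rows: the synonymous class carries S = 3 segregating sites
over an effective length of 67.3 fractional synonymous sites, giving
θ_W ≈ 0.0148 and π ≈ 0.0128 per site; the nonsynonymous class is much
less variable, as expected for a constrained coding region. The JSON
report adds the whole-region SFS statistics, here Tajima's D = 0.927 and
Fay & Wu's H = 0.758 (positive: this particular genealogy carries
intermediate-frequency variants; both statistics would be tested against
the simulated nulls via `popflux neutrality`). The MK stage,

```
popflux mkt --alignment demo/data/alignment.fasta \
    --samples demo/data/samples.tsv --annotation demo/data/annotation.tsv \
    --ingroup popA --outgroup out1 --out demo/mk
```

prints the 2×2 table and its Fisher p-value:

```
                Synonymous  Nonsynonymous  P-value
Polymorphic     3           1
Fixed divergent 1           1              1
```

Empirical null distributions for the SFS tests come from the simulator
(`popflux neutrality --observed-d ... --demography examples/demography.yaml`),
which reports one empirical p-value per statistic per demographic
scenario, the Bonferroni cutoff (α = 0.025/k), and "< 1/N" when no
simulated replicate is as extreme as the observation.

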