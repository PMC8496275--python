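# Methods

This note records the statistical procedures implemented in popflux, the
conventions and numerical choices behind them, what the synthetic-data
generators do and do not emulate, and the design decisions taken where
more than one defensible construction exists.

## Coordinates, site classes and effective lengths

All coordinates are 0-based half-open internally; human-facing reports
render 1-based inclusive. The codon frame is defined by the exon/intron
annotation: exon phases (position-in-codon of each exon's first column)
must chain consistently across splice junctions, and frame validation
requires every exonic gap run to be a multiple of three columns (indels
add or remove whole codons).

Columns are classified from the observed codon variants: a variable exon
column is *synonymous* iff all observed codons at its codon (holding the
other two positions at their observed context) encode the same amino
acid, *nonsynonymous* iff every observed allele encodes a distinct amino
acid, and *excluded* (and logged) when the codon segregates at more than
one position, shows mixed synonymous/nonsynonymous effects at one
position, contains a stop, or carries an alignment gap in any analyzed
row. Columns with N in a row drop that row from the affected computation
only. Monomorphic exon columns carry the label *invariant*; they enter
the analysis through the fractional site counts, not through variant
lists.

Effective lengths per class use Nei–Gojobori equal-weight counting: each
codon position contributes the fraction of its three possible single-base
changes that are synonymous (mutations to stops count as nonsynonymous,
so each codon always contributes 3 sites in total), averaged over the
analyzed rows. Intron effective length is the number of intron columns
complete in the sample. Equal-weight counting, rather than
transition/transversion-weighted variants, matches the behaviour of the
standard polymorphism tools this pipeline mirrors.

## Summary statistics

Per class: S, singleton count (folded minor-allele count of 1),
θ_W = S/(a_n·L_eff) with a_n = Σ_{i<n} 1/i, π as the mean number of
pairwise differences over all C(n,2) sequence pairs, and uncorrected
divergence as the mean proportion of differing sites over all
between-species sequence pairs (no multiple-hit correction — divergence
is used descriptively and inside contingency tests, not for rate
estimation). Sites with missing data anywhere in the population sample
are dropped listwise for S, π and the SFS, matching "complete deletion"
behaviour.

Tajima's D uses the 1989 constants; it is reported as undefined (None)
when S = 0 rather than coerced to zero. Fay & Wu's H is the
*unnormalized* θ_π − θ_H, with θ_π = Σ S_i·2i(n−i)/(n(n−1)) and
θ_H = Σ S_i·2i²/(n(n−1)) over derived-allele counts i — the scale on
which the classic polymorphism tools report it, which is why observed
values of magnitude several units arise for realistic loci. H requires
polarization: the ancestral state at a column is the outgroup state when
all covering outgroup sequences agree and that state matches one of the
two ingroup alleles; anything else (third state, outgroup disagreement or
absence, >2 ingroup alleles) flags the variant unpolarized and excludes
it from polarized statistics, with the reason recorded.

## Coalescent null distributions

The simulator is an exact back-in-time Hudson-style ARG, not an SMC
approximation: for a ~1.5 kb region with population recombination
parameter R of order 10², exact simulation is comfortably affordable.
Lineages carry intervals of ancestral material on [0,1); k lineages
coalesce at rate k(k−1)/2 rescaled by the population-size history;
recombination splits a lineage at rate (R/2) × its breakable span;
infinite-sites mutations fall at rate θ/2 per lineage per unit ancestral
span and record the exact set of descendant samples, so the polarized SFS
of each replicate is known without error. Material whose local leaf set
reaches the full sample (a local MRCA) is dropped from further tracking.

Time is in units of 2N₀ generations, θ = 4N₀μL, R = 4N₀rL — or 3N₀
scaling for X-linked loci, applied when converting a per-bp crossover
rate to R (`effective_R`). For the stated inputs (N_e = 10⁶,
r = 3.34×10⁻⁸/bp, L = 1500, X-linked) the formula gives R = 150.3; the
value 152 sometimes quoted for the same inputs is not reproduced by this
arithmetic, and the formula result is used.

Demography is piecewise-exponential: equilibrium, exponential growth
(size e^{−αt} backward), and a three-epoch bottleneck (sizes 1, s₁, s₂
with change points t₁ < t₂) are built-in factories. Epoch waiting times
are inverted analytically, so no time-discretization error enters.
Growth and bottleneck parameter values are deliberately *not* hardcoded
defaults: published estimates for any particular population belong in
the scenario config (`examples/demography.yaml` documents the format
with illustrative values).

Null distributions draw θ (and any demographic parameters) from
independent uniform priors per replicate, log every draw, and skip
replicates where the statistic is undefined (S = 0), with the skipped
count reported and the p-value denominator equal to the defined count.
Empirical p-values use inclusive tails — the proportion of null values
≤ observed (lower tail, for negative statistics) or ≥ observed (upper) —
and a zero count is reported as "< 1/N" rather than 0. Bonferroni
adjustment divides the family α (default 0.025 per side, i.e. cutoff
0.0125 for two tests) by the number of tests, with strict-inequality
rejection at the cutoff.

Default replicate count is 10,000 (a "< 0.0002" report requires ≥ 5,000);
it is a config field. The test-suite and acceptance-script calibration
runs use scaled-down sizes chosen to make Monte-Carlo error small
relative to the tolerances tested: 2,000 replicates at n = 10, θ = 5 for
the moment checks (±3 standard errors), 1,000-replicate nulls with 200
test points for p-value uniformity (Kolmogorov–Smirnov distance < 0.1),
and 300 replicates for the sign of E[D] under strong growth (α = 50).

## McDonald–Kreitman tables

A site is *polymorphic* when any listed species segregates more than one
nucleotide in its sample, and *fixed divergent* when all alleles of one
species differ from all alleles of the remaining species; a site that is
both counts as polymorphic only (the divergence definition requires all
alleles to differ, so the precedence is forced). Sites where a species
has only gaps/N are excluded and logged. Cross-tabulation against the
synonymous/nonsynonymous column classes gives the 2×2 table; the
combined-polymorphism variant simply lists two sister species in the
ingroup set, and reduces exactly to the single-species table when one
species' sample contains a single sequence.

The Fisher exact test is two-tailed by the point-probability rule: sum
the hypergeometric probabilities of all tables with the observed margins
whose probability does not exceed that of the observed table (relative
tie slack 1+10⁻⁷, the convention of R and scipy). This construction
reproduces the classic published MK p-values it is checked against
(0.015, 0.417, 1.00, and 0.031 for the frequency-filtered variant); a
one-tailed mode is available by flag. A zero margin yields p = 1.

The FWW filter removes polymorphic variants with frequency below a
threshold (default 15%) from the polymorphism cells only; frequency is
the derived-allele frequency when the variant is polarizable (unpolarized
variants are then excluded and logged) or the minor-allele frequency in
the alternative mode, and the mode used is recorded in the output.

## The codon-flux test

Fixed substitutions are assigned to a focal lineage by unpolarized
two-outgroup parsimony: the focal sample must be fixed for one codon
state and both outgroups share the alternative state; disagreeing
outgroups, focal polymorphism, stop involvement, or codons differing at
more than one position (path ambiguity) leave the change unassigned,
with the reason logged. Synonymous changes are labeled toward-preferred
or toward-unpreferred from a codon-preference table (config data, not
code; the shipped default marks one major codon per family for
*D. melanogaster*, and the species tag of the table is recorded in every
CF output for provenance).

"Sites" are current-state opportunity counts on the focal consensus:
codons currently preferred are opportunities for unpreferred change, and
codons currently unpreferred (in families possessing a preferred member)
are opportunities for preferred change — the only reading under which a
preferred-codon-rich gene shows many more unpreferred than preferred
sites, as observed. Met and Trp contribute to neither.

The 2×2 comparison of (substitutions toward each direction) vs (sites
available for each direction) uses the Pearson chi-square without
continuity correction by default; the Fisher exact test is available by
flag. The chi-square default is a reconstruction choice: on published CF
tables it closely matches the printed mid-range p-values (e.g. a (1,3 |
154,31) table gives χ² ≈ 9.0, p ≈ 0.0027), whereas no Fisher variant
does, so only order-of-magnitude agreement ("< 0.001" rows) is asserted
for the exact published values. The departure direction compares
per-site substitution rates and is reported only when p < 0.05. Type-I
calibration of the Fisher variant under symmetric flux is property-tested
(rejection rate ≤ 0.075 at α = 0.05 over 1,000 simulated tables); the
chi-square variant inherits the usual small-expected-count caveats.

## Parsimony substitution mapping

Per codon, the Fitch algorithm on the rooted (binary) species tree gives
the minimum number of amino-acid changes; parsimony is used rather than
ML because the quantities of interest are descriptive substitution
tallies, and the parsimony count is an exact lower bound on the true
event count (verified against logged simulation truth). One
deterministic resolution assigns changes to branches: top-down, a node
keeps the parental state when possible and otherwise takes the
alphabetically smallest member of its Fitch set, with ambiguity flagged
on the affected events; the number of assigned events always equals the
parsimony score. Codons with a gap in any species are excluded from both
the map and the region totals, symmetrically.

Region heterogeneity (substituted vs unsubstituted codons × region A vs
B) uses the closed-form 2×2 Pearson chi-square without continuity
correction, df = 1 — the construction that reproduces the published
N-vs-C-terminal comparison (24/137 vs 27/70 → χ² = 11.06, printed 11.1).
Region boundaries are config (default three-region layout 1–136 /
137–303 / 304–373, 1-based inclusive). The same generic operation serves
any published-count comparison; one published negatively-selected-site
chi-square (printed 0.023 for 77/137 vs 41/70) is not reproduced by this
formula (which gives 0.108) nor by the Yates-corrected variant, so that
printed value is not asserted.

## Synthetic data: what it does and does not emulate

`make_population_alignment` threads one ARG replicate onto a
codon-structured ancestral sequence: each simulated variant is assigned
to a still-unused column drawn by the requested class mix, with a derived
base whose effect matches the class, enforcing infinite sites globally
(a column eligible for two classes can still be used only once);
outgroups descend from the ancestral state with a configurable number of
fixed differences. `evolve_on_tree` runs Poisson numbers of synonymous
and nonsynonymous single-base codon events per branch, with a
controllable bias toward preferred codons. `make_mk_fixture` plants an
exact MK table into a three-species alignment (singleton polymorphisms,
ingroup-shared fixed differences). Every generator is
seed-deterministic, and every planted event is logged exactly once; the
truth logs replay to the emitted sequences.

These generators emulate the *combinatorial structure* of real data —
codon frame, site classes, genealogical frequencies, lineage-specific
fixations — not its mutational realism: no transition/transversion or
context bias, no rate heterogeneity among sites, no indels, no
sequencing error, and the population generator draws class labels
independently of genealogy. Passing tests therefore demonstrate that the
counting, polarization, assignment and mapping machinery is correct on
data whose truth is known, not that any particular biological dataset
will satisfy the tests' assumptions.

## Numerical and edge-case conventions

- Tajima's D and Fay & Wu's H return None (rendered explicitly) when
  undefined; empirical-p machinery skips and counts such replicates.
- Fisher: any zero margin → p = 1. Chi-square: zero margin → (0, 1).
- Bonferroni rejection is strict (p exactly at the cutoff is retained).
- Consensus calls break ties alphabetically (A<C<G<T) and ignore gap/N
  unless a column has no base at all (then N).
- Fitch tie-breaks are alphabetical, making maps reproducible
  run-to-run; ambiguous placements remain flagged.
- All RNG flows through `numpy.random.Generator` seeded once per run;
  identical seeds give byte-identical outputs.

## Known limitations

No α (adaptive proportion) estimators or asymptotic MK; no normalized H
or haplotype statistics; no gene conversion or selection in the
simulator; no ML ancestral reconstruction or dN/dS model fitting; CF
preference tables must be supplied for species other than the shipped
*D. melanogaster* default. The CF test's historical construction is
under-specified in the literature it descends from; the chi-square
default documented above is this package's explicit choice.
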