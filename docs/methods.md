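# Methods

This note records the models, parameter choices, and numerical
conventions behind each stage of the pipeline, and what the synthetic
cohorts do and do not establish about behaviour on real data.

## Simulation model

Cohorts descend from a single i.i.d.-uniform ACGT ancestral sequence
along an ultrametric clade history given as merge events in years
(`split_times_years`). A branch of duration *t* years receives
substitutions independently per site with probability
*t* · *g* · *μ*, where *g* is the generations-per-year value of the
configured growth model and *μ* the per-site per-generation mutation
rate (default 1.67 × 10⁻¹⁰). Two clades split *T* years ago therefore
show an expected pairwise divergence of 2 · *T* · *g* · *μ*; configs
whose deepest split implies an expected divergence above 0.75 are
rejected as saturated. Substitutions choose a transition with
probability `transition_fraction` (default 0.7), so TN93's separate
transition classes have signal; base composition stays uniform and GC
bias is not modelled. Strains coalesce within a clade
`within_clade_time_years` before the present (default 1,500 years,
which puts within-clade 30 kb window divergence an order of magnitude
below the painting threshold — the regime the painting method assumes).
There is no recombination apart from explicit admixture tracts, no
indels, no selection, and no aneuploidy; lineages are treated as clonal
mosaics.

Admixture is injected by copying a donor-clade strain's sequence over
stated intervals, so tract boundaries are exact and recorded to the
base pair. Variant profiles are synthesised to match each genome:
heterozygous sites at the requested rate with allele balance
Binomial(depth, 0.5); homozygous reference-difference records (the
strain against the cohort ancestor, standing in for a mapping
reference) with error-level secondary reads; and, for contaminated
strains, secondary reads at the mixing fraction wherever the
contaminant genome differs. Site depths are Poisson around the
configured mean; a small fraction of sites (default 0.5%) receives
sub-threshold quality.

Because mutations are placed uniformly, degenerate-site divergence
equals genome-wide divergence in these cohorts; on real data synonymous
sites diverge faster than the genome average, which is exactly why the
dating stage restricts itself to them. Passing the round-trip tests
therefore shows the estimator chain is consistent and correctly
calibrated on its own assumptions, not that those assumptions hold for
any particular real cohort.

## Quality control

Bases below phred Q40 are treated as missing (N). Heterozygosity is
heterozygous calls at quality ≥ 40 divided by the callable (quality
≥ 40) genome length. The contamination statistic operationalises a
visual allele-balance check that has no published numeric form: among
callable variant sites, the fraction whose consensus is homozygous but
whose secondary allele is carried by 10–35% of reads — too many for
sequencing error, too few for a diploid heterozygote. The band is
configurable; 10% keeps a Binomial(depth ≈ 50, error ≈ 0.002) site out
of the band with high probability, and 35% stays clear of the
heterozygote peak at 50%. All removal thresholds are strict
inequalities as worded (*over* 0.001 heterozygosity, *over* 1%
contamination, *below* 30× depth), so exact-boundary strains are kept.
Removal reasons are assigned in a fixed order (duplicate, missing
metadata, depth, contamination, heterozygosity); the kept set is
order-invariant because every rule is evaluated per strain.

## Distances and trees

All pairwise comparisons use pairwise deletion: a site enters only if
both sequences carry an unambiguous base. TN93 is the closed-form 1993
estimator from the two transition proportions, the transversion
proportion, and base frequencies averaged over the pair; the gamma
variant replaces each −ln(w) with α(w^(−1/α) − 1). Implementations
were checked against `ape::dist.dna` to full precision during
development, and the test suite re-derives them against an
independently coded formula. Saturated pairs (non-positive log
argument) return an inestimable sentinel (`inf`), never NaN, and
refuse to enter tree building.

Neighbour joining is the standard Saitou–Nei agglomeration. Ties on
the Q criterion are broken by joining the pair whose cluster
representatives (lexicographically smallest member ids) sort first,
making output deterministic; negative branch lengths are clamped to
zero. Bootstrap resamples alignment columns with replacement, rebuilds
the NJ tree, and annotates each internal edge of the full-data tree
with the percentage of replicates containing the same unrooted
bipartition (branch lengths and edge lengths ignored in the
comparison). Supports are properties of bipartitions, not nodes:
monophyly queries on unrooted trees look the support up in the
unrooted bipartition table before rerooting, which avoids the classic
label-migration artefact of rerooted Newick trees. Monophyly of a tip
set requires an outgroup to orient unrooted trees; the whole leaf set
and single tips are clades by convention with support reported as 100.

## Chromosome painting

Windows are non-overlapping, default 30 kb, 0-based half-open; a
trailing remainder at least half a window long stands alone, anything
shorter merges into the previous window (the historical script's
behaviour is unspecified; this rule is explicit and configurable). A
window with fewer than `min_callable_fraction` (default 0.3) compared
sites against every backbone strain is black (low coverage); the
original figure legend gives no numeric rule, so this one is declared.
Otherwise the window takes the clade of the backbone strain with the
minimum differing-site proportion — per-strain, not per-clade
consensus — and is white (diverged) when that minimum exceeds the
threshold (default 0.003). Cross-clade ties are flagged and resolved
to the alphabetically first clade. Composition is computed over
assigned windows only, excluding white and black windows, so that
regions likely to carry incompletely sorted ancestral polymorphism do
not contribute ancestry; a strain is admixed when its largest
single-clade composition is strictly below 90%.

Threshold calibration reports within- and between-clade window
divergence distributions from the panel and suggests the smallest
observed value below which at least 90% of within-clade windows fall,
floored at one mismatch per window. Backbone validation paints each
panel strain against the panel minus itself and removes strains with
under 50% own-clade or over 10% any-other-clade composition.

## Degenerate sites

Degeneracy of a codon position is the number of nucleotides at that
position preserving the encoded amino acid under the standard code;
4-fold and 2-fold positions are extracted, 3-fold (isoleucine)
excluded. Genes with introns, overlapping genes, and genes with N/gap
in any strain over at least half their columns are excluded first,
with a per-reason tally. Degeneracy is classified on a designated
reference strain (default the first genome); reference codons
containing N/gap or encoding stops are skipped entirely, and columns
where another strain's codon implies a different degeneracy class are
kept but flagged `discordant` in the provenance table, since codon
tools differ silently on this point and the disagreement should stay
auditable. Minus-strand genes are reverse-complemented before the
codon walk, so extraction is strand-invariant. Genes whose annotated
length is not a multiple of three are skipped with a recorded reason
rather than truncated.

## Dating

T_MRCA = k / μ / g. k is measured on a per-locus NJ tree rooted with
the outgroup: the mean over clade tips of the branch-length path from
tip to the MRCA of the clade plus any context tips. An empty context
measures to the clade's crown node; context tips from the sister group
move the node to the stem (divergence) node — which of the two a
published split refers to is often ambiguous, so it is a parameter
rather than a guess. The mean rather than the minimum or maximum
tip-to-node distance averages rate variation among tips. Loci where
the focal clade is not monophyletic are excluded with a recorded
reason and reduce n. The interval across loci is a Student-t CI on the
per-locus times (a normal-z alternative is configurable); with fewer
than two included loci the CI is undefined and flagged. Internal
values stay continuous; only report formatting rounds (generations to
the nearest integer, times to 0.1 kya), so the laboratory regime's
8086.15 generations/year prints as 8086.

## Problem sizes and reproducibility

The shipped study configurations are sized for single-CPU runs: the
dating study uses 20 cohorts of 2 clades + outgroup (3 strains each),
16 loci of 60 kb with ~12 genes and ~4,800 degenerate sites per locus;
the painting study uses 3 clades over six 300 kb chromosomes with 18
injected 90 kb tracts; the calibration panel is six clades over ~1 Mb
genomes. Every random draw flows from a single integer seed
(`numpy.random.default_rng`), and identical seeds yield byte-identical
cohorts. Under these conditions the dating round trip recovers a
12 kya split with ~4–7% mean relative error and 90–100% CI coverage,
tract recovery is 100% to window resolution, and calibration places
100% of within-clade windows under the 0.003 threshold — values
recomputed, not asserted, by `scripts/acceptance.py` and the test
suite.

## Known limitations

The simulator's uniform substitution process cannot produce the base
composition, rate heterogeneity, or indel structure of real genomes,
and its clean clade structure understates incomplete lineage sorting;
the painting and dating accuracies above are therefore upper bounds.
The contamination band is a proxy for a visual check and should be
re-tuned for depth regimes far from ~50×. The dating CI reflects
between-locus dispersion only, not phylogenetic error within loci.
ADMIXTURE-style allele-frequency modelling, ML tree search, and
relaxed-clock time trees are intentionally out of scope; painting
composition is the ancestry proxy and the k/μ/g estimator the dating
path.
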