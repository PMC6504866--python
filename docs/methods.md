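# Methods

`barcodegap` implements the analysis cycle of a curated COI barcode
reference library: reduce the library to unique haplotypes, characterise
the barcode gap with pairwise distances, delimit putative species from
those distances, classify every nominal species against each delimitation,
screen for misidentified specimens, and quantify how sampling effort biases
delimitation. This note records the models, parameter choices and numerical
conventions behind each stage, and what the synthetic validation does and
does not establish.

## Input model and filters

A library is an aligned FASTA of IUPAC DNA with headers carrying a
specimen id and, where available, a binomial identification
(`id|Genus epithet`, or BOLD-style whitespace separation). An epithet
whose first token is `sp`, `spp`, `aff`, `cf` or `nr` (with optional dot
or trailing digits) marks a specimen not identified to species; such
records participate in clustering but are never classified and never count
against another species. The standard inclusion filter keeps records with
strictly more than 486 ungapped bases (the minimum barcode-standard
length); an allowlist exempts individually curated shorter records.
Alignments are cropped with 0-based, half-open column windows; 667 columns
is the conventional COI barcode width used throughout the defaults.

## Haplotype collapsing

Duplicate sequences distort tree-based delimiters, so the library is
reduced to unique haplotypes in two passes. Pass 1 treats two records as
duplicates when they agree at every column where both carry an unambiguous
base and the less complete record's informative positions lie within the
other's informative span — ambiguity codes and N match anything, gaps are
missing data. Pass 2 re-checks survivors with plain pairwise identity
(zero observed differences over at least one compared site, no span
condition), catching staggered-coverage pairs. Within a duplicate set the
record with the greatest ungapped length is kept; equal lengths fall back
to the lexicographically smallest id, making the kept set independent of
input order. One representative per identified species is retained even
when species share a haplotype, so collapsing can never eliminate a
species from the library; `assert_species_preserved` re-checks this
invariant after the fact. The procedure is idempotent.

## Distances

All distances use pairwise deletion: per pair, only columns where both
records have A/C/G/T are compared. Three models are available — the raw
p-distance; Kimura's two-parameter correction

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with transition proportion P and transversion proportion Q; and the
Tamura–Nei 1993 correction with empirical base frequencies estimated from
the compared sites of the pair and separate purine/pyrimidine transition
classes. TN93 reduces to K2P when the four frequencies are equal and the
two transition classes balance; the test suite asserts this to 1e-9.
Saturated pairs (any logarithm argument ≤ 0) and pairs with no comparable
sites yield NaN, are flagged as undefined, counted in the log, excluded
from all min/max/mean summaries, and treated as +infinity (no edge) by the
clustering stages. Distances are stored as substitutions/site proportions
and rendered as percentages only in reports.

Per-species summaries give the maximum and mean intraspecific distance,
the nearest other species and the minimum distance to it; likely
misidentifications and unidentified specimens are excluded before
computation. Threshold reports list species pairs closer than 0.03 and
species with maximum intraspecific distance above 0.02 — the conventional
cutoffs for flagging taxa where diagnostic barcoding may struggle.
Standard errors come from a MEGA-style bootstrap that resamples alignment
columns with replacement (default 500 replicates), recomputes the
statistic per replicate and reports the standard deviation across
replicates; undefined replicates are dropped with a logged count.

## Delimitation

Two distance-based delimiters are provided. Single-linkage threshold
clustering returns the connected components of the graph joining pairs at
distance ≤ t; this is the clustering core of RESL-style procedures, without
any refinement stage. The recursive barcode-gap delimiter scans the sorted
pairwise distances for the first significant gap: consecutive gaps
g_i = d[i+1] − d[i] are examined where the gap reaches the prior maximal
intraspecific distance (d[i+1] ≥ PMID; distances wholly below the prior
are presumed intraspecific), and a gap is significant when it exceeds X
times the mean of the up-to-ten preceding gaps, where X is the relative
gap width. The matrix is split by single linkage at the gap midpoint and
the scan recurses independently within each subgroup, so different groups
can be delimited at different thresholds; recursion stops when no gap
qualifies, when a detected gap produces no actual split (chained groups),
or at a depth cap (default 20). A first gap with no preceding gaps cannot
be judged and is skipped.

This gap-significance rule is a concrete, documented variant of the ABGD
heuristic, whose published internals (theta-derived significance, slope
peaks) are not reproduced here; agreement with the original binary is not
claimed. What is validated instead is planted-truth recovery: with a
barcode gap of ratio 10 (see synthetic data below) and a prior inside the
gap, the delimiter recovers the generating species partition exactly
(adjusted Rand index 1) in at least 95 of 100 seeded libraries, and a
prior above all distances collapses everything to one group. The default
prior grid is the logarithmic series 0.001–0.1 in ten steps with
X ∈ {1.0, 1.5}.

## Trees and monophyly

Neighbor joining (Saitou–Nei Q-criterion) is the built-in tree builder
for distance matrices; externally inferred trees can be imported as Newick
and used interchangeably — NJ is a dependency-free fallback, not a claim of
equivalence to likelihood methods. Ties in the Q matrix are broken by the
smallest (i, j) index pair; negative branch-length estimates are clamped
to zero with the deficit moved to the sister branch, preserving the pair's
path length. On additive matrices NJ reproduces every pairwise distance
exactly and recovers the generating topology (asserted on random 5–12
leaf trees). Rooting places the root at the midpoint of the branch
separating a user-named outgroup, which must be a single leaf or a clade
of the unrooted tree. Species monophyly asks whether the smallest clade
containing all of a species' leaves contains any identified leaf of
another species; unidentified leaves are transparent, so a "Genus sp."
specimen inside a species' clade does not break its monophyly.

## Congruence classification

Each nominal species is classified against each partition: MATCH (one
cluster, pure), SINGLE (a match with exactly one sequence), MERGE (one
cluster, shared with another identified species), SPLIT (several clusters,
all pure), COMPLEX (several clusters, at least one shared). Unidentified
sequences never make a cluster impure. Across a panel of methods a species
is reported "high congruence" when all methods, or all but one (shown in
parentheses), agree on its category; each method is also scored by its
number of departures from the per-species modal category, with tied modes
skipping the species rather than guessing. The classifier is validated
exhaustively against a brute-force set-based reimplementation over every
partition of six sequences.

## Misidentification screening

A sequence is flagged when its minimum distance to sequences sharing its
label exceeds `t_self` (or it is its label's sole bearer) *and* its
minimum distance to some other identified species is at most `t_other`.
Defaults t_self = 0.05 and t_other = 0.02 reflect the empirical scale of
COI libraries, where intraspecific distances mostly sit below 5% and
interspecific distances above it. Severity records the rank of the
conflict (same genus → species_level, different genus → genus_level,
different family when a genus-to-family map is supplied → family_level).
Flags are advisory: the pipeline writes a corrections template
(id TAB corrected_species) for a human to confirm; a confirmed corrections
file is applied on re-run before any analysis. In real libraries this
screen replaces expert inspection of tree positions with an explicit
distance rule, so its flags are a reproducible approximation of, not a
substitute for, taxonomic judgment.

## Sampling-effort regression

Delimitation group counts per species are regressed on specimen counts by
ordinary least squares with the slope's F-test on (1, n−2) degrees of
freedom. Only MATCH and SPLIT species contribute: singletons cannot be
split (their inclusion biases toward matches) and merged or complexed
species have no well-defined own group count. Specimen counts use the full
pre-collapse library when a haplotype map is available (each haplotype
weighted by its multiplicity), since sampling effort is a property of
specimens, not haplotypes; a switch falls back to analysed-sequence
counts. Leave-one-out r² supports outlier influence checks. No
multiple-testing correction is applied across methods.

## Synthetic libraries

The generator plants the structure the analysis assumes. A root sequence
is drawn from the configured base frequencies; each species ancestor
receives Poisson(L·delta_inter) substitution events from the root and each
individual Poisson(L·delta_intra) events from its ancestor — a star
genealogy per species. Events pick a site uniformly with replacement
(multiple hits occur, so the distance corrections are genuinely exercised)
and apply a transition with probability kappa/(kappa+2), otherwise one of
the two transversions. Defaults describe a realistic stemborer reference
library: 64 species in genera of four, geometric sampling with mean 20
specimens (minimum 1, producing singletons and a heavy upper tail), 667 bp,
AT-rich composition (0.31/0.17/0.13/0.39), kappa = 4, delta_intra = 0.005
and delta_inter = 0.05 substitutions/site (a 10x planted barcode gap,
giving intraspecific distances around 1% and interspecific around 10%),
2% mislabeled specimens (swapped to a uniformly chosen other species),
16% specimens degraded to "Genus sp.", and 1% under-length records
truncated to 450 bp with flanking gaps. Everything is reproducible from a
single seed, and the ground truth (true species, true partition, injected
errors, ancestor sequences) is returned alongside the alignment.

Validation tests use scaled-down libraries (typically 10–40 species with
4–8 specimens each) so the full suite runs in well under half an hour on
one CPU; the statistical structure, not the library size, is what the
checks depend on.

Deliberate simplifications: no coalescent within species (independent
draws from the ancestor), no rate heterogeneity across sites, no indels,
no NUMTs or contamination, and label errors with no taxonomic structure.
Passing tests therefore demonstrate that each stage does what it claims on
data satisfying its own assumptions — a barcode gap, star-shaped
intraspecific variation, unstructured label noise — not that those
assumptions hold for any particular real library.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally, 1-based in messages.
Undefined distances never raise inside matrix computations; consumers that
cannot proceed with them (neighbor joining) refuse with an instruction to
impute or drop. Empty alignments, duplicate ids, non-IUPAC characters,
conflicting partition rows, constant-x regressions and out-of-range crops
raise immediately with the offending item named. All randomness (bootstrap,
simulation) flows from explicit integer seeds; the pipeline derives each
stage's stream from the single configured seed, so a rerun with the same
configuration produces bit-identical artifacts.

## Reproducing published-library numbers

The per-species summary, haplotype-collapse and threshold-report code
paths are the ones that, given the archived 1297-sequence stemborer
alignment (BOLD dataset DS-LSTEM), reproduce its published headline
numbers (620 haplotypes; minimum interspecific K2P of 0.028 between
*Acrapex albivena* and *A. minima*; maximum intraspecific K2P of 0.110 in
*Sesamia inferens*). That archive must be fetched separately and placed at
`data/lstem_haplotypes.fasta`; the two tests that check those numbers fail
with a clear message when it is absent. Everything else is validated
without external data.
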