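# Methods

## Interaction model and fitness estimation

Genetic interaction is scored as the deviation from the multiplicative
null: ε = W_AB − W_A·W_B, where fitness W is colony size in wild-type
units. Three plate sets enter a screen: the query × array double mutants
(W_AB), the control × array crosses (W_A per allele) and a query ×
neutral-array cross from which the query fitness W_B is taken as the
median colony fitness (an even count averages the middle pair). Each
array allele is pinned as a 2×2 technical quadruplicate; fitness is kept
at replicate resolution, so each allele yields up to four replicate ε
values. Missing colonies are flagged, never imputed; an allele with fewer
than two usable replicates on either cross is reported unscorable. Dead
colonies (size 0) are signal, not missing data.

Per allele, significance is a two-sided one-sample t-test of the
replicate ε values against zero. The screen this package models reports a
corrected p-value per allele without naming the test; the t-test over
quadruplicates is the minimal defensible choice, and whether the original
analysis pooled across plates instead is unknown — this implementation
tests within-allele replicates. p-values are Benjamini–Hochberg adjusted
across scorable alleles (statsmodels' step-up). A negative call requires
mean ε < −0.2 **and** q < 0.05; the positive rule is mirrored at +0.2, a
design default chosen for symmetry because only one positive interaction
was ever reported and no positive threshold was printed.

## Normalization and the fitness scale

Four modes: `none`; `median` (plate median of non-missing, non-border
colonies rescaled to the reference size); `gradient` (row/column median
polish in log space, plate scale untouched); `polish` (both). The polish
is classic Tukey iteration on log sizes; only the spatial deviations of
row/column effects from their medians are divided out, and rows or
columns with fewer than 12 usable colonies get no correction — with a
handful of colonies the line median *is* those colonies and the polish
would erase real per-allele signal (this matters on sparsely filled last
plates).

Absolute ε recovery needs a fitness-1 anchor. Plate-median anchoring
(`median` mode) assumes the typical array strain grows like wild type —
reasonable for temperature-sensitive collections handled at permissive
temperature, and the mode to use on real data. The simulated screens
instead use `gradient` mode with the generator's known pinning reference:
with a median single-mutant fitness around 0.75, anchoring the plate
median at 1 would inflate every ε by ≈1/(0.75·W_B) and recovery of the
planted values would be systematically biased. ε is invariant under joint
rescaling of all colony sizes in `median` mode (units cancel), which is
asserted as a property test.

## Validation rule

Spot-assay fitnesses are mean intensities divided by the mean control
intensity; expected double-mutant growth is W_A·W_B and a hit validates
when observed/expected < θ. θ defaults to 0.9: the qualitative rule "grew
more slowly than expected" has no margin, and 10% guards against
intensity noise at triplicate depth. Calls are invariant under common
rescaling of all intensities. The temperature-sensitive and tRNA single
mutants may reference separate control crosses; by default one shared
control is used, which changes nothing about the ratio's invariances.

## Growth kinetics

Three-parameter logistic, no lag term (matching the model family of the
R package conventionally used for microplate doubling times); doubling
time is ln 2/r and therefore reflects early exponential growth.
Initialization: K ← max OD, N0 ← first OD, r ← steepest 5-point slope of
log OD; bounded least squares with all parameters positive, `ftol` 1e-8,
at most 500 function evaluations. A series whose plateau is within 5% of
its start, or whose fit lands on a degenerate parameter set, is reported
`converged=False` with the fields unset rather than given a meaningless
doubling time. An optional scalar blank is subtracted before fitting.

## Substitution frequency

PSMs are filtered at q ≤ 0.01 (1% PSM-level FDR). A mistranslated peptide
(≥1 site with the −10.0207 Da Ser-for-Pro delta, matched within ±0.01 Da,
required to sit on a proline) qualifies only if the identical reference
sequence was also observed without the substitution; other modifications
(oxidation) do not disqualify a sibling. Unqualified mistranslated
peptides leave both numerator and denominator — the conservative reading
of the qualification rule. Frequency = 100 × qualified mistranslated
counts / counts of all retained peptides whose reference sequence
contains proline. Defaults count spectral counts and one event per
observed peptide (a doubly substituted peptide counts once); unique-
peptide counting and per-site counting are available because the field's
phrasing mixes "unique peptides" with "counts". The ±0.01 Da match
tolerance is generous for the catalogued monoisotopic deltas yet far
smaller than their pairwise differences.

## Dose–response categories

Normalized growth divides a construct's spot intensity by the same
strain's wild-type-tRNA construct (percent); the relative synthetic
effect divides that by the wild-type strain's normalized growth at the
same level, so 100% means no synthetic interaction, not no mistranslation
cost. Bootstrap dispersion (1,000 resamples of both numerator and
denominator replicates, seeded) accompanies each ratio.

The response categories form a biological continuum; the boundaries here
are this package's operationalization, all exposed in `CategoryRules`.
The cascade is: **uniform** if max−min ≤ 10 points; **proportional** if
low ≥ 90 and low > medium > high; **threshold** if 75 ≤ low < 90, medium
and high both < 75 and |medium−high| ≤ 10; everything else is
**low_sensitive**, whose characteristic pattern is a drop at the low
level at least 0.6× the drop at high. Two deliberate choices: threshold's
upper bound low < 90 makes the proportional and threshold regions
disjoint in the low coordinate, which guarantees the monotonicity one
wants from a dose classifier (deepening the high-level defect can never
re-label a threshold profile proportional); and the fallback clause makes
the classifier total — every admissible triple receives exactly one
category, verified exhaustively on a 1-point grid.

Group comparisons use Welch's unequal-variance t-test with Bonferroni
correction (p_adj = min(1, m·p)); two zero-variance groups with equal
means give p = 1 by convention.

## Synthetic-data generators

Generators are pure functions of (scenario, seed). Colony sizes and spot
intensities get multiplicative lognormal noise (default log-sd 0.05);
OD readings get additive Gaussian noise (default sd 0.01), truncated
below at 10⁻⁴ OD. Defaults encode the study conditions: 1,000 array
alleles, quadruplicate 1,536 layout with a border ring, single-mutant
fitness uniform on [0.5, 1]; query fitness 0.86 (the growth cost implied
by a 98- vs 84-min doubling time); planted interactions ε = −0.4 on 20
alleles; per-observation Pro→Ser rate 0.049 (control scenario 0.006) over
≥10⁴ proline-containing spectral counts; growth sampled every 15 min for
24 h; wild-type dose factors (0.71, 0.55, 0.37) at low/medium/high.
Allele placement on plates is randomly permuted: array layout is
arbitrary with respect to phenotype, and clustering planted interactions
into contiguous rows would make them indistinguishable from spatial
artifacts. Planted ε values are validated as feasible (W_A·W_B + ε ≥ 0)
at scenario construction.

What the generators do *not* emulate: pinning carry-over and neighbor
competition, batch/plate-scale drift, lag phases and diauxic shifts in
growth curves, peptide detectability bias and protein inference
ambiguity, and q-value miscalibration. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise models,
not robustness to every artifact of real arrays or real LC-MS runs.

## Problem sizes and numerical conventions

Recovery tests use one-plate (345-allele) screens; false-discovery
control uses 200 all-null 1,000-allele screens; frequency consistency
uses 50 tables of 5,000 counts; classifier totality is exhaustive over
the (0,120]³ 1-point grid — sizes chosen so the full suite runs in a few
minutes on one CPU. Coordinates are 1-based row-major (bench convention);
quadruplicates are modeled as 2×2 blocks, the standard 384→1,536
condensation geometry. The default simulation seed is 1729 wherever a
config requires one.

## Known limitations

Whether the original screen's border positions carried control strains is
not stated; the formats support annotated border/blank positions either
way, and border colonies are excluded from normalization statistics when
a border mask is supplied. The logistic model underestimates doubling
times for strongly lagged curves. The validation rule is a point
estimate, as in standard spot-assay practice — no replicate-level test is
attached to it.
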