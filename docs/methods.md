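# Methods

This note documents the models, conventions and design choices behind
`acrage`, in the order data flows through the pipeline, and states what the
synthetic study conditions do and do not establish about real data.

## Age categories on a dated species tree

The species tree must be strictly bifurcating and ultrametric (leaf depths
equal within a relative tolerance of 1e-6); split times are in million
years but are used only as ordinal labels.  Age categories are the nodes on
the path from the designated reference leaf to the root, plus the reference
leaf itself as the youngest category (age 0): a region with no alignment
coverage in any other analyzed species is species-specific sequence, not
missing data — absence of pairwise coverage is the only observable signal
that category has.  Polytomies and non-ultrametric trees are rejected
rather than resolved, since the analysis presumes a dated species tree.

The MRCA of a sharing set is resolved by nesting: reference-path clades are
totally ordered by inclusion, so the category of a set is the first path
node whose leaf set contains it.  A sharing pattern is **strictly
conserved** when it equals the full clade of its MRCA; any species missing
from that clade implies **secondary loss** after origin.

## Sharing profile

Per-species coverage intervals (0-based, half-open, sorted and merged on
input) are overlaid with a breakpoint sweep into maximal segments labelled
with the exact species set sharing them; uncovered stretches carry the
empty set, so segments tile each chromosome completely.  The profile is
invariant to species input order and is tested exhaustively against a
per-base brute-force labelling.  No minimum alignment-block length is
imposed at this stage (configurable downstream via `min_segment_len`,
default 1 bp).

## Age assignment (methods I–IV)

Methods I/II subdivide an ACR at profile boundaries, merge adjacent pieces
with identical (category, status), drop secondary-loss pieces under method
I, and drop pieces shorter than `min_segment_len`.  Methods III/IV assign
one age to the whole ACR: per candidate category the covered lengths are
summed, categories reaching at least one-third of the ACR length are
eligible, and the **oldest eligible** category is assigned.  Three choices
here were genuinely open and are fixed as follows:

* *Eligibility threshold* is `>=` one-third (strict `>` available via
  `strict_threshold`), and the aggregation is per category, not per
  species: a category qualifies through the summed length of its own
  segments.  An alternative reading aggregates per species (a species
  qualifies by covering one-third of the ACR, the age being the MRCA of
  qualifying species); the two differ only when a species reaches the
  threshold through several segments of different ages.  The per-category
  contract is what this package implements and tests.
* *Tie-break* when several categories are eligible: the oldest wins,
  attributing the element to its earliest substantial origin
  (`tie_break="coverage"` switches to largest coverage).
* *Exclusion under method III* is decided by the assigned category's own
  supporting bases: the ACR is excluded iff any base contributing to the
  assigned category implies secondary loss; bases of other categories do
  not affect exclusion.

By construction method I's segments are a subset of method II's, and method
III's assigned ACRs a subset of method IV's; both nestings are asserted on
every fixture.

## Read-level conventions

* **Tn5 correction**: the transposase duplicates 9 bp at the insertion
  site; plus-strand 5' ends shift +4, minus-strand −5 (both configurable),
  then only the single corrected base is kept.  Corrected positions outside
  the chromosome are clamped with a warning.
* **Consensus**: a pooled peak is retained iff, for every replicate, the
  summed overlap with that replicate's merged peaks is at least 50% of the
  *pooled* peak's length.  The pooled-length denominator is used because
  retention is decided per pooled peak.
* **Signal**: the count of corrected 5' ends in each (disjoint) ACR; RPM =
  count x 1e6 / total aligned reads; log10-RPM substitutes one pseudocount
  read for zero counts before the log.  FRiP is in-ACR count over total
  reads, with the ENCODE-style acceptability bound of 0.2 reported
  alongside.
* **Genomic context**: promoter (2 kb upstream to 1 kb downstream of any
  TSS, strand-aware, every annotated TSS spawning a window) > exon >
  intron (gene body) > proximal (5 kb upstream to 1 kb downstream) >
  distal; the precedence chain makes the labels a partition.  Promoter
  enrichment uses length-matched random controls placed by seeded
  rejection sampling, mutually non-overlapping, and a two-sided Fisher
  exact test.

## Recapitulation statistics

Relative tables normalize per (stage, replicate) to 100%; the denominator
contains only the segments the chosen method retained.  When raw reads are
available the pipeline recounts 5' ends inside each aged segment (exact
attribution); without reads, parent-ACR signal is apportioned to segments
by length, which assumes reads are uniform within the ACR.

Peak stages are argmaxes of replicate-mean trajectories with ties broken
toward the later stage (the hypothesis concerns late activation; the rule
is logged and configurable in spirit — the tie direction is fixed in code
and stated in the run summary).  The concordance statistic is Kendall
tau-b between category youngness and peak stage, restricted to a stage
window beginning at the configured phylotypic stage; categories whose
full-trajectory peak falls before the window are excluded so pre-window
behaviour cannot disturb the in-window statistic.  The p-value enumerates
all permutations of the peak vector for up to 8 categories and uses 10,000
seeded permutations above that.  Because peak stages are small integers,
this null is discrete: p-values are superuniform on their achievable atoms
(P(p <= a) <= a), which is the calibration property the tests assert; a
continuous-uniformity test would reject on discreteness alone.

Per-category stage effects use the Kruskal-Wallis rank-sum test on
replicate percentages across stages (tie-corrected; the degenerate
all-identical case yields H = 0, p = 1), with Benjamini-Hochberg control
of the FDR at 0.05 across categories.

## Phylotypic period (expDist / P_top)

The pairwise distance is 1 − Spearman rho over 1:1 orthologue FPKM values
(the monotone transform of the correlation does not affect rankings, which
are all the procedure uses); expDist of a one-stage-per-species
combination is the mean over the configured species pairs.  All
combinations are scored (guarded at 1e6), the lowest `ceil(0.01 N)` kept
(ties resolved deterministically by combination order), and P_top is the
percentage of kept combinations containing each stage, repeated 100 times
drawing one whole biological replicate per species-stage.  No expression
filtering is applied before ranking (the FPKM > 1 threshold belongs to the
gene-counting analysis only).  At desk scale the kept set is small (3 of
216 combinations under the default conditions), so the *recovered
phylotypic stage* is defined as the argmax of P_top summed over species;
per-species argmaxes can tie when so few combinations are kept.

## Gene-level analysis

Gene ages reuse the MRCA/conservation machinery on a gene x species
homolog presence matrix (presence meaning any sufficiently similar
sequence in that species' genome); the exclusion flag removes genes whose
presence pattern implies secondary loss.  Expressed-gene counts use a
strict FPKM > 1 threshold on replicate-mean values.  The relative
expression table sums FPKM of all aged genes by default (restricting to
expressed genes is an option), and feeds the same peak/concordance/KW
machinery as the chromatin tables.

## Synthetic study conditions

Defaults: a 7-leaf ladder tree (reference + outgroups at 90, 160, 320,
430, 530, 600 MY — seven categories including reference-specific), two
500 kb chromosomes partitioned into 500–2000 bp segments with genomic
category proportions (30, 22, 16, 12, 10, 6, 4)% skewed young, 210 ACRs of
400 bp (40% spanning two origins with a 35–65% split so both origins clear
the one-third rule), 8 stages x 3 replicates x 50,000 reads, 20%
background reads (FRiP ≈ 0.8), and a monotone planted schedule: category
rank k peaks at stage index 7−k.  Per-bp expected rates are Gaussian bumps
over stage index (baseline 1, amplitude 8, width 0.75 stages) — the shape
is irrelevant to the rank-based statistics; replicate noise is a
multiplicative lognormal factor (sigma 0.1) per (ACR, stage, replicate)
followed by Poisson counting; per-stage totals are normalized, emulating
read-depth control.  With `noise_sd = 0` counts are deterministic rounded
expectations and the recovered table equals the manifest's analytic
percentages exactly.

Two generator choices matter for interpretation:

* **Losses never remove the clade's most distant species.**  Losing the
  MRCA-pinning species changes the observable age itself — no method could
  recover the planted category even in principle.  Restricting Bernoulli
  losses (rate 0.08 per losable species per segment, putting the share of
  loss-affected ACRs near 15%, within the 10–20% range such data show) to
  the remaining clade members keeps every planted category identifiable
  while still exercising the strict/secondary-loss machinery.  On real
  data, outermost losses do occur and silently rejuvenate a region's
  apparent age; passing recovery tests here says nothing about that
  failure mode.
* **Reads are uniform within each origin segment** and follow that
  segment's category trajectory, so segment-level recounting recovers pure
  category trajectories.  Real ACRs have structured read pileups; the
  length-apportioning fallback is correspondingly approximate there.

Expression: log-FPKM = mu_g + t_g(s) + bump_g(s) + d(s)·delta_{sp,g} +
noise, with gene baseline mu ~ N(2, 0.6), a stage profile t following an
AR(1) with phi = 0.9 shared across species, an age-linked activation bump
(amplitude 1.5) peaking per the planted schedule plus a late "reuse" bump
(amplitude 2.0) for half of the older genes, species deviations delta ~
N(0,1) scaled by a divergence profile d(s) rising linearly from 0.15 at
the planted mid stage (index 2 of 6) to 1.75 at the far ends (depth 1.6),
and N(0, 0.1) replicate noise.  The depth and AR smoothness are set so the
lowest-expDist combinations are dominated by mid-stage-containing
combinations rather than matched off-mid ones — the planted structure the
hourglass emulates.  The P_top-uniformity null disables the hourglass
depth, the AR profile and the bumps together, since any of them breaks
stage exchangeability.  Orthology maps are identity up to a 5% per-pair
missing rate; the homolog presence matrix applies the same
outermost-protected loss rule as the genome.

What the passing tests show: the pipeline's inference machinery is correct
on data that satisfy its assumptions (exact sharing profiles, planted
schedules, lognormal-Poisson noise).  What they do not show: robustness to
alignment artifacts, repeat-driven spurious coverage, peak-calling noise,
stage misalignment between species, or expression normalization problems —
none of which the generator emulates.

## Numerical and reproducibility choices

All interval arithmetic is integer, 0-based half-open.  Every stochastic
component draws from `numpy` generators seeded from a single
`SeedSequence`; the generator emits byte-identical files and the pipeline
byte-identical tables for the same (config, seed).  The run summary
records the config hash, seed and every convention in force (shift sizes,
consensus denominator, tie-breaks), and pipeline errors name the failing
stage.  Problem sizes throughout (1 Mb genome, 210 ACRs, 1000-instance
oracle sweeps, 100 resamples, 1000-simulation calibrations) were chosen so
the full test suite and the acceptance script each complete in a few
minutes on one CPU while leaving the statistical assertions
well-powered.

## Known limitations

Methods III/IV implement the per-category one-third rule (see above), not
the per-species aggregation variant.  The concordance statistic is an
added summary — descriptive orderings plus per-category tests are what
such analyses usually report — and its discrete permutation null limits
p-value resolution below ~2/n! for n categories.  The phylotypic module
assumes the full combination space is enumerable; very deep stage series
need subsetting.  Coverage semantics are "a similar sequence exists"
(alignment-pipeline agnostic); reciprocal-best filtering, repeat masking
and alignment generation are upstream concerns.
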