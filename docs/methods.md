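# Methods

This note documents the models, numerical choices and limitations behind
`semkit`, in the order data flows through the toolkit.

## Quality representation

Raw phred scores are carried at full resolution only inside the coverage
model. Everywhere else they use a reduced representation: bins of 5 phred
units, bin *b* covering `[5b, 5b+5)`, with every score ≥ 45 in bin 9
(assemblers cap reported scores near 50, and differences above 45 carry no
usable signal). MAF `q` lines encode bins as `0`–`9`, `F` for
finished-grade sequence (treated as bin 9) and `-` at gaps.

A bin's *representative* value is its lower bound `5b`, and every
threshold in the toolkit compares against the representative: "q < 20"
selects bins 0–3 exactly. Using the lower bound is the conservative choice
— a bin straddling a threshold is treated as low quality — and is exact
whenever thresholds are multiples of 5, which all defaults are. Rounding
raw scores instead of flooring them would shift bin boundaries by 2; with
threshold comparisons on representatives the two conventions select the
same bins, so flooring was adopted without a flag.

Bases outside `{A, C, G, T, N, -}` are mapped to `N` with a warning.
Coordinates are 0-based half-open throughout (MAF/BED native); rows on the
negative strand keep MAF semantics.

## Difference tabulation and polymorphism correction

In a draft-vs-finished pairwise alignment, a base mismatch counts one
basecall difference at the draft base's bin; a maximal gap run in the
finished sequence counts one candidate insertion error, a maximal run in
the draft one candidate deletion error. An insertion run abutting a
deletion run is two events (one of each type); runs separated by at least
one aligned column are always distinct events. Sites where either base is
`N` are excluded from numerator and denominator, so masked bases can never
re-enter rates. Indel events are binned by the minimum quality over the
inserted bases (insertions only) and up to 5 draft bases on each side,
truncated at block edges.

The correction `r_esq = max(d_esq − d_esQ, 0)` treats the bin-9 difference
rate as nucleotide diversity π. Negative values arise from sampling noise
and are clamped to zero with a warning rather than propagated. The
aggregate "corrected" rate is aggregate raw minus the bin-9 rate,
reproducing a Raw/Poly./Corr. table layout. Correction is undefined when
an error type has no bin-9 sites; such types are flagged, not silently
zeroed. Region-restricted tabulation (e.g. CDS-only) uses the *reference*
species' coordinates and supports region-specific polymorphism estimates;
genome-wide and region-specific corrections are deliberately independent
calls.

Mitigation bookkeeping uses expected confusion counts: within each
(type, species, bin) stratum a fraction `f = d_esQ/d_esq` (capped at 1) of
observed differences is assumed polymorphic; `f` of masked differences
moves from TP to FP, and `f` of unmasked differences from FN to TN. The
total count is conserved for any `f`. Strata with undefined `f` contribute
raw counts and are flagged.

The per-exon error expectation multiplies each species' corrected per-bp
rate by its covered fraction of exonic bases and the exon length, sums
over species, and scales by 20/14 to extrapolate from the species with
finished-grade truth to a full 20-species panel; incomplete draft coverage
*reduces* the expectation and is intentionally not compensated.

## Coverage model

Assumptions: (1) read depth per position is Poisson(λ); (2) quality scores
accurately predict error rates (`P(error) = 10^(−q/10)`); (3) quality
scores are independent across the reads covering a position; (4) the
assembled base's score is the sum of its reads' scores. Under these, the
assembly quality distribution is `Σ_x w_x p_x`, where `p_x` is the x-fold
convolution of the single-read distribution `p1` (computed by direct
recursive convolution) and `w_x` is the Poisson pmf renormalized over
`x ≥ 1` — an assembly contains no zero-coverage bases, so the zero class
is truncated rather than folded in. Depth is truncated at
`x_max = max(Poisson 0.999 quantile, 10)`, overridable; enlarging it
changes Q\* by well under 0.01 phred at the defaults, and tests that
compare against infinite-sum closed forms simply raise it.

Quality sums are *not* capped inside the model: capping at an assembler's
encoding limit (≈50) would saturate the linear quality-vs-coverage trend.
The cap applies only when scores are encoded into MAF output. Q\* is the
generalized f-mean of basewise scores with `f(q) = 10^(−q/10)`, which is
why a few low-quality bases dominate an assembly that is "mostly very high
quality". `F1` restricts the error sum to depth 1; `F1_lowq` further to
single-read scores below 20 (default cut, configurable).

Non-Poisson depth distributions (real assemblies are overdispersed) are
out of scope; the model is exact only under assumption (1).

## Phylogenetic error score

Column likelihoods use Felsenstein pruning under a reversible nucleotide
model (Jukes–Cantor default; HKY and GTR constructors provided; transition
matrices via a precomputed eigendecomposition). `N` and gaps are missing
data (all-ones partials). The error log-odds for base `x_s` of species *s*
in column *X* is

```
log [ Σ_{i≠x_s} P(X with x_s→i) · M[i, x_s] ]  −  log P(X)
```

where `M` is the species' error transition matrix — `M[i, j]` is the
probability that true base *i* is misread as *j* given an error — with
zero diagonal and unit row sums, estimated by row-normalizing the
low-quality-bin mismatch spectrum of the difference tabulation (uniform
1/3 fallback for empty rows). The numerator is deliberately left
unnormalized: the score is used only as a monotone evidence measure (a
regression covariate or a sign check), so a proportionality constant would
cancel. The single-error assumption (at most one erroneous base per
column) keeps the sum linear in candidate true bases.

Both likelihoods carry a column-specific branch-length scaling factor ρ,
optimized separately for the error and no-error models over `ρ ∈ [0.01, 20]`
by deterministic bounded scalar minimization (tolerance 1e−4, with a
guard that ρ = 1 is never beaten by a worse boundary optimum). Absorbing
column rate variation this way is what makes a disagreement at a conserved
column score higher than the same disagreement at a fast column. Columns
with no aligned partner return an explicit undefined sentinel; callers
fall back to quality-only masking.

## Base masking

Threshold masking converts a base to `N` iff its quality representative is
below T (default 20, the setting used for downstream analyses). Masking
never changes alignment geometry, coordinates, other rows, or the quality
track itself, so the operation is reversible given the decision log.
Replacement bases are never imputed — a miscalled base carries only weak
information about its true identity.

The optional classifier is a logistic regression; default covariates are
the base's quality and the phylogenetic log-odds (with a missingness
indicator imputing 0 at the sentinel). Window covariates (local G+C,
flanking-quality min/mean over ±10 bp) are implemented behind a flag but
off by default — they add little once quality and log-odds are present.
Fitting uses IRLS (statsmodels GLM, Binomial family) to gradient tolerance
1e−8, deterministic given input order; fractional
(polymorphism-weighted) labels enter as likelihood weights, matching the
confusion-adjustment convention; perfect separation falls back to a light
ridge penalty (1e−6) with a warning.

## Indel imputation

Indel regions are extracted per block: maximal runs of gap-containing
columns flanked by gapless columns. Species absent from a block are
missing (`?`) throughout; a species' maximal gap run longer than 10 bp
becomes `?` across the run (long gaps are treated as missing data rather
than disqualifying the whole region). Gap runs abutting a block edge have
no gapless flank and are not emitted; cross-block bridging of gaps is not
implemented — inputs here are single-block or block-independent, and
stitching across blocks would need alignment-wide coordinate bookkeeping
that single-coverage draft alignments rarely justify.

Identical adjacent columns are compressed with multiplicities (events cost
the same regardless of length, so duplicate columns carry no signal).
Regions wider than 10 compressed columns are flagged and skipped. The cost
`w_ij` between presence/absence states is the minimum number of indel
events, where one event inserts or deletes a set of columns *contiguous in
sequence coordinates of the larger state* (consecutive among its
1-columns). This makes a deletion spanning an interior gap column a single
event — e.g. `101 → 010` costs 2, where naive per-column run counting
gives 3. `W` is computed by BFS over the state graph and cached per width;
it is a graph metric (symmetric, zero diagonal, triangle inequality), so
parsimony costs are invariant to the arbitrary rooting of unrooted input
trees. The naive column-run cost is available as a comparison function.

Ancestral states use exact min-sum message passing with full enumeration
of optimal states at every node. Lineage-specific calls are made column by
column under a unanimity rule: a leaf present where *all* optimal parent
states are absent is an LS insertion, and vice versa for deletions; any
parent ambiguity suppresses the call, and `?` leaves are never called.
Adjacent same-type called columns merge into one call. Only LS indels are
ever corrected — shared indels would require multiple coinciding errors.

Correction (threshold 25 by default, stricter than base masking because an
edit is more invasive than an N): spurious insertions are excised (columns
made all-gap are dropped), spurious deletions are filled with `N` at
quality bin 0 so downstream tabulation ignores the filled bases. Row
size/start fields and downstream block starts on the same source are
updated; overlapping contradictory calls resolve first-wins with a
warning, and every edit is logged with coordinates sufficient for
reversal. Alignments are never re-estimated after editing.

## Synthetic data

The generator's defaults are the study conditions, chosen once:

* coverage λ = 2 (the "2×" regime), genome G+C 0.41;
* single-read quality profile with 13.7% of bases below phred 20 (the
  heavy lower tail contributed by read ends), a small mid-range shelf and
  ~80% of mass at ≥ 45;
* basecall error probability `10^(−q/10)` at the true summed quality;
* polymorphism π = 5×10⁻³ per bp, independent of quality (typical
  mammalian nuclear diversity);
* insertion and deletion errors each at 0.125 × the basecall error
  probability of the site (indel error rates run a factor ~4 below
  basecall rates and share the quality dependence), lengths geometric
  (p = 0.7) capped at 10;
* true indels at 0.05 events per expected substitution, 60% deletions,
  lengths ≤ 10; coding mode draws 90% of lengths from {3, 6, 9}.

`simulate_assembly` emits a pairwise draft/reference block with full truth
(every polymorphism, basecall, insertion and deletion error, with raw
summed qualities); `simulate_alignment` evolves sequences down a six-taxon
tree recording every true indel's final column span; `inject_errors`
corrupts designated rows of an existing alignment and records a truth
table from which `replay_truth` reconstructs the input exactly. All
randomness flows from one seeded generator; outputs are bit-reproducible.

What the generator does *not* emulate: repeats and transposons, assembler
artifacts, alignment error, overdispersed read depth, context-dependent
substitution, indels longer than 10 bp. Passing recovery tests therefore
show the estimators are correct under the model's own assumptions, not
that real assemblies satisfy those assumptions.

## Problem sizes and numerical tolerances in the test suite

Recovery tests use a 200 kb assembly, 30 kb multi-species alignments and
3-SE binomial bands; the model-vs-simulation cross-check uses 1e5
positions for the 3-SE moment comparisons and 4e5 for the total-variation
check (the analytic quality pmf spreads over several hundred support
points, so 1e5 draws leave TV sampling noise above the 0.01 criterion).
Closed-form comparisons for degenerate read profiles use a widened depth
truncation (x_max 60) so truncation error sits below the 1e−6 tolerance.
Pruning is validated against explicit ancestral-state enumeration at
relative tolerance 1e−10 on trees of up to 5 leaves; parsimony against
exhaustive labeling enumeration for widths up to 4 (up to 5 leaves) and 3
(6 leaves), exact integer equality.
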