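# Methods

## Model and procedure

`regionsig` profiles how mutational-signature activities vary along a cancer
genome. The pipeline runs in five stages.

**1. Classification.** Each somatic single-base substitution is assigned to
one of the 96 SBS channels from its substitution type and trinucleotide
context. Channels are referenced to the pyrimidine strand: a mutation whose
reference base is a purine is mapped through the reverse complement of its
context (and complement of its alternate base) before lookup, which makes
classification involutive under strand flips. The canonical channel order is
the six substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each expanded by
5' then 3' flanking base in (A, C, G, T) order.

**2. Binning.** Mutations are ordered by chromosomal coordinate and grouped
into bins of equal mutation count (default 100). Two orderings are supported:
*chromosome-wise* (each chromosome binned and segmented independently — the
recommended setting for mutation-rich samples, since a concatenated ordering
carries no biological meaning across chromosome ends) and *genome-wise*
(chromosomes laid end-to-end in [1–22, X, Y] order, appropriate when
per-chromosome counts are small). A sample with N mutations yields
floor(N/bin_size) bins; the terminal bin (per chromosome, or per genome)
absorbs the remainder, so no mutations are discarded. Chromosomes with fewer
than `bin_size` mutations in chromosome-wise mode are kept as single
undersized bins with a logged warning — activity estimates on fewer than
~100 mutations are noisy, but silently dropping data would be worse.

**3. Activity fitting.** A segment's channel counts `n` are modelled as draws
from the mixture `p(k) = sum_s pi_s mu_s[k]`, where the emissions `mu_s` come
from the signature catalog and the mixture coefficients `pi` are the
activities. The categorical log-likelihood (the multinomial coefficient is
constant in `pi` and dropped) is concave in `pi` for fixed emissions, so EM
from a uniform start converges to the global maximiser: the E-step computes
per-channel responsibilities `pi_s mu_s[k] / sum_t pi_t mu_t[k]`, the M-step
sets each `pi_s` to its count-weighted mean responsibility. Channel counts
are sufficient statistics, so the per-mutation one-hot representation is
collapsed to a 96-vector per bin. Activities are not floored away from zero;
the M-step may reach the boundary exactly. The set of signatures fitted for a
sample can be restricted by an explicit per-tissue list or by fitting the
full catalog on the pooled sample counts and keeping signatures with at
least 5% activity.

**4. Segmentation.** The bin series is partitioned to minimise
`sum(-2 * logL per segment) + beta * n_changepoints` subject to two
constraints: every segment spans at least one bin, and no two changepoints
sit at adjacent bins (enforced inside the recursion, not post hoc). The
default penalty is the BIC charge `beta = (S-1) * log(N)` for the `S-1` free
mixture coefficients each additional segment introduces, with `N` the total
mutation count of the series being segmented (each chromosome's own count in
chromosome-wise mode); a scale factor is exposed for sensitivity analyses.
The optimisation is PELT: dynamic programming over candidate previous
boundaries with cost-based pruning, which is exact here because segment costs
are superadditive (pooling two segments never fits better than fitting them
separately). Pruning decisions are applied with a one-position delay so the
adjacency constraint never invalidates the pruning argument; the result is
identical to exhaustive dynamic programming, which the tests verify on small
series. With a single signature no changepoint is identifiable and the
penalty is infinite.

**5. Reporting.** A changepoint's magnitude is the cosine distance
`1 - cos(pi_left, pi_right)` between the flanking segments' activity vectors.
Its genomic interval is reported as the union of the two flanking bins'
spans, reflecting bin-scale positional uncertainty (the changepoint is only
localised to "between the last mutation of one bin and the first of the
next"). A bin's span runs from its first mutation to one past its last
mutation; whether the original formulation anchors bin edges at mutations or
at midpoints between bins is not documented anywhere we could find, and the
first/last-mutation convention is the simplest one consistent with reporting
multi-megabase changepoint regions. When a genome-wise bin boundary coincides
with a chromosome break the interval is clipped to the right-hand chromosome.

## Confidence, cohorts and association tests

**Bootstrap.** Bin boundaries are held fixed and each bin's mutations are
resampled with replacement (implemented as a multinomial redraw of the bin's
channel histogram, which is exactly equivalent and conserves bin sizes by
construction); the segmentation is re-run per replicate. A changepoint's
support is the fraction of replicates placing a changepoint within one bin of
it (the ±1-bin match tolerance is our operationalisation of "the same
changepoint" across runs — bin-level jitter is expected); a changepoint found
in more than one replicate is flagged high-confidence. Defaults: 5 replicates
for profile support, 20 for the cohort robustness protocol. All replicate
randomness derives from one user seed via counter-based `default_rng([seed,
replicate])` streams.

**Recurrence.** Each changepoint contributes a genomic range: a Gaussian KDE
with Silverman bandwidth over its location evidence (its bootstrap-replicate
placements plus its own midpoint), with range mean ± one SD of the smoothed
density — the sample SD inflated by the bandwidth, `sd * sqrt(1 + factor^2)`.
Degenerate evidence (single location, zero spread) falls back to the
flanking-bin span. Ranges from one tissue's samples are overlaid and counted
in sliding windows (1 Mb window, 0.5 Mb step by default — the window must
resolve the 4–5 Mb regions of interest; both are flags); each sample counts
at most once per window. Maximal runs of windows reaching the threshold
(default seven samples) merge into one region, reported at the maximum-count
window, leftmost on ties for determinism. Lowering the threshold only grows
the qualifying-window territory, so no region is ever lost — though two
regions can merge into one, so the raw region *count* is monotone only for
well-separated clusters.

**Kataegis.** An event is a maximal run of at least six consecutive
same-chromosome mutations whose mean inter-mutation distance is at most
1000 bp. The detector scans left to right: from the first start index that
admits any qualifying run it takes the farthest qualifying end (the mean is
not monotone in run length, so the scan continues past temporary violations
until the mean provably cannot recover), emits the event, and resumes after
it. Emitted events satisfy the criterion, cannot be extended by one adjacent
mutation, and never overlap; the tests verify exact agreement with full
enumeration of all qualifying windows. Cross-chromosome nearest-event
distances are measured along the [1–22, X, Y] concatenated coordinate — a
reporting convention (distances can exceed any chromosome length), not a
physical distance.

**Association tests.** The overlap test asks whether more of a sample's
changepoints overlap a discrete feature (CNAs, kataegis events, TAD
boundaries) than expected at random: null changepoint sets of the same
cardinality are drawn uniformly from the profile's admissible bin boundaries
— without replacement and respecting the non-adjacency constraint, so null
sets are themselves admissible segmentations (drawn exactly via the
combinatorial bijection when the boundary set is contiguous, by rejection
otherwise). The flank test compares a feature's distribution between the
changepoint-containing segment and equal-width upstream/downstream segments:
with `m` the midpoint between the changepoint centre and its neighbour (next
changepoint, or chromosome boundary when none), both segments have width
`|mid(c) - m|`, one centred on the changepoint and one on the neighbour,
clipped to chromosome bounds. The inner comparison is Fisher's exact test
for count features (2x2 table of events versus empty windows, 1 Mb windows by
default) and a two-sided Kolmogorov–Smirnov test at native track resolution
for continuous ones; the observed inner p-value is referred to an empirical
null of inner p-values from random boundary pairs separated by at least one
bin, which absorbs the discreteness and spatial autocorrelation of the inner
statistic. Empirical p-values use the add-one (Phipson–Smyth) correction so
they are never exactly zero; the plain proportion is available with a flag.
Per-changepoint results are reported raw at alpha = 0.05, with a
Benjamini–Hochberg column emitted alongside for convenience. Chromatin A/B
compartments are recoded A→1, B→0 and tested as counts; replication-timing
consensus is the per-segment median across cell lines.

## Synthetic data

The simulator is the generative mirror of the analysis model: planted
segments tile a synthetic genome (default four chromosomes, 80–120 Mb), each
carrying an activity vector, and every mutation's channel is drawn from the
segment's mixture. Positions are uniform within segments; the "piecewise"
density mode scales per-segment rates to decouple mutation-density changes
from composition changes. Kataegis clusters are injected as tight runs
(Poisson gaps around a target mean) biased to a single channel — by default
the modal channel of the local segment's mixture, so injected data remain
possible under the catalog. The bundled catalog has up to six synthetic
signatures, each concentrating `1 - overlap` of its mass on a private
16-channel block with the remainder uniform; `overlap` tunes pairwise cosine
similarity from 0 (orthogonal) upward, letting tests control identifiability
without shipping third-party reference data (a loader accepts real
COSMIC-style files).

What the simulations do not emulate: real trinucleotide-context composition
of a reference genome, clonal/subclonal structure, copy-number-driven
mutation-rate variation, sequencing or calling error, and the correlated
spatial structure of real feature tracks. Passing tests therefore establish
the correctness and calibration of the algorithms under the stated generative
model, not the biological findings obtainable from patient genomes.

## Problem sizes and numerical choices

- EM: uniform initialisation, convergence when the log-likelihood improves by
  less than 1e-6, at most 1000 iterations; monotonicity asserted every
  iteration. Catalog rows must sum to 1 within 1e-9 (readers renormalise).
- Segmentation exactness is verified against exhaustive enumeration on series
  of up to 12 bins; planted-switch recovery uses 20 bins of 100 mutations
  with adjacent-activity cosine distance well above 0.3, 50 seeds; the
  constant-activity null uses 100 seeds. These sizes keep the full suite and
  the acceptance script at a few tens of seconds while leaving the
  Monte-Carlo bounds meaningful.
- Calibration of the randomization tests uses profiles with eight planted
  switches so the overlap proportion takes a fine grid of values — with very
  few changepoints the discrete null cannot reject at small alpha at all, a
  property of the test, not a bug. Null sizes of 199 give an exact empirical
  test at alpha = 0.05 (rejection iff the observed statistic ranks in the
  top 9 of 200).
- Ties: equally maximal recurrence windows resolve leftmost; kataegis run
  selection prefers longer runs; the empirical-rank comparison of p-values
  uses a relative (not absolute) tolerance because inner p-values span many
  orders of magnitude.
- Degenerate inputs: empty mutation lists, all-zero activity vectors,
  single-signature catalogs (infinite penalty, no changepoints), segments
  with no feature windows (direction skipped with notice), and channels
  impossible under the catalog (hard error) are all handled explicitly.

## Known limitations

- The BIC constant is our accounting of the original method's "BIC penalty"
  (per changepoint, on the -2 logL scale, N in mutations); other accountings
  (N in bins, per-segment charges) are reachable through the penalty scale
  flag but not the default.
- The recurrence sliding-window width/step and the KDE location-evidence set
  are our operationalisations where the protocol leaves them unspecified.
- CCF-based (pseudo-time) trajectory analysis, de novo signature extraction,
  and indel/doublet catalogs are out of scope.
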