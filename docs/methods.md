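# Methods

`oncosnv` implements a complete, testable pipeline for classifying
somatic single-nucleotide variants (SNVs) as oncogenic drivers or
neutral passengers: dataset construction from mutation catalogues,
multi-source feature-group integration selected by greedy
leave-one-chromosome-out cross-validation, Platt-calibrated confidence
scores with cautious-classification thresholds, and a run-statistic
scanner for regions of interest. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Dataset construction

Positive examples are catalogue SNVs annotated with a **recurrence**
count — the number of independent cases in which the identical variant
was observed. Since co-located passengers contaminate driver
catalogues, positives are retained only when `recurrence >= r`
(inclusive; `r` is configurable, defaults `r = 5` for the coding model
and `r = 3` for the non-coding model). Negative examples come from a
germline-variant catalogue and carry their own contamination risk; to
control for genomic-location bias between the two sources, a negative
is retained only when it lies within a window `w` of a *surviving*
positive on the same chromosome (`|pos_neg − pos_pos| ≤ w`, inclusive;
defaults `w = 10,000` coding and `w = 1,000` non-coding). Pipeline
order is fixed: region routing → recurrence filter → window matching →
label merge; a variant key appearing in both catalogues is treated as a
driver observation and removed from the negatives (logged). Duplicate
keys collapse keeping the maximum recurrence, since recurrence counts
observations.

A mutation is routed to the **coding** model iff its position overlaps
at least one CDS interval of any transcript; everything else (intronic,
intergenic, UTR) is non-coding. Consequence-based routing would require
live annotation and is out of scope; the any-CDS rule is a declared
choice.

Coordinates are 1-based internally (VCF convention); BED (0-based
half-open) and GFF3 (1-based inclusive) are converted on read.
Chromosome names are stored without a `chr` prefix; `M`/`chrM`/`MT`
collapse to `MT`.

## Feature groups

Features are organised as named groups, each an `n × d` block with an
explicit missingness mask:

- **spectrum** — k-mer counts or frequencies for `k ∈ {1,2,3}` over a
  51 bp window centred on the variant (all `4^k` k-mers in
  lexicographic order; windows containing N skip the affected
  positions and renormalise). The exact window and k-range for this
  kind of feature are not canonical; these defaults are configurable.
- **gc** — GC fraction of the same window over non-N bases.
- **disruption** — spectrum(alt window) − spectrum(ref window), plus
  the L1 norm of the difference and the GC change: how much the
  substitution perturbs local sequence composition.
- **genomic_context** — per annotation kind (CDS, exon, splice site,
  start/stop codon, TSS): an overlap indicator and a signed distance to
  the nearest interval of that kind, capped at ±10,000 bp and
  missing-masked on chromosomes lacking the kind.
- **track groups** — one group per score track (conservation,
  mappability, or any chrom/pos/value table): the value at the
  position plus the mean and max over a ±2 bp window, with unscored
  positions excluded and all-missing windows masked. External
  annotation sources are deliberately consumed through this one
  uniform interface so the integration machinery treats every source
  identically.

Groups concatenate into a single design matrix with group-traceable
column spans. Missing entries are imputed with the **training-row**
column mean; optional standardisation (subtract mean, divide by sd) is
likewise fitted on training rows only, and zero-variance columns pass
through unscaled. Test rows never contribute to imputation or scaling
statistics.

## Leave-one-chromosome-out evaluation and integration

Each autosome present in the data is held out in turn as a test set;
X, Y and MT records only ever train. Per fold, a balanced training
sample (default 1,000 per class; all available when fewer) is drawn
from the remaining chromosomes, the classifier is fitted, and the
held-out autosome is scored; balanced accuracy (mean of sensitivity
and specificity) is averaged over folds, then over repeats (default
30 for model comparison, 10 for parameter tuning) with per-repeat
seeds derived deterministically from the base seed via a hash of
(seed, stream label, repeat index).

**Greedy data-level integration**: groups are ranked by individual
LOCO balanced accuracy (ties broken alphabetically so the ranking is
input-order invariant); the top two are concatenated and remaining
groups appended in rank order, recording cumulative accuracy. Both raw
and standardised variants are evaluated and the better recorded. The
selected set is the shortest prefix within `ε = 0.002` of the best
prefix — an operationalisation of "stop at the peak or plateau"; ε is
configurable and not canonical.

**Kernel-level comparator**: one Gaussian kernel per group, bandwidth
set by the median heuristic on pairwise training distances
(standardised per group), combined as a convex combination with
weights proportional to each group's individual balanced accuracy
above chance (floored at zero, renormalised; uniform fallback),
feeding an SVM on the precomputed aggregate kernel. This
accuracy-weighted combination is a deliberately simple stand-in for
heavier multiple-kernel-learning optimisation; the contract it serves
is the data-level versus kernel-level comparison, not a specific MKL
algorithm.

Classifiers: gradient boosting (default 300 stages, depth 3, learning
rate 0.1 — standard settings, all exposed) and an RBF-kernel SVM with
`C` tuned over nine log-spaced values from 1e-4 to 1e4 (ties take the
smaller `C`).

## Calibration and cautious classification

Raw scores `s ∈ R` map to confidence values ("p-scores") by Platt
scaling, `p(s) = 1/(1 + exp(A·s + B))`, with `(A, B)` fitted by Newton
iteration (gradient tolerance 1e-8, ≤100 iterations) on the
regularised targets `t+ = (N+ + 1)/(N+ + 2)`, `t− = 1/(N− + 2)`, which
keep the estimate finite on separable data. Inside the pipeline the
sigmoid is fitted on out-of-fold scores from an internal 3-fold
stratified split, avoiding the optimism of calibrating on training
scores.

At the default threshold, `p ≥ 0.5` is called a driver (a p-score of
exactly 0.5 counts as a driver call — a measure-zero tie rule). Under
**cautious classification**, predictions are accepted only when
`p ≥ τ` (driver) or `p ≤ 1 − τ` (passenger); the rest abstain and count
only toward coverage. Sweeping `τ` from 0.5 to 1 in steps of 0.01 gives
the cautious curve of balanced accuracy and coverage; entries with no
predictions or a missing class are flagged undefined, never
interpolated, and degenerate metric denominators return 0 with a flag
rather than NaN so the sweep stays total. The high-confidence threshold
is the smallest-τ local maximum within 0.002 of the best local maximum
among entries with coverage ≥ 0.05 (both configurable): when the curve
has two comparable peaks this picks the lower, because higher p-scores
are supported by fewer examples and are less reliable.

## Regions of interest

Per-position p-scores are scanned for contiguous runs of
high-confidence positive calls. With `q` the pooled fraction of scored
positions at or above the cutoff `c` and `N` the total number of scored
positions, the expected number of maximal runs of length ≥ L under an
i.i.d. Bernoulli(q) null is

    E(L) = q^L · (1 + (N − L)(1 − q)),

exact for all N, L, q (a run either starts at the first position, or at
one of the N − L interior positions preceded by a failure); this is
verified against full 2^N enumeration for N ≤ 12. A run passes when
`E < α` (default 0.01) and `L ≥` a minimum length (default 2); up to
`max_gap` sub-threshold scored positions may be absorbed inside a run
(default 0), and any unscored gap breaks a run. The exchangeable null
deliberately ignores the autocorrelation that conservation induces in
real score tracks, so on real data the expectation is anti-conservative
in conserved regions; this is flagged in the output metadata rather
than modelled.

## Synthetic fixtures

The generator emulates the *structure* of real inputs with known ground
truth: i.i.d. uniform-nucleotide chromosomes (default 4 × 100 kb);
non-overlapping two-exon genes at ~1 per 10 kb with CDS, splice-site,
start/stop and TSS sub-features; drivers with shifted-geometric
recurrence (ρ = 0.4, counts ≥ 1) placed half inside CDS; neutrals
placed within 1 kb of a driver with probability 0.8 (else uniform); and
score tracks valued at mutation positions, Normal(μ + δ, 1) at drivers
versus Normal(μ, 1) at neutrals for the planted informative subset,
pure Normal(μ, 1) otherwise, each value retained with probability 0.9.
The Gaussian class-conditional model is chosen because analytic
accuracy bounds exist (single-track Bayes accuracy Φ(δ/2)); it does not
mimic real conservation-score distributions, linkage among neutrals, or
mutational-signature context, so passing tests demonstrate the
machinery's correctness and calibration, not real-data performance.
A JSON manifest records which tracks are informative, δ, and the seed;
the same seed reproduces the fixture byte-identically.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at fixture scale
chosen as the smallest sizes at which the planted effects are resolved
cleanly: ranking-recovery replicates use 2,000 mutations per class with
one evaluation repeat and 150 boosting stages; the null and
integration-comparison checks use 300 per class with 2–3 repeats; the
library defaults (30 repeats, 300 stages, 1,000 + 1,000 samples) remain
the recommended settings for real analyses. Other numerics: Platt
Newton solver with 1e-12 Hessian ridge; sd < 1e-12 treated as
zero-variance; Gaussian-kernel PSD verified to 1e-8; duplicate score
track positions keep the last value (warned); balanced sampling draws
drivers first from a single seeded stream.

## Known limitations

- The feature set implements the sequence-computable groups exactly and
  treats every external annotation source as a generic score track or
  table; consequence predictions are consumed only as precomputed
  tabular features.
- The RoI null ignores spatial autocorrelation (see above).
- The greedy search examines only rank-ordered prefixes, by design;
  exhaustive subset search over many groups is intractable and not
  attempted.
- No liftover, compressed-index, or BigWig support; inputs are plain
  text formats.
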