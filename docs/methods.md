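# Methods

This note documents the models, parameters and numerical choices behind
`tubaquant`, and what the synthetic-data tests do and do not establish.

## Generative model of a cohort

A pool of lentiviral vectors is described by `PoolDesign`: each vector's
8-nt sgID maps to an sgRNA and target gene, with roles
inert / active / positive control / negative control. Synthetic pools
place sgIDs at pairwise Hamming distance ≥ 3, so a single sequencing
error can never convert one designed sgID into another; error-derived
sgIDs are therefore recognizable and are excluded from tumor calls as
"unrecognized".

Per mouse and per sgRNA, the tumor count is Poisson with rate
`tumors_per_sgRNA_rate × initiation_multiplier`. Tumor sizes follow a
mixture: with probability `1 − tail_fraction` a log-normal body
(`body_mu`, `body_sigma` on the natural-log scale of cells), otherwise a
Pareto tail with shape `tail_alpha` starting at
`tail_xmin_multiplier × exp(body_mu)`. Genotype effects multiply sizes
(`effect_multipliers`), which for the log-normal body is a location shift
on the log scale. Sizes are floored to integer cells with a ≥ 1 guard;
integer handling is a package decision, as is the mixture (rather than
spliced) form of the body/tail model, chosen for testability.

Defaults describe a mid-sized study: 10 mice, 100 tumors per sgRNA per
mouse, median tumor ~1000 cells (`body_mu = 6.9`), `body_sigma = 1.15`,
a 0.3% tail with `tail_alpha = 2` starting at 44.73× the body median,
and 0.1 sequencing reads per cell. Where no study value exists these are
one-time choices of realistic magnitudes, not tuned quantities.

### Read simulation and the error process

Each clone's amplicon is `left_context + left_flank + sgID + barcode +
right_flank + right_context` (68 nt with the default 10-nt segments);
mate 1 is the amplicon, mate 2 its reverse complement (a fully
overlapping short-amplicon read pair), and quality strings are a constant
`I` since the pipeline filters on alignment score, not PHRED.

Read errors are injected **per template molecule**, shared by both mates.
This models the *recurrent* (PCR-derived) errors that the denoiser
targets; it is also what makes the six substitution rates identifiable —
a mate-independent error would surface only as an `N` consensus position,
never as a clean base change. Errors are drawn from one multinomial per
clone over {clean, each single (site, class) event, double-error}, with
per-opportunity probabilities given by the `ErrorModel`; double-error
molecules pick two events weighted by probability, and third order and
higher (~(Lp)³ ≤ 1e-5 per read at default rates) is neglected.
`simulate_pileups` applies the identical event machinery directly to the
28-nt dual barcode, skipping FASTQ; it is statistically matched to the
FASTQ route (verified by a zero-noise identity test) but does not model
alignment-score dips from flank errors.

Determinism: every stage derives its RNG as
`default_rng([seed, crc32(mouse_id), stream])`, making all outputs —
including gzip FASTQ, written with a fixed mtime — byte-reproducible.

## Barcode extraction

Reads are aligned to `left_flank + N×28 + right_flank` with
Biopython's `PairwiseAligner` (local mode; match +4, mismatch −2, gap
open −6, gap extension −1, a gap of length g costing
`open + (g−1)·extend`). Placeholder `N` positions match any base, so
barcode content never penalizes alignment. Because that degeneracy makes
gap placement ambiguous (an indel inside the barcode region can be
traded for one at a flank boundary at equal score), placeholder matches
are internally down-weighted by 10⁻³; the perturbation is far below the
1-point score granularity, so the chosen path is always optimal under
the canonical scoring, which is what `align_read` reports. The reported
`score_fraction` divides by the maximum attainable score,
`4 × min(read length, reference length)`.

The dual barcode is the read segment aligned to reference positions
10–38 (0-based, half-open; insertions at or inside the region
boundaries included), extracted from each mate after
reverse-complementing mate 2. Agreeing positions keep their base;
disagreements become `N`. When the two extractions differ in length the
pair is marked length-mismatched and its pileup is later removed — under
template-level errors this effectively never fires (both mates carry the
same indel), which is intended: unresolvable pairs should not silently
join a clean pileup. Dereplication tallies identical consensus barcodes;
the pileup filter removes tallies with any length-mismatched member or a
mean score fraction strictly below 0.50.

Every input pair is accounted for: extracted, or dropped as
`unalignable` / `region_not_covered` with counts that reconcile exactly.

## Error model and Poisson denoising

The eight parameters are per-read, per-opportunity rates: six symmetric
substitution rates for the unordered A/C/G/T pairs, one insertion and
one deletion rate. Opportunities are counted per eligible base for a
substitution pair, L for deletions and L+1 for insertions (one deletable
site per base, one insertable gap per boundary), so that estimation
exactly inverts the generative process. Estimation takes, for each of
the 100 largest pileups of every mouse, the reads of its distance-1
satellites per class divided by parent reads and opportunities, and uses
the study-wide median of these per-parent rates (zeros included, making
the estimator robust to true tumors that happen to sit one edit from a
parent). Rates are estimated once for the whole study.

Edits involving `N` have no identifiable base change; they are excluded
from estimation and scored with the largest of the six substitution
rates (a conservative choice — more removal — for artifact candidates).

For each pileup the nearest neighbor is the pileup at minimal edit
distance with strictly more reads, ties broken by larger read count and
then lexicographically smaller barcode. The search is exact where it
matters and bounded where it cannot change the verdict:

- distance 1 by enumerating all single-edit variants (hash lookups);
- otherwise the nearest same-length pileup by vectorized Hamming
  distance, plus a cross-length probe (|Δlength| ≤ 2) against the 32
  largest candidates per length;
- the cross-length probe is skipped when an upper bound
  λ ≤ max(reads) × max(rate)² already leaves the likelihood below the
  threshold — beyond distance 1 no neighbor can then flip the decision.

λ multiplies the neighbor's reads by the product of the per-edit class
rates of the minimal edit script. The likelihood is the Poisson upper
tail P(X ≥ reads | λ), computed via the regularized-gamma survival
function (stable for large counts); λ = 0 gives exactly 0. Pileups with
likelihood above 10⁻¹⁰ are removed; reads are discarded, never merged
into the parent. The neighbor search spans all of a mouse's pileups
rather than only those sharing an sgID: with designed sgIDs at distance
≥ 3 this is equivalent for real barcodes, but it lets satellites whose
error fell inside the sgID region find their parent.

Diagnostics: the collision report gives, per sgID, the fraction of
random barcodes seen in more than one mouse and a method-of-moments
effective diversity D̂ = Σᵢ<ⱼ nᵢnⱼ / (cross-mouse repeat pairs), with the
birthday-approximation within-mouse collision probability
1 − exp(−n(n−1)/2D̂). GC bias is the least-squares slope of log reads on
barcode GC fraction with a t-interval.

## Quantification

cells = reads ÷ median(reads of the three ~10⁵-cell spike-ins) × 10⁵.
All three high spike-ins must survive the pipeline — a spike-in eaten by
filtering makes the sample unquantifiable, loudly. The 100-cell
spike-ins never normalize; they are recovered as a calibration check
(expected within Poisson error at the configured read depth). The
400-cell minimum cutoff keeps calls with cells ≥ 400 (inclusive) and is
applied after error filtering; spurious-pileup removal before size
selection is a package decision.

## Statistics

- **LN mean**: exp(μ̂ + σ̂²/2) with μ̂ the mean and σ̂² the divide-by-n
  variance of log sizes — the MLE of the mean under a log-normal
  sampling distribution. Always ≥ the geometric mean.
- **Percentiles**: linear interpolation between order statistics;
  percentiles beyond the resolution of n (fewer than one expected
  observation above) return the maximum with a saturation flag.
- **Heavy-tail burden**: summed cells strictly above
  `tail_multiplier × inert median`; the default multiplier 44.73 is the
  study-derived constant. `derive_tail_multiplier` re-derives a cutoff
  as the smallest multiplier where the empirical burden exceeds (and
  stays above, up to the 99.9th percentile) the burden expected from the
  fitted log-normal — explicitly non-canonical.
- **Relative statistics**: ratio to the pooled inert sgRNAs within each
  mouse, then arithmetic mean across mice; mice whose inert statistic is
  undefined (or zero) are excluded with a logged count. Gene-level
  statistics pool each gene's sgRNAs; both granularities are emitted.
- **Bootstrap**: two-stage — mice with replacement, then tumors within
  each resampled mouse — chosen because between-mouse variability
  dominates. Percentile CIs at 95%; two-sided p doubles the smaller tail
  around the null ratio 1 and is floored at 1/iterations. The default
  2,000,000 iterations is the study constant; tests and the acceptance
  script scale it down explicitly. With one usable mouse the mouse stage
  degenerates to tumor resampling, with a warning; iterations with an
  undefined statistic are dropped, and >50% undefined marks the result
  unstable.
- **Fisher's exact test** for tumor number: the observed group/inert
  tumor counts against the counts expected from pool composition, with
  the two-sided p computed by exact integer hypergeometric enumeration
  (tables with probability ≤ the observed are summed in rational
  arithmetic). No multiple-testing correction is applied by default.

## What the synthetic tests establish — and what they do not

Green tests establish internal consistency of the stated world:
alignment agrees with an independent full dynamic program, the Poisson
tail agrees with direct summation, injected error rates are re-estimated
within a factor of two, ≥99% of satellite pileups are removed with no
well-covered true tumor lost, sizes are recovered within ~5% median
error at 0.1 reads/cell, a ×5 log-normal location effect is recovered
within 20% with calibrated null coverage, and the whole pipeline is
byte-deterministic. They do not establish performance on real libraries:
the simulator omits PCR chimeras and jackpot amplification (beyond the
GC-bias diagnostic), lentiviral template switching, mate-independent
sequencing noise, quality-score structure, and primer/adapter artifacts.
The LN-mean effect-recovery checks use a tail-free log-normal world,
since under an infinite-variance Pareto tail the LN-mean ratio is not a
consistent effect estimator.

## Known limitations

- The denoiser's exactness beyond edit distance 1 is limited to the
  same-length Hamming search and a bounded cross-length probe; this is
  decision-exact under the documented λ bound but the *reported*
  neighbor of a clearly-true pileup may be a same-length one even when a
  marginally closer cross-length pileup exists.
- Error-rate estimation needs deep parents (expected satellite reads per
  class ≳ 1 among the top-100 pileups); on very shallow samples the
  median collapses to zero and denoising degrades to the min-cell cutoff.
- Percentile bootstrap intervals are first-order accurate; no BCa
  correction is applied.
- One sample per mouse is assumed; technical replicates must be merged
  upstream.
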