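# Methods

## The masking idea

The package treats TSS prediction as a one-sided problem. Every stage of
the classifier is thresholded at the minimum score attained by a training
TSS, so by construction no training TSS is ever rejected ("100% training
sensitivity"). Positions the chain rejects are then demarcated NTL. The
value of an NTL map rests entirely on the false-negative rate being at or
near zero: only then can a rejected position be read as "cannot initiate
transcription" rather than "was missed".

The four stages read different views of the same 200-nt window (TSS at
character 101; upstream [−100,−1], downstream [+1,+100]; minus-strand
windows are reverse-complemented so they always read 5′→3′ on the
transcribed strand):

1. joint upstream/downstream occurrence envelopes of all 1,364 k-mers
   (k = 1..5);
2. a 20-nt PWM over [−10,+10], conditioned on the dinucleotide at [−1,+1]
   (16 subsets);
3. a per-subset Fisher linear discriminant over 40 section-PWM scores
   (40 non-overlapping 5-nt sections);
4. one RBF SVM over the same 40 features, with the adjustable threshold
   t_SVM (strict >; everything else uses ≥, so ties pass stages 1–3 but
   not stage 4).

The stages are conjunctive and ordered cheap-to-expensive; the SVM sits
last because it is the costliest per window and carries the only tunable
threshold.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| window length | 200 nt (fixed) | [−100,+100] with no position 0; TSS at character 101 |
| k_max | 5 (fixed) | 4+16+64+256+1024 = 1,364 k-mer features |
| PWM pseudocount | 0.25 per base | additive smoothing; keeps all weights finite |
| PWM background | uniform (0.25) | log2 likelihood-ratio weights w = log2(p̂/bg) |
| SVM γ | 1.28 | radial-basis bandwidth |
| SVM C | 1.0 | standard soft-margin default; the sensitivity contract is carried by thresholding, not the margin |
| feature scaling | off | features enter the SVM as raw PWM-score sums; z-scaling (training mean/sd stored in the model) is available behind `TrainConfig.scale_features` |
| t_SVM | −2.5 | default operating point: 100% sensitivity on training data |
| threshold grid | −2.50 … 1.25 (12 values) | the standard sweep range for trade-off tables |
| LDA ridge | 10⁻⁶·trace(S_w)/40 | added to the pooled covariance diagonal only when its condition number exceeds 10⁸ |

PWM normalization is a free choice for stages 2–3: each subset threshold
is the minimum of its members' scores under the same matrix, so any
strictly monotone transform of the scoring yields identical decisions
(this equivalence is asserted by a test). It is *not* free for stage 4,
where the feature scale interacts with γ — see "Known limitations".

## Decision rules at the boundaries

- **Unobserved counts reject (stage 1).** The envelopes are defined only at
  observed values; if a window's u (or d) for some k-mer was never seen in
  training, the constraint fails. This is the conservative reading of a
  region "containing all TSS locations" and preserves the training-
  sensitivity contract exactly. The alternative — interpolating bounds
  across gaps between observed boundary points — was evaluated and changes
  held-out decisions by <0.3% on synthetic data (failures are new count
  *extremes*, not interior gaps), so the simpler rule is kept.
- **Absent subsets reject (stages 2–3).** A window whose central
  dinucleotide had no training members cannot be scored and is rejected,
  mirroring the stage-1 logic; no training member is ever in an absent
  subset.
- **Data-starved subsets pass stage 3.** A subset whose positive or
  negative class has fewer than two members cannot support a covariance
  estimate; it receives a degenerate discriminant (zero coefficients,
  threshold 0) that passes every window of the subset. This keeps the
  training-sensitivity contract without inventing a separating direction
  from one point. A subset with positives but *no* negatives is a training
  error naming the subset.
- **UNSCORED ≠ NTL.** Scanned positions whose window would overrun a
  sequence end, or whose window contains non-ACGT characters, are labeled
  UNSCORED. Conflating "cannot evaluate" with "cannot initiate
  transcription" would corrupt NTL fractions, so NTL/TIAR fractions are
  reported over scored positions with the UNSCORED fraction alongside.
- **Negative sampling.** Random 200-nt windows are drawn with probability
  proportional to sequence length, strand uniform; windows containing
  non-ACGT are redrawn, as are windows whose center lies within ±10 nt of
  any CAGE 5′ end. The CAGE exclusion ignores the strand of the CAGE
  record — the conservative choice, since a TSS signature on either strand
  near the center makes a window a doubtful negative.
- **Evidence-based TSS compilation** keeps a CAGE 5′ end only when its
  (sequence, position, strand) triple exactly matches an independent
  transcript 5′ end; duplicates collapse, and no minimum spacing between
  neighboring TSSs is enforced.

## Numerical choices

- LDF scores are computed everywhere by one elementwise multiply-and-sum
  path. A BLAS dot product can round differently for a single row than for
  a batch, and the member attaining LDF_min is compared with exact ≥, so a
  single arithmetic path is required for the tie-passes contract to be
  bitwise reliable.
- After fitting, the SVM's support vectors, dual coefficients and intercept
  are extracted and all decision values are computed by the package's own
  kernel expansion Σᵢ αᵢyᵢ·exp(−γ‖xᵢ−x‖²) + b. The persisted model stores
  exactly these arrays as JSON (floats round-trip exactly), so a reloaded
  model reproduces decision values bit-for-bit, and retraining on an
  identical corpus and configuration yields a byte-identical file.
- With pseudocount 0 a zero-probability base would score −∞; it is mapped
  to a finite sentinel (−10⁹) so scores stay finite and orderings survive.
- Fold assignment in cross-validation permutes each class separately
  (seeded) and deals indices round-robin, so fold sizes differ by at most
  one and both classes appear in every training fold. All four stages,
  including every minimum-score threshold, are re-derived on each training
  fold.

## What the synthetic generator emulates

Positives are i.i.d. background DNA (GC 0.42, the mammalian genome-scale
value) with three planted signals, chosen to live on exactly the feature
axes the stages read: +0.15 GC inside [−40,+40] (stages 1 and 3), a
pyrimidine–purine initiator at [−1,+1] with probability 0.8 (stage 2
subsets), and "TATAAA" at −30 in 30% of windows (stages 2–3). Negatives
are pure background. Genomes embed full positive windows (strand-aware) in
background sequence and return the planted coordinates as ground truth.

The generator does **not** model CpG islands, nucleosome positioning,
conservation, repeat structure, or the long-range isochore composition of
real chromosomes. Passing tests therefore demonstrate that the machinery
is correct and that the chain exploits planted composition signal — not
that the quantitative NTL fractions transfer to real genomes, which depend
on corpora of ~10⁵ experimentally validated TSSs.

## Problem sizes

The test suite and the acceptance script run at desk scale: training
corpora of 2,000/2,000 windows (4,000/4,000 for the genome-scan
experiment), 4-fold cross-validation at 2,000/2,000, genome scans of
~40 kb with 50 planted TSSs, and oracle comparisons on ≥500 random
instances per operation.

## Known limitations

- **Envelope saturation.** The stage-1 envelopes are order statistics of
  2×1,364 conditional count distributions. A fresh positive passes only if
  it sets no new record, so held-out sensitivity grows with corpus size:
  at desk scale (10³–10⁴ positives) measured held-out stage-1 pass rates
  are 0.39 (n = 2,000) to 0.56 (n = 4,000), and saturation to ≥0.95
  requires on the order of 10⁵ training windows. Desk-scale held-out
  sensitivity (cross-validation rows, planted-TSS recall) is therefore far
  below what saturated-regime training achieves, and those numbers should
  be read as small-sample behavior of the envelope stage, not as the
  method's ceiling.
- **RBF locality at the default bandwidth.** With log2 likelihood-ratio
  PWM features, squared distances between 40-dimensional feature vectors
  are large relative to 1/γ at γ = 1.28, so the kernel is extremely local:
  training points are memorized and fresh windows receive decision values
  near the intercept. In consequence stage 4 separates training classes
  perfectly, while on fresh data the discrimination burden falls on stages
  1–3 and t_SVM behaves as a near-binary gate around the intercept. The
  bandwidth and the feature normalization are jointly responsible; both
  are exposed in `TrainConfig` (γ, pseudocount/background, z-scaling).
- **No smoothing of tracks.** NTL/TIAR runs are emitted raw; at
  single-nucleotide resolution they can be small and clustered. Consumers
  wanting contiguous masks should post-process the BED output.
- The negative-sampling retry budget makes pathological inputs (exclusion
  zones covering every center) fail fast with an explicit error rather
  than looping forever.
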