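# Methods

## The problem

Saturation-mutagenesis reporter assays (MPRA) measure, for (nearly) every
single-nucleotide variant of a cloned promoter or enhancer, a confidence
score on [0, 1] for an expression effect and a direction label (-1/0/+1;
variants with confidence >= 0.1 are called regulatory).  Machine-learning
benchmarks built on such data typically split each reporter *internally*
into alternating training and validation segments.  Because regulatory
function lives in contiguous sequence elements and most genomic features are
locally autocorrelated, nearby training and validation items are not
statistically independent: a model can interpolate its training labels into
the neighbouring validation segments.  This package measures that
information leakage by holding the learner fixed (a non-tweaked random
forest) and varying only (a) the train/validation layout and (b) whether the
features carry any biological signal at all.

## Synthetic study conditions

All experiments run on synthetic data whose generator
(`mpra_leakage.synthetic`) emulates the statistical structure of a
multi-reporter saturation-mutagenesis assay.  Defaults (the study
conditions):

- **14 reporters of 420 bp** (5 "enhancers", 9 "promoters"), each assayed in
  its own cell type, plus one duplicated reporter: the last reporter's
  sequence and genomic interval appear a second time under another cell
  type with an independently noised effect table — the analogue of a
  promoter assayed twice.  All 3L SNVs per reporter are present.
- **3 planted regulatory elements per reporter**, sampled from five synthetic
  position weight matrices of width 33–37 bp with strongly peaked columns
  (Dirichlet(0.3) column probabilities, floored at 1e-3).  The width is that
  of a clustered binding segment rather than a single core motif: the
  element, not the isolated base, is the unit of regulatory function, and
  measured effects cluster within elements.
- **Effects**: the latent effect of a substitution is
  `effect_scale * ΔPWMscore` at an overlapping element (0 elsewhere) plus
  `Normal(0, noise_sd)` noise (`noise_sd` = 1).  A two-sided P-value of the
  effect is taken against a conservative null `Normal(0, 5 * noise_sd)`;
  confidence = min(-log10 P, 5) / 5.  The inflated null keeps pure-noise
  positions essentially always below the 0.1 threshold, mirroring pipelines
  that call significance conservatively; without it ~32% of null positions
  would cross the threshold, which would contradict both the 2:7 class
  balance and the spatial clustering of regulatory calls.
- **Class balance**: `effect_scale` is solved by bisection at generation
  time so the pooled regulatory fraction (confidence >= 0.1) hits 2/9
  (+-0.03), the approximate regulatory:neutral balance of the emulated
  assay.  Bisection is deterministic given the seed and is preferred over
  rejection sampling.
- **Informative tracks** (4 by default): the planted-element 0/1 indicator
  smoothed with a Gaussian kernel of width 80 bp (peak-normalised) —
  extended-read coverage and window-based signals are much smoother than
  base resolution — scaled by a per-(track, locus) relevance amplitude
  drawn from U(0, 1), plus smoothed unit-sd noise scaled by 0.5.  The
  relevance amplitude emulates assays from many cell types: any given track
  is informative for some reporters and nearly irrelevant for others, which
  is what makes holding out a reporter genuinely costly, while the local
  autocorrelation that carries leakage is unaffected.  (A sharper kernel
  can be configured; the identity-kernel limit reproduces the exact 0/1
  indicator and is covered by a test.)
- **Alien tracks** (8 by default): the identical smoothed-noise process
  (kernel width 80 bp — emulating window-based deep-network features, which
  are much smoother than base-resolution tracks) on a separate coordinate
  system of 21001 bp, with no element term.  Features are looked up at
  `(reporter_start + position) mod 21001`; the region is sized so exactly
  one reporter wraps around (the analogue of a reporter lying beyond the
  alien chromosome) while every wrapped interval stays hundreds of bp away
  from all other reporters' intervals.  That distance matters: if wrapped
  intervals came within the autocorrelation width of another reporter's
  interval, nominally independent features would correlate across reporters
  and contaminate the leak-free holdout reference.
- **RNG discipline**: one stream per reporter (and per track) derived from
  the master seed by a counter, so enlarging the dataset never perturbs
  earlier reporters; identical (config, seed) regenerates byte-identical
  files.

What the generator deliberately does *not* model: raw read counts and
barcodes, cell-type-specific trans-factor biology, sequence-dependent
assay artefacts, and any fitting of the synthetic marginals to a real
dataset.  Passing tests therefore demonstrate properties of the *pipeline*
(layout leakage, metric correctness) under controlled conditions, not
predictive accuracy on real MPRA data.

## Layouts

All layouts label reporter *positions* and lift labels to the three SNVs per
position, so alleles of one position never straddle the split.

- **zebra** (the emulated challenge layout): training blocks of 16 bp with
  spacers of `round(16 * (1-f)/f)` bp (48 bp at f = 0.25, making the 25/75
  ratio exact); phase 0; a trailing partial period goes to validation.  The
  spacer rule and phase are this package's reconstruction — the original
  layout's spacers are not published.
- **single_block**: one contiguous block of `round(f*L)` bp at
  `round(shift*L)`; round-half-even throughout.
- **random_blocks**: `k = round(f*L/b)` non-overlapping blocks placed
  uniformly over all feasible placements via the combinatorial gap
  bijection (exact uniformity, no rejection loops).
- **reporter_holdout / grouped_holdout**: the target reporter is entirely
  validation; other reporters contribute their zebra training blocks, or
  all their SNVs under complete training.  Grouped holdout additionally
  excludes every reporter sharing the target's sequence — necessary for the
  duplicated reporter, whose twin would otherwise compensate for the holdout
  with identical features and correlated labels.

Holdout-family models are always *scored* on the target's zebra-validation
SNVs so deltas against the baseline compare identical evaluation sets.

## Features

- **Motif features** (2 per matrix): -log10 of the best-hit P-value
  overlapping the substituted base (reference allele), and
  log10(P_alt/P_ref) (> 0 when the substitution weakens binding).  Both
  strands are scanned by default.  Score-to-P-value conversion uses an exact
  dynamic program over the background word distribution after rounding the
  weights to integer multiples of a grid step (default: score range / 1000).
  Scoring uses the same rounded matrix, so table lookups are exact for the
  rounded matrix and within one grid bin of the float score; the dynamic
  program is verified against exhaustive word enumeration in the tests.
  Dinucleotide matrices use a 4-state DP over the previous letter with an
  i.i.d. uniform letter background.
- **Track features** (2 per track): the per-base value min-max-scaled
  separately per reporter (a degenerate constant track maps to 0, not NaN),
  plus the unscaled per-reporter mean as a constant column.  Uncovered
  positions contribute 0 after a logged warning.
- **Alien features**: track features computed at the wrapped alien
  coordinates; columns carry provenance tag `alien`.  A shuffling ablation
  permutes per-position alien values within each reporter, destroying local
  autocorrelation while preserving each reporter's value distribution.

## Models and metrics

The predictor is scikit-learn's random forest with 500 trees and library
defaults, no hyperparameter search — deliberately plain, because the object
of study is the layout.  Confidence is a regression task (predictions
clipped to [0, 1]); direction is a 3-class task whose score is the expected
class value Σ k·P(k).  Direction correlations are computed against that
expected value by default (the encoding of 3-class predictions for
correlation is not standardised; hard labels are available too).

Metrics per reporter and pooled: MAE_c, MSE_c, signed ME_c, PCC_c, SCC_c on
confidence; PCC_d, SCC_d on direction; and the primary ranking pair on the
regulatory-vs-neutral binarisation (|direction|, equivalently confidence >=
0.1), using predicted confidence as the threshold-free score:

- **AUCROC** from average ranks (Mann–Whitney; ties count 0.5);
- **AUPRC** as average precision with tied scores processed as one block —
  step interpolation, never trapezoidal, which is known to overestimate.

Correlations of constant vectors are reported as missing (NaN), never 0.
Reporters whose validation set has a single class get NaN ranking metrics
and a `single_class` flag; fewer than 20 positive validation SNVs raises a
`low_support` flag.

## Experiments and problem sizes

Every experiment family shares one pipeline (generate → features → layout →
train regressor on training rows → score validation rows) and varies one
element.  Desk-scale problem sizes, chosen once and used by both the test
suite and `scripts/acceptance.py`:

- irrelevant-feature control: 10 seeds; per seed one zebra fit, three
  grouped-holdout fits with rotating targets (pooled held-out predictions),
  and one within-reporter-shuffled fit;
- holdout sweep: one seed, all 15 reporters × {zebra-minus-target,
  complete-minus-target} plus grouped holdout for the duplicated pair;
- block-length sweep: one seed, lengths {1, 2, 4, 8, 16, 32, 64} × 10
  random layouts each;
- shift sweep: one seed, shifts {0, 0.25, 0.5, 0.75};
- experiment-level forests use 200 trees (the metric rankings are
  insensitive to tree count well below the 500-tree library default, which
  remains the `ModelSpec` default).

Aggregation is means (with sd) over seeds/samples; no significance testing
is attached.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; SNV positions are offsets
  within the reporter.
- PWM pseudocounts when reading count matrices: 0.25 per cell (mono),
  0.0625 (di), against a uniform background.
- Confidence values outside [0, 1] in input files are rejected, not
  clipped.
- Round-half-even for every fraction-to-position conversion.
- Ties among equally best motif windows are resolved by the shared minimum
  P-value (the value, not the window, is reported).
- The leak-free holdout reference in the irrelevant-feature control uses
  grouped-holdout semantics (see Layouts) — with a duplicated reporter in
  the dataset, plain single-copy holdout is not leak-free by construction.
- The rotating-target pooling in the irrelevant-feature control (3 targets
  per seed, advancing across seeds) trades the full leave-one-out sweep for
  a tractable estimate whose pooled variance is dominated by the number of
  distinct element clusters evaluated, not by the number of fits.

## Known limitations

- Planted elements have sharp edges and uniform within-element effect
  scale; real effect profiles taper.  Position-interpolating leakage is
  therefore bounded more tightly here than in real data with smooth effect
  profiles.
- Alien-feature leakage depends on the ratio of feature autocorrelation
  width to the zebra spacer; the 80 bp default emulates window-based
  features.  Sharper alien features leak less.
- Per-reporter ranking metrics rest on ~3 element clusters per reporter and
  are accordingly noisy; pooled metrics are the stable quantities.
- The external-validation path evaluates on freshly generated synthetic
  reporters; it demonstrates the protocol, not transfer to any real assay.
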