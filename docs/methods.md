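# Methods

## The screen model

The pipeline analyses an ORF-overexpression screen: a genes × samples
expression matrix in which each ORF condition was profiled in replicate
(three infections per ORF is the design default), conditions were processed
in batches, and every batch contains empty-vector control samples. The
statistic treats the whole screen as its own reference: instead of testing
each ORF against controls alone, every gene's **baseline** is the median of
its merged log2 expression across *all* conditions (the pooled controls
contributing one condition). This makes the baseline robust to any single
ORF's perturbation — a gene strongly induced by one ORF out of a dozen
keeps a baseline set by the unperturbed majority — and the per-ORF
**effect** `x = profile − baseline` is a log2 fold-induction against that
consensus. The fold-change equivalent is `FC = 2^x`.

The decision rule is deliberately threshold-based rather than test-based:
with ~3 replicates per condition, per-gene error models are weakly
identified, so the screen instead asks whether an effect is large (`fold >
2`) *and* sits outside the gene's empirical **expected range of variation**
across the entire dataset. That range is summarised per gene by a robust
scale `s_g` — the median absolute deviation of the gene's effects across
all conditions times 1.4826 (the consistency constant for the normal
distribution) — giving `Z = x / s_g`. MAD is used precisely because the
very hits being sought are outliers in the effect vector; a standard
deviation would be inflated by them (an `sd` estimator mode exists for
comparison). Scales are floored at 0.25 × the median scale over detected
genes, so a gene that happens to be constant across conditions cannot
produce an infinite Z; the floor is configurable, and for degenerate
all-constant inputs an explicit floor must be supplied.

Classification: genes whose baseline falls below the detection floor
(log2 value 3, mirroring the expression pre-filter used to select
detectable genes) are `below_detection` and never called; otherwise
`|Z| ≤ 2` is `within`, `2 < |Z| ≤ 4` `suggestive`, `|Z| > 4` `outside`.
Hit tiers combine both criteria: `hit` = detected ∧ `|x| > log2(2)` ∧
`outside`; `suggestive` analogously with the middle band. Boundary values
stay in the lower class, and detection is assessed on the baseline, not on
per-condition expression, so a gene cannot drift in and out of the universe
across conditions.

Design choices that were genuinely open, and how they were fixed:

- **Normalization**: counts input is scaled to counts-per-million per
  column and transformed as `log2(cpm + 1)` — the simplest defensible
  default, pseudocount configurable; pre-normalized log2 input passes
  through untouched. Quantile normalization is deliberately not assumed.
- **Batch merging**: every batch carries the empty-vector control, so
  batches are anchored per gene by subtracting (batch control mean − global
  control mean). This equalises control means across batches exactly,
  preserves all within-batch contrasts, and is idempotent (to float
  rounding). No model-based batch correction is attempted.
- **Replicate merging**: unweighted arithmetic mean on the log2 scale,
  i.e. the geometric mean of fold-changes.
- **Variance source**: condition-level (merged) effects by default;
  replicate-level effects are available via
  `ScreenConfig(replicate_level_variance=True)` since "variance across all
  samples" is ambiguous between the two readings. Condition-level was
  chosen because the hit criterion itself operates on merged effects.
- **Hit threshold**: `|Z| > 4` defines the hit tier (with `|Z| > 2`
  reported as suggestive); both are exposed because the outside-expected-
  range criterion could defensibly sit at either bound.
- **Median with even counts**: mean of the middle two; ordering ties in
  hit-count tables break alphabetically.

## Concordance and overlap

Replicate-set concordance splits one condition's replicates into two
halves, merges each half separately, computes each half's effects against
the full-screen baseline, and reports Pearson r over detected genes
(Spearman optional). Shared-hit structure between ORF pairs is quantified
by overlap of hit sets — sign-aware by default, so a gene must move the
same direction in both ORFs — with an exact upper-tail hypergeometric
p-value P(X ≥ k) on the universe of *detected* genes (only a detectable
gene can ever be a hit). The significance test is this package's own
addition to the overlap analysis, and outputs label it as such implicitly
by construction; it is not a literature procedure being reproduced. The
same test scores hit sets against user-supplied GMT gene sets with
Benjamini–Hochberg adjustment across sets. The promoter/factor utility is
pure interval logic on BED records (0-based, half-open; strand ignored;
promoter windows must be pre-computed): a factor qualifies when at least
one of its peaks overlaps every promoter in the query.

## The synthetic screen

The generator emulates the study design, not sequencing: per-gene log2
baselines ~ N(6, 2²) (a realistic bulk log2-intensity spread), a
`frac_undetectable = 0.1` subset pinned one log2 unit below the detection
floor, per-gene-per-batch additive shifts ~ N(0, 0.3²) shared by all
samples of a batch (emulating infection-date/extraction/array batch
variation), additive Gaussian per-sample noise on the log2 scale
(SD 0.25 by default), and planted per-ORF effects: 50 genes per ORF drawn
from the detectable pool, |log2 effect| uniform on [1.5, 3], sign
Bernoulli(1/2). ORFs are assigned round-robin to three batches, three
replicates per ORF and three controls per batch. Defaults are the
conditions under which the pipeline's recovery behaviour is validated
(10 ORFs × 5,000 genes); the full published-scale design (~42 ORFs in
three batches of ~15) is one config change away. An optional counts mode
exponentiates the log2 signal, applies per-sample library-size factors
(gamma, CV 0.1) and draws negative-binomial counts via a gamma-Poisson
mixture whose mixing CV reuses `noise_sd` as the dispersion knob.

What the simulator does *not* model: count-level mean–variance coupling in
log2 mode, correlated gene modules, ORF integration effects, partial
transduction, or platform-specific probe effects. Passing recovery tests
therefore demonstrates that the statistic does what it claims under its
own assumptions (additive log2 noise, batch shifts removable by control
anchoring), not that any particular biological screen will reach the same
sensitivity.

Planted effects start at |x| = 1.5 rather than at the fold threshold of 1
so that recovery failures reflect the variance model, not borderline
rounding; a sub-threshold `effect_low < 1` is allowed (with a warning) for
power studies.

## Numerical notes and validation scale

- The MAD constant is the literal 1.4826; medians over even counts are the
  mean of the middle two values. These choices are mirrored bit-for-bit by
  a pure-Python brute-force oracle in the test suite, which the vectorized
  pipeline must match *exactly* (no tolerance) on random small screens.
- Anchoring idempotence and control-mean equality hold to float rounding
  (asserted at 1e-9–1e-10); effect/fold duality `2^x · 2^−x = 1` at 1e-12.
- Hypergeometric tails are checked against exact integer enumeration
  (`math.comb`) over all k for universes up to N = 60, at 1e-12.
- Interval intersection is checked against an all-pairs quadratic oracle.
- Validation problem sizes: null calibration and recovery run at the
  default 5,000 genes × 39 samples (10 ORFs × 3 replicates + 9 controls),
  20 null screens and one planted screen; concordance at 3,000 genes with
  6 replicates split 3 + 3. These sizes make the full suite run in seconds
  while leaving hit-count statistics stable across seeds.

## Known limitations

- The universe for overlap statistics is the detected-gene set of the
  screen at hand; cross-screen comparisons need a common universe supplied
  by the caller.
- The hypergeometric overlap test assumes exchangeable genes; co-regulated
  modules violate that and inflate significance, so p-values are best read
  as ranking scores.
- Batch anchoring assumes batch effects are additive per gene on the log2
  scale and shared by all samples of a batch; sample-specific technical
  drift is not corrected.
- `score_recovery` matches on (gene, condition, sign) triples only; effect
  magnitudes are not compared.
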