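# Methods

This note documents the models, conventions, and numerical choices behind
each stage of the pipeline, what the synthetic generator does and does not
emulate, and the known limitations.

## Stimulus schedules and response windows

Both imaging protocols last 65 s at 3 frames/s (195 frames; frame count is
`round(65 × frame_rate)` for other rates). The tonic protocol is
5 s horizontal baseline (0°), 15 s nose-down (−19°), 15 s horizontal,
15 s nose-up (+19°), 15 s horizontal. The impulse protocol is 20 s baseline,
a 10 ms impulse, 30 s horizontal, a second 10 ms impulse, ~15 s horizontal
(the tail is trimmed by the two impulse durations so the total stays 65 s).

Because imaging happens only at horizontal, responses are read out in the
**first second of restoration to horizontal**. "One second" is
`ceil(frame_rate)` frames starting at the frame nearest the restoration
time, so at 3 frames/s it is exactly 3 frames. The 10 ms impulses are much
shorter than the 333 ms frame period; the response window therefore starts
at the frame nearest the impulse onset (frames 60 and 150 at 3 frames/s).

## ΔFF scoring

- ΔFF = (mean F in the response window − baseline mean) / baseline mean.
  This is the standard ΔF/F convention and matches the reported unit scale
  (tilt responses of order 1–2).
- Baselines: the initial 5-s window for the nose-down response; the last 3 s
  of the horizontal segment following the nose-down tilt for the nose-up
  response; the full 20-s pre-impulse window for both impulses.
- Significance: ΔFF > 2 × SD(baseline), with the baseline SD expressed in
  ΔFF units (per-frame baseline samples ΔFF-transformed against their own
  mean) so the criterion is unit-consistent. Traces are divided by ROI area
  (μm²) first; because both the response and the baseline scale together,
  significance calls are invariant to ROI size (property-tested).
- Tuning index: (up − down)/(up + down) after clamping each ΔFF below at
  zero, keeping the index in [−1, 1]. How suppression (negative ΔFF) should
  enter the index is not specified by the source analysis; clamping is the
  choice here and is documented in the score output. When both clamped
  inputs are zero the index is undefined and carried as NaN; such neurons
  are untuned.
- Classification: nose-up requires index ≥ +0.1 **and** a significant
  nose-up response; nose-down symmetrically; everything else is untuned.
  Whether the untuned class additionally requires a significant response in
  at least one direction is unstated in the source analysis; here
  significance is required only in the preferred direction for a
  directional label, so neurons significant in neither direction are always
  untuned.
- Repeats: the three stimulus repeats are aggregated by the mean of the
  per-repeat ΔFF values, the significance threshold re-evaluated against
  the mean baseline SD, and the index and label recomputed. Aggregation by
  mean is a design choice (the source is silent); a Monte-Carlo test
  verifies it never increases classification error relative to single
  repeats.
- Impulse selectivity pairs impulse 1 as the numerator-positive direction;
  the pairing is arbitrary and documented here (both impulses receive equal
  amplitudes in the generator's default, matching the near-zero impulse
  selectivity of the emulated data).

## Synthetic data generator

The generator is the test bed for every stage; it is a pure function of
(seed, config) and its defaults describe one genotype arm of the emulated
study: 16 fish × 19 neurons (≈300 neurons, matching the ~300-neuron null
cohort), subtype mixture 47% nose-up / 46% nose-down / 7% untuned, three
repeats, 3 frames/s.

- **Fluorescence**: F(t) = roi × [B·(1 + A·k(t)) + ε(t)] with baseline
  B = 100 a.u., a unit-peak single-exponential kernel k (τ = 1.8 s,
  GCaMP6s-like — the source does not model indicator kinetics; τ is chosen
  so the 1-s read-out window captures near-peak signal), response amplitude
  A in ΔFF units, and Gaussian noise ε. ROI area acts multiplicatively so
  the scoring module's normalization is exercised. Noise-free null
  configurations reduce to F = B × roi exactly (tested closed form).
- Defaults A = 1.5 ΔFF for tilts and 0.35 for impulses (the reported
  response scales), noise SD 5 a.u. (0.05 ΔFF) — a realistic somatic
  GCaMP6s noise level at which the 2-SD criterion behaves as in the real
  data. Trace noise magnitudes are not stated by the source; these defaults
  are configurable and are not claims about the real recordings.
- Untuned neurons carry **equal transients in both windows**, so they are
  responsive but non-selective and genuinely exercise the |index| < 0.1
  rule (rather than failing significance trivially).
- **Somata**: nose-up somata are uniform over a dorsal band, nose-down over
  a ventral band, overlapping by `dv_overlap` (default 8 μm of a 40 μm
  dorsoventral extent; 0 makes the supports disjoint). Mediolateral and
  rostrocaudal coordinates are uniform and non-topographic. Eight equal
  dorsoventral sections supply the ground-truth section index.
- **Counts**: per-gene means log-uniform on [20, 500]; per-gene NB
  dispersion log-normal around 0.05 (σ = 0.3, settable to 0) — drawn rather
  than fixed so dispersion estimation is exercised without an external
  dataset. A planted fraction of genes (default 5%) carries a true
  |log₂FC| = 4 split symmetrically about the base mean, half up, half down.
- **Atlas**: Bernoulli detection per cell with per-gene rates drawn
  Beta(0.3, 1.5) (most genes lowly detected, a long right tail — the shape
  of real single-cell detection); 1,468 cells of which 32% form the
  labelled projection cluster, the reported atlas geometry. Planted genes'
  rates can be pinned (`planted_detection_rate`) to test the
  detection-filter/DE interaction.

What the generator does **not** emulate: image formation, ROI segmentation
and neuropil contamination, slow drift or motion artifacts, correlated
noise across neurons, fish-level batch effects, library-size artifacts
beyond a global size factor, and dropout structure tied to expression
level. Passing tests therefore demonstrate correctness of the analysis
logic under the stated model, not robustness to those real-data features.

## Topography statistics

- Coordinate standardization subtracts the origin landmark; when no
  landmark is given, the per-axis minimum corner of the data is used, which
  makes standardization exactly translation-invariant.
- Dorsoventral sections use half-open bins [bᵢ, bᵢ₊₁); a depth exactly on
  an internal boundary goes to the deeper section. The source used
  anatomical landmarks for its eight sections, which are unrecoverable
  here; equal-width boundaries are the default.
- Bootstrap densities resample n values with replacement per iteration
  (default 100 iterations), histogram them on 20 equal-width bins over the
  observed (or supplied) range, and report per-bin mean and SD. A numerical
  guard zeroes the SD where all iterations are bitwise identical, since
  pairwise-summation rounding can otherwise report ~1e-14 spread on
  constant input.
- MANOVA uses Wilks' Λ with its F approximation (Pillai's trace by option);
  the source names only "multivariate analysis of variance". Zero
  between-group scatter returns Λ = 1, p = 1 exactly. Null calibration is
  simulation-tested (KS of 200 null p-values against uniform).
- Rank-sum count comparisons are exact by full enumeration of rank
  assignments (midranks, so ties are exact) when both groups have ≤ 10
  fish, and fall back to the tie-corrected normal approximation otherwise.
- Median shifts ≤ 2 μm between groups are flagged as within registration
  error in reports, not suppressed.
- Per-axis orientation signs and density binning are config with the
  defaults above; the source does not state them.

## NB Wald differential expression

The DE test is written for this package as a transparent stand-in for
shrinkage-based fitters (the source analysis used such a fitter); its
p-values are internally calibrated but are not comparable to any external
tool's, and nothing in the acceptance checks compares them to reported
p-values.

- Size factors: median-of-ratios over genes positive in all samples.
- log₂FC: log₂((m̄_null + 0.5)/(m̄_sibling + 0.5)) on normalized counts;
  the 0.5 pseudocount stabilizes zero-mean genes.
- Dispersion: per-gene method of moments on the pooled within-group
  variance, floored at 1e-8, then **floored at a fitted trend**
  α(μ) = a₀ + a₁/μ (least squares across genes). With 3 vs 3 replicates the
  gene-wise estimate is very noisy and underestimates inflate the Wald
  statistic badly (empirical type-I ≈ 0.11 with raw gene-wise estimates);
  taking the max of gene-wise and trend protects against underestimation
  and yields a slightly conservative, calibrated test (type-I ≈ 0.035–0.05
  in the packaged null simulation at 2,000 genes).
- Wald statistic: log₂FC / SE with SE from the delta method,
  Var(m̄) = Σⱼ(μ/sⱼ + αμ²)/n², two-sided normal p. All-zero genes are
  flagged and excluded (NaN p).
- BH adjustment implements the step-up directly with an explicit universe
  size m, so the per-threshold reanalysis can re-adjust on each filtered
  universe; it is cross-checked against statsmodels.
- The filter ladder re-runs the **full test** on each filtered universe by
  default (re-estimating size factors and dispersions), because the
  per-threshold analyses are separate analyses; `full_retest=False` only
  re-adjusts stored raw p-values. Whether the source re-estimated or only
  re-adjusted is unstated; both are exposed.
- Genes absent from the atlas get detection 0 (excluded at any positive
  threshold) and are counted in the table's metadata. Detection is
  "count > 0 in a cell", the common single-cell convention; the source does
  not define it.
- A variance-based QC flag for outlier sequencing repeats is deliberately
  not given a numeric cutoff; the exclusion rule in the emulated study was
  qualitative (principal-component variance), so the config only requires
  ≥ 2 samples per condition.

## Group statistics

One-way ANOVA with Tukey-HSD pairwise comparisons by default; the source
says only "multiple comparisons", so Tukey is the documented choice and
Bonferroni-corrected Welch t-tests are available by option. Cohen's d uses
the pooled-SD denominator. Fish-level nesting is not modelled (neurons are
pooled within genotype, as in the emulated analysis).

## Determinism and problem sizes

Every stochastic stage takes an explicit seed; generator streams are
derived per stage from CRC-keyed `SeedSequence` spawns so stages are
independently reproducible, and the pipeline summary is rounded to six
decimals and serialized with sorted keys so identical config + seed gives a
byte-identical JSON file. Simulation sizes used in the tests and the
acceptance script (600 neurons for subtype recovery, 500 for impulse
recovery, 2,000 genes for DE calibration, 50 datasets × 200 genes for the
filter ladder, 100 bootstrap iterations) were chosen to make the Monte-Carlo
bounds sharp while keeping any run to seconds.

## Known limitations

- The NB test's normal-reference Wald p-values lean on the trend floor for
  calibration at n = 3 + 3; with many fewer genes the trend fit itself is
  noisy.
- The impulse tuning pairing (impulse 1 minus impulse 2) is a convention;
  reversing it flips the sign of the impulse index only.
- Equal-width dorsoventral sections approximate a landmark-based anatomical
  subdivision.
- The generator's subtype and detection models are deliberately simple;
  see the emulation caveats above for what passing tests do not show.
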