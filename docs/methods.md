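# Methods

## The matching model

A *feature* is the elution peak of one charge variant of a peptide inside an
extracted-ion chromatogram (XIC). Given a source run Q1 where a peptide's
identity and retention time are known, and a target run Q2 where they are not,
the matcher scores every detected candidate interval in the Q2 XIC with

    P(y) = P(AT) · P(AR)

and reports the argmax. The two statistics, and the assumptions behind them:

* **AT** — residual elution-time shift after warp correction,
  `t_apex(Q2) − w(t_apex(Q1))`, where `w` is a polynomial fitted by least
  squares to the identified time pairs of the training set. Assumption:
  once the smooth (mean) inter-run shift is removed, the remaining shift of a
  true corresponding pair is Gaussian, `AT ~ N(μ, σ²)`, with parameters
  estimated as the sample mean and the unbiased (n−1) standard deviation.
* **AR** — alignment R². Each peak trace is linearly interpolated onto
  `ar_grid_points` (default 50) equally spaced points spanning its own
  detected interval, and the Q2 vector is regressed on the Q1 vector with an
  intercept; AR is the resulting R², clamped to [0, 1]. Resampling boundary
  to boundary makes the statistic a *pure shape* comparison: it is invariant
  to time position (decoupling it from AT) and to any positive affine
  transform of intensity, so concentration fold changes do not degrade it.
  Assumption: for true corresponding pairs X = 1 − AR is small with a right
  tail, modelled as `X ~ Gamma(k, θ)` and fitted by maximum likelihood
  (location fixed at 0). X is clamped below at `x_floor` (default 1e-6)
  because perfectly correlated synthetic pairs would otherwise drive the MLE
  to a degenerate spike at 0.
* Independence: AT is driven by run-to-run chromatographic variation, AR by
  the peptide's physicochemistry; the likelihood multiplies the two densities
  with no candidate-level normalisation. Scores are densities, not
  probabilities — only their ordering across candidates matters.

Degenerate training samples are possible in noiseless simulations: identical
residual shifts raise a `DegenerateModelError`, which the pipeline converts to
a tiny-sigma Gaussian (1e-6 s) so the argmax remains well defined; an
all-identical shape sample disables the AR factor (constant 1), logged, and
the score reduces to the AT density.

## Pre-processing

XICs are computed at the monoisotopic and first-isotope m/z (spacing
1.0033548/z) with a ±10 ppm window (config `ppm_window`), summing all
centroids inside the window per MS1 scan. Detection runs on the
first-isotope trace by default (`detection_trace`; the mono trace is more
prone to −1 Da co-eluting interference), configurable to `mono` or `sum`.

Noise is estimated per XIC as `level = median(intensity)` and
`sigma = c · median(|intensity − level| over points ≤ the 90th percentile)`.
Excluding the top decile keeps the elution peaks themselves from inflating
the estimate; the constant `c = 1/Φ⁻¹(0.725) ≈ 1.673` makes the estimator
consistent for Gaussian noise *under that truncation* (the familiar 1.4826
constant assumes the median is taken over the full sample and would read ~11%
low here).

Candidate intervals are maximal runs of consecutive points strictly above
`level + 3·sigma`; runs shorter than `min_peak_points` (default 3 scans) are
dropped as spikes, and if more than `max_candidates` (default 20) remain the
highest-apex ones are kept. In the source run, the peptide's own interval is
the one containing its recorded retention time, falling back to the nearest
apex within `rt_tolerance_sec` (default 60 s); peptides with no such interval
are excluded from training and testing with a logged warning. In the target
run every detected interval is a candidate.

## Ground truth, training and evaluation

Identifications are deduplicated per (sequence, charge) — the highest
probability wins, ties to the earlier retention time — filtered at
`prob_threshold` (default 0.95), and intersected across the two runs.
Features with the top `train_fraction` (default 20%) Q1 apex intensities form
the training set (brighter features are least noise-corrupted); the remainder
is the testing set. Ties are broken lexicographically so splits are
reproducible. Non-corresponding (decoy) training pairs replace the true
target interval with a uniformly random other interval of the same XIC,
drawn from a seeded generator.

A prediction is correct iff the chosen target interval contains the recorded
target-run retention time; unmatched peptides (no candidates) count as
errors, keeping the denominator equal to the full testing set. ROC curves for
the AT density, the AR density and their product are computed by threshold
sweep over pooled corresponding/decoy scores (trapezoidal AUC); the density
value is the natural likelihood-analogue ranking for the single-statistic
curves.

## Multi-run propagation

For ≥3 runs, models are trained once per unordered run pair on *all* of the
pair's common identifications (no held-out split — nothing is evaluated
inside propagation, and small studies would otherwise starve the fit;
direction-specific warps and AT models are fitted deterministically from the
shared list, the AR model being symmetric). Every union peptide lacking an
interval in some run is matched from the run with its most confident
identity, native identities preferred over propagated intervals, iterating to
a fixpoint; conflicts resolve by that same preference order and are logged.
Pairs with fewer common identifications than `min_training_size` are skipped
and reported. The coverage report exposes both denominators — the
union-minus-intersection set (peptides not already complete from Tandem MS
alone) and the full union — plus partial (≥2 runs but not all) counts.

## The synthetic study

The generator produces the statistical regime the matcher assumes, with every
quantity known:

* each peptide owns a pair of mass channels on a grid spaced ≥2.2 Th so ppm
  windows never overlap (the high-resolution assumption);
* a per-peptide *shape fingerprint*: an exponentially modified Gaussian
  (width 0.9–1.5 s, tail 0.2–0.6 s) plus a shoulder component at a fixed
  relative offset — reproduced across runs up to `shape_noise` (5% relative
  on width/tail/shoulder plus 5% multiplicative point noise), which is what
  makes AR informative. `shape_reproducible=False` redraws shapes per run;
* per-run true warps (identity, plus mild monotone quadratics), residual
  jitter `N(0, at_sigma²)` per run (default 9 s, so a run pair shows ~12.7 s
  of residual spread), intensity fold changes log-uniform up to 50×;
* per peptide and run, `decoys_per_peptide` (default 2) interfering peaks
  with freshly drawn shapes at 20–26 s offsets — inside three jitter standard
  deviations, i.e. a crowded chromatogram where nearest-feature matching
  fails regularly. Offsets below ~16 s would let bright-peak tails bridge the
  detection threshold and merge intervals; the defaults keep planted peaks
  resolvable so the ground truth stays meaningful;
* baseline noise `N(30, 10²)` counts clipped at zero, per channel and scan;
* identification tables sampled at `identified_fraction` per run, recorded
  retention times jittered by 1 s, probabilities from Beta(200, 3) (mode
  ~0.99) for true identifications and Beta(4, 2) for planted false ones; a
  false identification is planted per *peptide* (a mis-assigned sequence —
  its recorded time points at a decoy peak in every run where it is emitted),
  so a rate f contaminates the two-run ground truth by f, not ~2f.

Default sizes are a desk-scale stand-in for the motivating experiments: 150
peptides over a 900 s run at 1 Hz MS1 sampling give ~135 ground-truth
peptides per pair (~27 training), and the three-run coverage study uses 90
peptides at `identified_fraction` 0.5 with `min_training_size` 15 (~20 common
identifications per pair). Around 200 common identifications are preferable
for stable models; the package logs a warning below `min_training_size`.

What passing on this generator does *not* show about real data: real XICs
contain chimeric and overlapping species within the mass window, isotope
envelopes beyond two traces, detector saturation and retention-time drift
that is not a smooth polynomial; real identification errors are not uniform
decoy swaps. The generator's peaks are also cleaner than real chromatography
at low intensity.

## Numerical and design notes

* Warp fitting uses least-squares polynomial regression (degree 3 by
  default, config `warp_degree`) of target times on source times, with
  automatic degree reduction on rank deficiency; extrapolation beyond the
  training time span is allowed and logged. A cubic fitted on ≥200 pairs at
  replicate-scale residual noise (3 s) changes by <1 s over the central 90%
  of its domain when the training set doubles; at the crowded benchmark's
  pairwise noise (~12.7 s) the edge of the domain moves by a few seconds
  between refits, which is why candidates are scored, not gated, under
  extrapolation.
* AR uses the squared-correlation identity for the simple regression R²; a
  zero-variance target vector has no defined R² and scores 0 with a warning.
* Argmax ties (exactly equal scores) break to the smaller |AT|, then the
  earlier apex; all orderings in the package (dedup, splits, TSV rows) have
  deterministic tie-breaks so byte-identical reruns are guaranteed for a
  fixed seed.
* Time-shift landmarks are apex times by default (`at_landmark`), the
  sharpest feature of a peak; interval midpoints are available for very flat
  peaks.
* The AT-only and AR-only scoring modes rank by the corresponding density
  alone; AT-only ranking is equivalent to nearest-feature matching whenever
  μ ≈ 0, which the benchmarks reproduce.
* When peak-shape reproducibility is absent the AR factor adds ranking noise
  rather than information, and time-shift-only matching is the right tool in
  that regime (small residual shifts, e.g. technical replicates) — the
  matcher exposes the per-statistic ROC curves so users can see which factors
  separate on *their* training pairs before trusting the combined score.

## Limitations

* No FDR or posterior for matches: the argmax is reported with its raw
  density score. A `min_score_quantile` rejection exists but is off by
  default.
* Overlapping-peak deconvolution is out of scope; a merged interval (two
  species above threshold with no gap) is treated as one candidate.
* Quantification (peak areas, ratios) is deliberately not computed; the
  output is the located interval per run.
* pepXML/mzIdentML parsing is not included — identification tables are plain
  TSV with sequence, charge, m/z, retention time and probability.
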