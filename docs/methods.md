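# Methods

## Problem and labels

Intrapartum cardiotocography yields a fetal heart rate (FHR) series,
here at 4 Hz in beats per minute, with the value 0 encoding missing
samples.  Umbilical-artery pH measured at birth provides the outcome
label: pH > 7.20 → Normal, pH ≤ 7.05 → Pathological, in between →
Suspicious.  The two boundary values are assigned to the more severe
class, consistent with the pipeline's pathological-first priority; this
closure is a convention, since the interval endpoints themselves are
clinically ambiguous.  The class order Normal < Suspicious <
Pathological is ordinal and is relied on by the weighted kappa and the
decision rule.

## Stage I — cleaning and segmentation

Three repair rules run in a fixed order (zeros → range → instability):

1. **Missing runs.**  Maximal runs of zeros shorter than 15 s are
   bridged linearly between the nearest *in-range* flanking samples
   (50–200 bpm); anchoring on merely non-zero flanks would let an
   adjacent spike poison the bridge.  Runs ≥ 15 s, and runs without a
   usable flank, are dropped.
2. **Out-of-range samples** (> 200 or < 50 bpm) are replaced by
   shape-preserving (monotone cubic Hermite, PCHIP) interpolation over
   the in-range samples; PCHIP values depend on two anchors per side and
   cannot leave the anchors' envelope, so repairs stay physiological.
3. **Instability.**  A sample deviating more than 25 bpm from the
   previously retained sample is flagged and bridged linearly.  After
   5 s of consecutive rejections the current sample becomes the new
   reference: a sustained level shift is real signal (a deceleration),
   not a point artifact, and without this guard a single bad reference
   cascades into hundreds of false flags.

Cleaned signals are tiled into non-overlapping 600 s windows anchored at
the *end* of each dropped-free stretch, so the latest window always ends
at the last valid sample — late-in-labor data is the most informative.
A window is valid when at most 20 % of its samples were interpolated
(the cap is configurable; no established definition exists).  Normal and
Suspicious recordings contribute only their latest valid window;
Pathological recordings contribute all valid windows, partially
offsetting the class imbalance.  Suspicious follows the Normal policy:
the one-window-per-recording reading is the only one consistent with a
114-segment Suspicious cohort.

## Stage II — the 68 features

Five families, concatenated in a fixed documented order
(8 + 4 + 7 + 36 + 13):

* **Time (8):** mean, std, median absolute deviation, summed successive
  differences (telescopes to last − first), skewness, kurtosis,
  pulse indicator (max/mean), and the total sum.  Moments of a
  zero-variance signal are defined as 0.
* **Spectral (4):** band energies of the demeaned one-sided power
  spectrum over (0, 0.03], (0.03, 0.15], (0.15, 0.5] and (0.5, 2.0] Hz —
  the conventional FHR ULF/VLF/LF/HF split; edges are configurable since
  no canonical values exist for this battery.  Half-open bands tile
  (0, Nyquist], so the four energies sum exactly to the total.
* **Autocorrelation (7):** the normalized autocorrelation at lags 1–240
  (one minute at 4 Hz); features are the count of interior strict local
  extrema plus the sum/median/standard deviation of the local maxima and
  of the local minima (empty families → 0).  The extrema are of the
  autocorrelation function, not the raw signal: a quasi-periodic trace
  (cyclic decelerations) produces acf ripples whose geometry these
  statistics summarize.
* **EMG-inspired (36):** the standard surface-EMG toolbox battery
  (integrated amplitude, waveform length, zero crossings, slope-sign
  changes, Willison amplitude, Teager–Kaiser energy, cardinality, v-order,
  fractal length, an order-4 Yule–Walker AR first coefficient, ...).  Of
  the 40 toolbox names, the four plain duplicates of time-domain moments
  (skew, kurt, sd, var) are excluded; `mad.1` (mean absolute deviation),
  `iqr`, `cov` and `ae` are kept, giving 36.  Crossing-type features with
  a deadband (zc, fzc, ssc, wa, myop) operate on the mean-removed signal —
  a strictly positive bpm series never crosses zero — with deadband
  0.01 × std; amplitude-type features (iemg, mav, ssi, ae, ld, ...) use
  the raw values.  Both choices make the shape features invariant under a
  constant bpm offset.  Cardinality counts distinct values after rounding
  to 3 decimals (bpm data are quantized anyway).
* **Morphological (13):** events are detected against an estimated
  baseline: accelerations are excursions > +15 bpm and decelerations
  < −15 bpm sustained ≥ 15 s; decelerations ≥ 180 s are prolonged.  The
  deviation series is smoothed with a 2 s moving average before
  thresholding so short-term variability cannot split one sustained
  excursion into sub-threshold fragments.  Features: counts of
  accelerations, decelerations and prolonged decelerations; mean
  amplitudes (peak deviation) and durations per type; IQR, skewness and
  variance of deceleration durations; mean within-deceleration
  cardinality; the standard deviation across deceleration events of the
  per-event kurtosis; and the fraction of time spent in deceleration.
  Statistics over empty event sets are 0.

### Baseline estimation

The baseline is the slowly varying reference rate during stable periods.
It is estimated by iterative trimmed smoothing: the initial estimate is
a centered 3-minute moving **median** (robust against events, which
occupy well under half of such a window); then, repeatedly, samples
deviating more than 15 bpm from the current baseline are replaced *by
the current baseline value* and the result re-smoothed with a 1-minute
moving average, until the maximum change falls below 0.5 bpm or 10
iterations.  Replacing trimmed samples with the baseline, rather than
bridging between the excursion's shoulders, matters: shoulder bridging
let long decelerations drag the estimate several bpm downward, hiding
the very events the baseline exists to reveal.  The output is clipped to
50–200 bpm.  All constants are configuration keys; this estimator is a
self-contained design, not a reimplementation of any external tool.

## Stage III/IV — resampling and the two forests

Stratified 3-fold cross-validation preserves per-class proportions
(502 segments at 351/114/37 give test supports (117, 38, 13),
(117, 38, 12), (117, 38, 12)).  Training folds only are randomly
undersampled: every class down to the minority count, uniformly without
replacement — duplicates would carry no information to a tree learner.

Both ensembles grow 25 depth-10 CART trees (Gini) on independent
bootstrap resamples whose index multisets are recorded; tree induction
is delegated to scikit-learn's `DecisionTreeClassifier` and the fitted
trees immediately converted to a plain array form on which all
traversals and the JSON serialization operate.  Reproducibility is
guaranteed by seeding; split tie-breaking follows the library's seeded
splitter rather than a bespoke rule.

The **probabilistic** mode models feature-value uncertainty:

* each tree's bootstrap is augmented with 10 % jittered copies of its
  own rows, noise scaled per feature by the training median absolute
  deviation (MAD);
* at prediction time a sample follows *both* children of each split with
  branch probabilities `logistic((threshold − x)/s)`, `s = softness ×
  MAD_feature` (softness 0.3); paths whose cumulative probability falls
  below the `keep_proba` floor (default 0.05) are pruned and surviving
  mass renormalized.  If pruning kills every path the sample falls back
  to the hard traversal.

With `keep_proba = 1`, zero softness and no augmentation the soft
traversal reduces exactly, tree for tree, to the deterministic forest —
a property the test suite asserts.  `keep_proba` and the augmentation
fraction are interpreted as a pruning floor and a per-tree fraction
respectively; both semantics are configuration-driven conventions.
Label-noise softness is not modeled.

**Out-of-bag capture:** each training sample is scored by averaging
exactly the trees whose bootstrap omitted it (expected omission fraction
(1 − 1/n)^n → e⁻¹ ≈ 0.368).  Samples no tree omitted are flagged
uncovered and excluded from threshold tuning, never imputed.

## Stage V — fusion and threshold moving

Test and OOB probabilities fuse as `w·P_RF + (1−w)·P_PRF` with w = 0.5
(equal weighting; the weight is a config key).  The decision rule:
Normal iff Normal holds the strict maximum (Normal-vs-rest ties resolve
away from Normal); otherwise Suspicious iff `P(S) − P(P) > λ`, else
Pathological.  λ = 0 reproduces argmax exactly, and the Pathological
prediction set grows monotonically with λ while Normal decisions are
λ-invariant — so raising λ can only convert Suspicious predictions into
Pathological ones.

λ is tuned per fold on the fused OOB probabilities of that fold's
(undersampled) training set, over the grid 0.00–0.44 in steps of 0.04
(a 0.02 step is selectable), maximizing
`f_score = κ_linear + precision(Pathological)` — an equally weighted sum
of a chance-corrected ordinal agreement term and a term rewarding
trustworthy Pathological calls; precision is 0 when no Pathological
predictions exist, so `f_score ≤ 2` with equality only for perfect
predictions.  Ties break toward the largest λ, the most
pathological-favoring setting among equals.

## Evaluation artifacts

Confusion matrices use rows = predicted, columns = true (the orientation
is an explicit field).  Reports show half-up 2-decimal rounding while
retaining full precision internally; zero denominators yield 0 so
degenerate classifiers still produce finite reports.  Cohen's kappa
supports none/linear/quadratic weights.  Method comparison uses the
Friedman rank test with the Iman–Davenport F correction: per-fold ranks
(best = 1, mean ranks for ties), `χ²_F = 12/(nk(k+1))·ΣR_j² − 3n(k+1)`,
`F = (n−1)χ²_F/(n(k−1) − χ²_F)` with (k−1, (k−1)(n−1)) degrees of
freedom; the statistic is undefined (an error) when the denominator
vanishes, which occurs under perfect domination at small n·k.

## Synthetic cohort

The generator emulates exactly the structure the pipeline exercises: a
class-dependent baseline level with a slow sinusoidal drift (2–5 bpm,
4–8 min period), band-limited 0.03–1 Hz Gaussian variability (6/4/2 bpm
for N/S/P — variability falls as the fetus decompensates),
raised-cosine accelerations (2/1/0.3 events per 10 min) and
decelerations (0.3/1.5/4 per 10 min, 18/25/35 bpm deep, with a 15 %
prolonged-deceleration probability in the Pathological class), plus
short zero-dropout runs (< 15 s, capped at 3) and > 200 bpm spikes
(capped at 6), both kept away from the record edges so every 660 s
record yields exactly one valid segment.  pH is drawn uniformly inside
the class's label interval with a 0.01 guard band off the boundaries.

Because cord pH is an outcome proxy only loosely coupled to the trace,
25 % of recordings are *atypical*: their morphology is drawn from an
adjacent severity class while the pH (hence label) stays true.  This
overlap is what makes the classification problem non-trivial — without
it the simulated classes separate perfectly and threshold moving is
vacuous.  What the generator does **not** emulate: uterine-contraction
coupling, maternal-heart-rate capture, autonomic spectral signatures,
gestational-age effects, or any real waveform statistics.  Passing tests
therefore demonstrate the pipeline's mechanics and its imbalance
handling, not clinical performance; real-cohort results require real
recordings.

## Problem sizes and numerical choices

The end-to-end experiments in the test suite run the full default cohort
(502 recordings, 3 folds) across 10 seeds; a full experiment takes a few
seconds.  Feature extraction is deterministic; forests, undersampling,
fold assignment and the generator are seeded, and a rerun with the same
configuration writes byte-identical JSON.  Degenerate conventions used
throughout: moments of constant signals are 0, statistics of empty event
sets are 0, `cov` with zero mean is 0, kappa with degenerate marginals
is 0 (with a warning).  Log-type EMG features add 1e-12 inside the
logarithm.

## Known limitations

* The pH boundary closure and the Suspicious segmentation policy are
  conventions over unspecified corners of the protocol.
* The EMG battery replicates definitions, not any particular toolbox's
  binary output; small numeric differences from other implementations
  are expected (e.g. signed-power conventions for fractional exponents).
* The baseline estimator is deliberately simple; traces whose events
  occupy more than roughly half of a 3-minute window can still bias it.
* `keep_proba` semantics for the probabilistic forest are a declared
  interpretation; published descriptions of comparable models leave the
  parameter's meaning open.
* One λ is tuned per fold; a globally tuned λ is a trivial variant but
  is not what the pipeline records.
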