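# Methods

## The classification problem

An outflow-tract ectopic beat projects a characteristic 12-lead QRS
morphology that depends on its site of origin (SOO). The package's task is
binary chamber discrimination — LVOT (encoded 1) vs RVOT (encoded 0) —
from a single normalized QRS complex, with nine finer sublocation labels
(six aortic-cusp-region LVOT sites, three RVOT sites) carried through for
augmentation constraints and stratified analyses. Two beat representations
feed the classifier: the *raw10* representation (each lead reduced to 10
bin-mean potentials, 120 values) and a 381-feature battery.

## Synthetic beat model

The generator replaces a biophysical simulation chain with a
phenomenological lobe-sum model chosen to preserve exactly the statistical
structure the classifier exploits; it is a stand-in for simulated data, not
a replication of any electrophysiological model.

Each lead's QRS is a sum of three Gaussian lobes (small Q, dominant R,
opposing S) within a 300 ms beat sampled at 1 kHz (both configurable; the
defaults keep arrays small while resolving the QRS). Morphology is
controlled by:

* **Chamber** — the precordial R/S amplitude balance of lead V(p+1) follows
  a logistic r_frac = σ(1.8·(p − t)) in the 0-based precordial index p,
  where the transition position t sits at V3 ± 0.75·`class_separation`
  (LVOT early, RVOT late). This yields the standard electrophysiological
  signature: predominantly negative V1–V2 with late transition for RVOT,
  larger early-precordial R waves and early transition for LVOT.
  `class_separation` (default 1.0, dimensionless ≥ 0) scales the gap
  between the chamber-conditional parameter means; 0 collapses the classes.
* **Sublocation** — each of the nine sites has fixed 2-D chamber-local
  coordinates; a small linear offset of the transition (±0.15 per unit
  coordinate) and limb-lead amplitudes makes graph-adjacent sublocations
  morphologically closer than distant ones (verified as a population
  property in the tests).
* **Anatomy id** — per-anatomy perturbations of lobe widths (±15%), R
  timing (σ = 4 ms), transition (σ = 0.25) and per-lead gains, drawn from a
  seed-derived stream so an anatomy's traits are stable across the
  database.
* **Electrode configuration id** — per-precordial-lead gain (±15%) and
  latency (σ = 3 ms) perturbations plus a small transition shift,
  emulating shifted chest electrodes.

Limb leads use fixed R/S amplitude templates giving the inferior axis
typical of outflow-tract ectopy (tall II/III/aVF, negative aVR/aVL).
Ground-truth QRS onset/offset are defined as the first/last sample where
any lead exceeds 2% of the beat's maximum absolute amplitude; the R-peak
ground truth is the R-lobe center. Everything is bit-deterministic given
(ids, label, config seed).

**Clinical-like populations** emulate the domain shift of real recordings
relative to noise-free simulation: Bernoulli class sampling with an
expected LVOT share (default 77/334 ≈ 0.23, the typical ~3:1 right-sided
imbalance), additive white noise (`noise_sd`, mV), sinusoidal baseline
wander with amplitude drawn in [0, `wander_amplitude` = 0.1 mV] and
frequency in [0.3, 1.5] Hz, and a per-record global gain in [0.7, 1.3].
The record RNG stream is consumed identically whatever the noise settings,
so varying `noise_sd` at a fixed seed re-noises the *same* population —
noise-robustness curves are paired comparisons, not resampling noise.

What the generator does *not* emulate: true anatomical geometry variation,
Purkinje interaction, repolarization, scar, multi-beat rhythm context,
electrode-contact artifacts, or the inter-center acquisition shifts of real
hospital data. Passing tests therefore demonstrate that the pipeline
recovers the class structure it is pointed at — not clinical-grade accuracy
on real ECGs.

## Preprocessing

* **Delineation** — per-lead scale-2 à-trous wavelet moduli are combined by
  a max across leads; the QRS onset is the last sample below 3% of the
  window's maximum modulus before the first sample above 25%, the offset
  the first sample below 3% after the last. The thresholds were fixed from
  the tail behaviour of Gaussian lobes (a 3–5% modulus threshold lands
  within a few ms of a 2% amplitude bound). For synthetic records the
  generator's ground-truth fiducials can be used directly
  (`use_true_fiducials`, default on), keeping the delineator an optional,
  independently tested component.
* **Normalization/alignment** — per-lead baseline (mean of the 10 ms before
  onset) subtraction, zeroing outside the half-open QRS window, division by
  the *global* across-lead max-abs (preserving inter-lead amplitude ratios
  used by comparative features; per-lead mode available as a flag), and
  R-peak centering in a fixed 200 ms window, zero-padded. The operation is
  idempotent and gain-invariant.
* **Downsampling** — each lead's window is split into 10 contiguous
  near-equal bins (remainder samples assigned to the leading bins, a
  deterministic tie-break) and replaced by bin means, i.e. mean electrical
  potentials of consecutive time intervals. Bin-mean pooling, not
  decimation, is used deliberately: it is linear and noise-averaging.

## Transforms

The wavelet is the quadratic-spline derivative-of-smoothing pair
(lowpass [1,3,3,1]/8, highpass [2,−2]) implemented as an undecimated
à-trous bank with symmetric boundary extension, so all scales align with
the signal grid and coefficients behave like smoothed derivatives.
Fiducials: the dominant opposite-signed modulus-maxima pair is found at
scale 4 near the R hint (score = pair strength discounted by distance),
refined down through scales 3→1 in ±2^(s+1)-sample windows; R is the
scale-1 zero crossing between the pair, and flanking opposite-signed
maxima exceeding 12.5% of the maximum scale-1 modulus (configurable)
contribute Q and S. Inverted beats are handled by the pair's sign pattern;
monophasic waves report Q/S absent.

Welch PSD: Hann taper, segment length min(256, L), 50% overlap,
`nfft = 256`. The 256-bin grid (≈ 3.9 Hz at 1 kHz) is the package's
resolution choice: the native grid of a 200 ms window (5 Hz) would leave
the [6, 9) Hz feature band without any frequency bin.

## Feature battery

381 features in three families, canonical names
`<family>.<feature>.<lead|leadA_leadB>`:

* signal (161 = 2 + 8×12 + 3×21): QRS duration (ms), precordial transition
  code (first V-lead whose signed maximum flips polarity relative to V1,
  coded k/5 with sentinel 1.0 for no flip); per lead polarity, max, min,
  signed and unsigned absolute max, amplitude, raw and absolute trapezoidal
  area; per pair signed maximum and area of the lead difference and
  zero-lag Pearson cross-correlation.
* wavelet (136 = 1 + 6×12 + 3×21): the same transition code on scale-1
  signed maxima; per lead max, min, mean, area, fragmentation (raw/absolute
  area, bounded [−1, 1]) and the R/S amplitude ratio at the detected
  fiducials; the three comparative features on scale-1 coefficients.
* spectral (84 = 7×12): fundamental frequency (argmax of power) and six
  band-averaged powers over [0,3), [3,6), [6,9), [9,12), [12,25),
  [25,50) Hz.

Vectors are total and NaN-free by convention: zero-amplitude polarity is
+1, an absent S wave floors the R/S denominator at √ε ≈ 1.5·10⁻⁸ (such
ratios are large outliers by design — the standardizing scaler in the
feature-based SVM absorbs them), and degenerate cross-correlations resolve
to 1 for equal inputs and 0 otherwise. A literal enumeration of the three
families yields 381 columns; family-drop flags allow smaller batteries.

## Augmentation

Mixup on raw beats before feature extraction: λ ~ Beta(α = 5, β = 1.5)
(mean ≈ 0.77, so mixtures stay near the first parent), x̂ = λx_i + (1−λ)x_j,
label of the dominant parent (λ > 0.5), λ retained as SVM sample weight.
Ratio 3 augmented samples per original (each original serves as first
parent exactly `ratio` times). In sublocation mode the second parent must
share the first parent's sublocation or be adjacent in the anatomical
graph — default edges: the aortic-cusp neighborhood
(LCC–commissure–RCC, RCC–NCC, LCC–NCC, AMC–{LCC, NCC},
LV-summit–{LCC, RCC}) and the complete triangle over the three RVOT sites,
with no cross-chamber edges. The graph is an edge-list text file and fully
overridable. Chamber mode pairs uniformly without constraint.

## Classification and evaluation

SVMs use an RBF kernel, C = 1 and the 1/(n_features · mean variance)
kernel-width rule (unstated in the problem definition; conventional
defaults, exposed in config). Feature-battery inputs are standardized;
raw10 inputs are not — their values already share the normalized [-1, 1]
scale, and standardizing near-constant edge bins (fit on noise-free
training data) would amplify test-set noise by orders of magnitude.
Cross-validation is stratified 5-fold with plain accuracy (balanced
accuracy is reserved for the imbalanced held-out sets); hybrid scenarios
pool both training sources in every fold. Confusion counts are reported
with rows/columns ordered (RVOT, LVOT).

The exhaustive lead search trains one SVM per non-empty subset of the 12
leads (4,095 models) on concatenated raw10 lead vectors and assembles each
lead's accuracy distribution from the 2,048 subsets containing it; a
linear-kernel fast mode keeps the full sweep tractable. Feature ranking
uses extra-trees (200 trees, no bootstrap, random split thresholds) with
mean impurity-decrease importances and per-tree dispersions. PCA
cumulative-variance curves justify the low-dimensional representations.

## Reproducibility and problem sizes

A single global seed is expanded into per-stage child seeds with numpy's
`SeedSequence.spawn` over the fixed stage order (generate, clinical,
augment, scenarios); every stage echoes its seed into the results bundle,
and identical configurations produce byte-identical results JSON. The test
suite exercises the full 2,496-beat default database where counts are the
point, and reduced factorial populations (e.g. 4–8 anatomies × 12 SOOs ×
2–5 placements) for model-fitting properties — the package's structural
guarantees are size-invariant, so the reduced designs are the suite's
chosen problem sizes, with generation parameters otherwise at their
defaults.

## Known limitations

* The generator's realism is a stand-in: its morphology distribution
  beyond the SOO/anatomy/electrode factors is invented, so absolute
  accuracies on synthetic populations do not transfer to clinical data.
* The wavelet delineator replaces a learned delineator; it assumes a
  single beat per record and does not handle P/T waves or rhythm context.
* The 9-class sublocation problem is supported by the data structures and
  augmentation constraint but is not evaluated as a headline task.
* Which 25 features would reduce the 381-column battery to a 356-column
  one is undecidable from the battery's description; the package keeps the
  full enumeration and documents the discrepancy rather than guessing.
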