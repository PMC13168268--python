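# Methods

## Pipeline model

One particle transit is one classifiable sample. The preprocessing turns a
transit's events into a binary feature: events in the transit window are
accumulated per pixel and polarity, each count grid is binarized at ≥ 1
event (pure presence/absence — the feature a scattering-based encoding
physically provides), each binary map is optionally reduced by OR-pooling
over non-overlapping blocks, and the positive and negative maps are either
concatenated (`split`, length 2·H′·W′) or OR-merged (`merged`, length
H′·W′). OR-pooling rather than stride subsampling is deliberate: the
feature semantics are "events present in a region", and OR-pooling is the
presence-preserving reduction (it is monotone: adding an event can never
clear an output bit). Stride subsampling is available behind a flag for
comparison. Binarization precedes down-sampling so that pooling operates on
presence bits, not counts; the two orders are equivalent for OR-pooling
with a ≥ 1 threshold but the presence-first formulation keeps the semantics
explicit.

The classifier is binary hyperdimensional computing. Each class prototype
is the positionwise majority vote over its training hypervectors; training
is one pass, so the model is permutation-invariant in the training list and
deterministic given the encoder configuration and the tie-break seed. A
query is assigned to the prototype at minimum Hamming distance. Two
encoders map features to hypervectors: `identity` (D = feature length; the
default, because the event-derived feature is already a binary
hypervector), and `subsample` (a seeded permutation prefix of D positions,
fixed for the life of a model), which supports a fixed D = 10,000 with
full-resolution 640×480×2 features. The mapping between pixel-feature
length and a fixed D is genuinely underdetermined in the source system, so
both are provided and neither is claimed canonical.

Majority ties (possible whenever a class has an even sample count) are
resolved by a single tie-break hypervector drawn once from `tie_seed`, not
re-drawn per bundling call; prediction ties go to the lexicographically
smallest label. Both rules exist purely to make results reproducible — with
thousands of samples per class, tied positions are rare and the choice is
immaterial statistically, but bitwise reproducibility requires a rule.

## Transit segmentation

How single-particle windows are delimited in time is an implementation
choice (an event stream has no frames to count). `segment_transits` bins
the stream (`bin_us`, default use ~100 µs), marks bins with ≥ `min_rate`
events active, takes maximal active runs and merges runs separated by fewer
than `min_gap` quiet bins. Windows are half-open `[t_start, t_end)` and
bin-aligned. With a particle transit lasting ~2 ms and producing thousands
of events against a background of a few events per bin, the threshold is
not delicate.

## Synthetic data generator

The generator emulates the statistical structure of the experimental
recordings, which are not publicly deposited.

* **Interference pattern.** An Airy profile `I(ρ) = (2 J₁(v)/v)²` with
  `v = 3.8317·ρ/r₁`, so the first null sits exactly at the first-ring
  radius `r₁`. By Fraunhofer scaling, `r₁ = 1.22 λ z / (d · pitch)` pixels
  for particle diameter `d`: larger particles give tighter patterns.
  Defaults: λ = 632.8 nm, pitch 10.56 µm, effective propagation z = 5.8 mm,
  giving r₁ ≈ 47/35/27/21 px for 9/12/16/20 µm on the 640×480 sensor. The
  real pattern of a sphere in a channel is richer; only the monotone
  size→scale relation and approximate geometry matter here, and only the
  ordering is asserted anywhere. An explicit `pattern_scale` table can
  override the physical formula.
* **Flow.** The pattern translates vertically (top-to-bottom, matching a
  vertically mounted channel) by `travel_frac`·height (default 25%) across
  `frames_per_transit` rendered frames spanning `transit_duration_us`
  (default 2 ms, ~10 frames). Per-transit beam jitter (`transit_jitter_px`)
  adds sample-to-sample variability.
* **Diffuser.** Grit g ∈ {120, 600, 1500} maps to a Gaussian envelope blur
  of σ = 16/8/4 px (640×480 scale) — coarser grit, lower number, scatters
  wider — followed by multiplication with a fixed seeded speckle field
  (smoothed complex-Gaussian intensity, mean 1, grain ~4 px). The blur is
  applied *before* the speckle: the envelope models the plate's angular
  scattering spread while the grain size is set by the illuminated spot,
  not the grit, so grain contrast must survive at every envelope width.
  Per-frame total intensity is renormalised to the input (the plate
  redistributes energy rather than absorbing it; preserved to well within
  1%). Only the width *ordering* across grits is treated as a fact about
  the physical system; the σ values themselves are package defaults.
* **Event sensor.** The standard per-pixel contrast-threshold model: each
  pixel holds a log-intensity reference; between frames, every multiple of
  `contrast_threshold` (default 0.15, typical for DVS hardware) crossed
  away from the reference emits one event with a timestamp interpolated
  linearly in log intensity, and the reference advances by the quantised
  amount — so over a monotone ramp the signed event count is exactly
  ⌊|Δlog I|/θ⌋, which the tests check in closed form. `log_eps = 1e-3`
  floors the logarithm at dark pixels. Background noise is Poisson at
  `noise_rate` (default 5 events/pixel/s) with uniform position, time and
  polarity; an optional refractory period suppresses same-pixel events
  closer than `refractory_us` (default 0 = off).
* **Session drift.** Each session perturbs the transit intensity by a gain
  (sd 0.05), an additive offset (sd 1e-4) and a beam-centre displacement
  (sd 10 px at 640×480 ≈ 105 µm). With `class_correlated=True` (default) a
  fresh realisation is drawn per (class, session) block — emulating
  sequential acquisition of class A, then B, C, D within a session — which
  couples drift to labels and produces measurement bias; with `False` one
  realisation per session is shared across classes. The additive offset is
  the dominant bias channel: it moves the dark-pixel log floor and thereby
  the number of visible diffraction rings. The scales were chosen once so
  that the default study lands in the qualitative regime of interest
  (single-session accuracy near ceiling, intertwined accuracy high but
  clearly below it); they are not fitted to any measured values.

All randomness flows from `master_seed` through `SeedSequence` spawns (one
stream for drift, one per transit), so datasets are byte-reproducible, on
disk and in memory.

### What the generator does *not* model

Rigorous Mie/Fraunhofer scattering of a sphere in a channel, coherent
speckle statistics beyond a fixed multiplicative field, fluidics (velocity
profiles, particle rotation, focusing), multi-particle coincidences,
refractive-index variation, sensor pixel mismatch and latency jitter.
Consequently, passing tests show that the *pipeline* behaves correctly and
that the documented directional effects (polarity, bias, diffuser width,
feature resolution) follow from the stated mechanisms — not that the
specific accuracy figures of any physical instrument are reproduced.

## Study scales

The package defaults describe the full-scale study: 640×480 sensor, four
classes (9/12/16/20 µm), 6 sessions per class, 1,100 transits per
class-session (≈ 6,600 per class, matching a 6,000-train/600-test budget).
Simulation-heavy studies in the test-suite and in `scripts/acceptance.py`
use `SimulationConfig.reduced()`: a 128×96 sensor with 52.8 µm pitch — an
exact 5×5 binning of the full sensor, so every physical scale (ring radii,
jitter, envelopes) lands at one fifth of its full-sensor pixel value — with
8–25 transits per class-session and 10 frames per transit. These sizes were
chosen so each study completes in minutes on one CPU while test sets remain
large enough (hundreds of samples) for stable accuracy estimates.

Protocol defaults: the intertwined protocol is leave-one-session-out
averaged over all six holdouts (the exact train/test session assignment of
the source system is unknown); the single-session protocol shuffles each
session per class, cuts at `train_fraction = 5/6` (a 500-train/100-test cut
of a 600-sample session) and averages over sessions; accuracy is micro-averaged (trace over total)
on class-balanced test sets. Diffuser comparisons report the mean over
seeded repeats (5 by default), with both the dataset seed and the diffuser
plate seed varied per repeat.

## Numerical and degenerate-input choices

* Windows are half-open; coordinates 0-based, x = column, y = row, origin
  top-left. On-disk polarity is {0, 1} (0 ≡ −1), in-memory {+1, −1}.
* An empty event stream segments to no windows and accumulates to zero
  grids; a transit that produces no events yields all-zero polarity maps.
* OR-pooling pads grids with zeros up to a block multiple
  (`⌈H/bh⌉ × ⌈W/bw⌉` output).
* Gain perturbations are clipped at 0.1 and intensities at 0 to keep the
  log defined; event timestamps are rounded to integer microseconds and the
  stream re-sorted stably, preserving order among equal timestamps.
* `radial_second_moment` and `first_ring_minimum` are the independent
  geometric probes used in tests; the ring probe averages 0.5 px annuli,
  skips annuli containing no pixel centres, and requires a candidate
  minimum to fall below 5% of the central intensity to avoid discretisation
  dips.

## Known limitations

* The polarity `split` advantage on default synthetic data is small: the
  simulated positive and negative maps cover nearly the same swept region,
  so merging loses little. The constructed polarity-swap dataset (classes
  differing only in which map carries which region) isolates the effect and
  shows the expected collapse of merged-mode accuracy to chance.
* Under the diffuser, the offset-drift channel interacts with speckle
  visibility and produces larger session-to-session accuracy spread than
  the no-diffuser condition; directional comparisons are therefore made on
  means over seeded repeats.
* Prototypes store bits only; incremental retraining and real-valued
  (cosine-similarity) hypervectors are out of scope, as are proprietary
  camera formats and live acquisition.
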