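# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package, in the spirit of a model-description appendix.

## Signal model and preprocessing

The device records integer acceleration counts at 4 Hz on the lateral
(x) axis; a y axis may be present and is carried through unchanged but
never used by the models. The preprocessing chain is

1. centered 5-point moving average (truncated-centered boxcar: at the
   edges the mean is taken over the samples that exist);
2. integer normalization: `round(x) − round(mean(x))`, rounding half away
   from zero. This is mean *subtraction*, not scaling — the point is to
   keep the network input integer-valued on a device with no FPU budget;
3. down-sampling by decimation (keep every 4th sample), applied after the
   filter so the average is computed on the full-rate signal.

Geometry: 300-step (5-minute) segments are the unit of classification;
90-step windows slide in steps of 22 (one quarter window, as printed — not
22.5), giving `floor((300−90)/22)+1 = 10` scores per segment. Trailing
partial segments and windows are discarded, never padded: classification
repeats over time, and padding would fabricate signal.

## Networks

All three variants are one-hidden-layer tanh networks with a tanh output
unit; scores live in (−1, +1) and the sign is the window-level call (an
exact 0 maps to non-digging, the conservative side).

- **IDNN**: every hidden unit sees the whole 90-sample window
  (90 weights + bias = 91 per unit). Hidden units default to 5; the
  model-selection range is 1–10.
- **IDNN-LRF**: four contiguous 22-sample sub-windows starting at offset
  0, one hidden unit each (23 weights incl. bias). Samples 88–89 of the
  window are unused (4 × 22 = 88 < 90); uniform 22-sample fields are the
  only layout consistent with the uniform per-unit weight count.
- **IDNN-LRF-WS**: the two "ascent" fields (sub-windows 0 and 2) share
  one weight vector, the two "descent" fields (1 and 3) the other. A
  shared unit **sums the pre-activations** of its two fields and adds its
  bias once, then applies tanh. This is the only combination rule
  consistent with the stored-parameter count (2 × 23 + 3 = 49 floats =
  196 bytes at 4 bytes/float), and it makes the output exactly invariant
  under swapping the contents of paired sub-windows.

Memory accounting counts distinct stored float parameters (hidden vectors
with biases, plus the output unit's n_hidden + 1 weights) times 4 bytes;
the 90-integer input buffer is excluded.

## Training

Full-batch gradient descent on the summed squared error with classical
heavy-ball momentum; weight decay adds `λ‖w‖²` (biases included) to the
loss and its exact gradient `2λw` to the update — the momentum term
carries the decay gradient too. For the weight-shared variant the shared
vector's gradient is the sum over both receptive fields. Initialization:
input→hidden uniform in ±1e−5, hidden→output uniform in ±0.01.

Stopping: relative training-loss improvement below 1e−5 for 50 consecutive
epochs, or 3000 epochs. The patience is deliberately long: with the tiny
initialization the loss crosses a near-flat plateau (relative change
~1e−5) for tens of epochs before learning takes off, and a short patience
stops there with a chance-level network.

Default hyperparameters were selected by grid search over the stated
search ranges (learning rate [1e−4, 0.1], momentum [0, 0.1], weight decay
[0, 1e−3]) on two independent synthetic benchmark realizations with ten
initializations each: learning rate 0.002, momentum 0.1, weight decay
3e−4 for IDNN and 1e−3 for both LRF variants.

Training patterns: positives are *characteristic patterns* — windows
aligned at a square-wave onset (first upward crossing of half the peak
magnitude) plus a uniform jitter of up to ±3 steps that emulates the
imprecision of marking the excerpt by eye. Negatives are windows sampled
at uniform random offsets of walking/eating segments. Alignment matters:
positives cut at arbitrary phase are ~20% mislabelled from the network's
point of view and cap pattern accuracy near 80%.

## Output filter

NP counts strictly positive scores; MP is the positive mass over the
stream length; MPT the mass above τ over the stream length. "Positive"
and "above" are strict everywhere; NP's vote uses ≥ 2 because it is
phrased as a count threshold. τ is the mean of positive scores pooled
over all filter-validation streams. MP/MPT bounds: midpoint of the gap
between the two validation groups when one exists (perfect validation
separation by construction); otherwise the accuracy-maximizing cut,
lowest value on ties. Thresholds are recalibrated per trained instance —
they live on that instance's output scale. The segment vote needs two of
three features to pass. A digging detection is confirmed only if the
segment two positions (10 minutes) later is also digging.

## Synthetic data

The generator emulates the three signal classes as the field descriptions
characterize them:

- **digging**: square wave of half-height `amplitude` (default 40 counts)
  around `baseline` (100), period 45 s (two waves per 90 s window) with
  per-wave uniform period jitter of ±20%, plus Gaussian sensor noise
  (sd 3). Duty cycle 50%, symmetric about baseline.
- **walking**: mean-reverting AR(1) (Ornstein–Uhlenbeck) oscillation with
  a 2 s correlation time, lightly smoothed, scaled to sd 25 counts. A
  *pure* random walk would stay autocorrelated over minutes, which the
  chaotic gait-driven carapace oscillation is not; the short correlation
  time reflects step-cadence dynamics.
- **eating**: baseline plus sensor noise only.

Amplitude, baseline, noise and walking scale are not published quantities;
they were fixed once at values plausible for a ±2 g sensor mapped to
integer counts and are deliberately not tuned against any benchmark
outcome. Default dataset composition mirrors the field campaign (62
digging, 15 walking, 6 eating sequences), and the default split sizes are
134 training patterns, 20 validation patterns, 30 filter-calibration
segments, 56 test segments, all class-balanced and disjoint by source
segment.

What a green synthetic test establishes: the pipeline wiring, the exact
arithmetic of preprocessing/networks/filter, determinism, and that the
full protocol learns a strong classifier on signals with the stated
structure. What it does not establish: field performance. The synthetic
world is harder than real recordings in one specific way — per-wave
period jitter makes each segment's phase drift, so the 10 scanned windows
land at effectively random phases relative to the wave onsets.

## Measured behaviour and limitations

With the defaults, mean test-segment accuracy over five initializations
is roughly 75–90% depending on variant and benchmark seed (LRF is
typically best). Error anatomy, measured on the benchmark:

- *Missed digging segments* are phase-coverage losses: the trained
  detector tolerates ~±4 steps of window/wave misalignment, so the number
  of firing windows per digging segment behaves like a Binomial(10, ~0.2)
  draw, and occasionally only 0–1 windows fire.
- *False digging calls* are saturated spurious fires on walking windows
  whose slower excursions mimic plateau phases.
- An oracle allowed to pick the three filter bounds directly on the test
  streams reaches only ~89–96%: the ceiling is in the scores themselves,
  not in threshold estimation. Calibrating on 15+15 validation segments
  costs a further ~3 points.

Other limitations: no quantized/integer inference path (training and
scoring run in float64; the byte accounting models the device layout);
the walking model is statistical, not a gait simulation; the y axis is
ingested but unused; thresholds and weights serialize to JSON text, not
a device image.
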