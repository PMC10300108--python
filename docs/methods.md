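# Methods

This note documents the models and numerical choices behind
`spinescreen`: what the two policy engines compute, what the synthetic
sit-to-stand generator emulates (and what it does not), and where the
design was genuinely open.

## Screening model

The screening task is to decide, from a wearable inertial measurement
unit (IMU), whether a person's sit-to-stand movement pattern looks
natural or stiffened — the latter being the guarded movement style
associated with spine conditions such as sagittal imbalance or
scoliosis. Two 9-axis IMUs at 25 Hz are assumed, one on the head and
one on the upper chest along the spine. Each repetition of the
exercise produces one impulse on the torso vertical (Z) axis; the
screening signal is carried by two temporal features of that impulse:

* **Amplitude** — the maximum deviation from baseline (signal units
  are left arbitrary: the policies only compare them against
  references in the same units);
* **Width** — the impulse duration in samples, measured between the
  crossings of 5% of the impulse's own peak height.

Natural movement is brisk and confident: tall narrow impulses
(amplitude ≈ 2, width ≈ 100 samples). Stiffened movement is careful
and slow: shallow wide impulses (≈ 0.6, ≈ 300 samples) with a
pronounced lateral head-X component from leaning sideways to unload
the spine.

## Crisp engine (AGILE PDL)

A policy suite is an XML document of declarative objects: environment
variables (the features), internal variables initialised by
*templates* (the thresholds), *rules* (binary comparisons),
*tolerance range checks* (TRCs), *utility functions* (UFs), *actions*
and *policies*. Evaluation walks the entry policy's action graph and
stops at the first `Return`, emitting a named decision plus a full
ordered trace (the audit trail a clinician or engineer can read back).

Semantics fixed by this package:

* **TRC dead-zone** — with deviation d = value − reference:
  in-zone iff |d| ≤ tolerance (boundary inclusive, matching the
  "tolerance" reading of the word), below iff d < −tolerance, above
  otherwise. Exactly one zone holds.
* **Control flow is explicit** — a TRC zone's action is the action
  that performs the next check; there is no implicit fall-through.
  A zone or rule branch without an action continues with the next
  step of the enclosing action; an entry action that ends without a
  `Return` is an error ("policy returned no decision") — a screening
  run must never end silently.
* **Utility functions** — utility = Σ weightᵢ·valueᵢ dispatched
  through ordered half-open bands [bᵢ, bᵢ₊₁); a utility exactly at a
  breakpoint belongs to the upper band. This is the simplest monotone
  reading of banded goal-attainment dispatch and is an extension
  point: the shipped spine policy does not use UFs.
* **Recursion** — `Yield`/action chains are depth-limited (default
  32) to guard against author error in cyclic policies.
* Variable references are bare names resolved environment → internal
  → local; cross-scope shadowing is a validation warning.
* Numbers serialize in shortest round-trip decimal form, so policy
  files diff cleanly; parse ∘ serialize is the identity on the model.

The shipped worked-example suite checks Amplitude against 2 ± 0.5
(TRC1) and then Width against 100 ± 10 samples (TRC2), returning
`SpineOK` only if both pass — so the `SpineOK` acceptance region
under an amplitude sweep is exactly the closed interval [1.5, 2.5].

## Fuzzy engine

The fuzzy policy grades the same two features against Small / Medium /
High linguistic terms and produces a severity scalar on [0, 1]
(0 = no spine issue detected, 1 = severe condition). Inference is
Mamdani: min-conjunction for rule firing, min-implication (clipping)
of consequents, pointwise-max aggregation, centroid defuzzification
by trapezoidal quadrature on a uniform 1001-point grid. Mamdani was
chosen over Takagi–Sugeno because the policy model aggregates clipped
output terms into a single fuzzy output variable before producing a
crisp value; with the shipped fixture, doubling the grid resolution
moves the worked outputs by < 1e-3.

Membership shapes are trapezoids (a ≤ b ≤ c ≤ d, plateau on [b, c];
degenerate edges give crisp steps) and Gaussians
μ(x) = exp(−(c − x)²/2σ²). Inputs outside a universe are clamped to
its bounds — extreme movements should degrade gracefully, not error.
If no rule fires the engine raises instead of emitting a default
severity.

The 3×3 rule base maps (Width term × Amplitude term) → severity term,
monotone by construction: severity never decreases with width and
never increases with amplitude. The healthy corner (high amplitude,
small width) maps to Small severity; the diseased corner (small
amplitude, high width) to High.

### Fixture calibration

The shipped reference policy's membership parameters are this
package's calibration, not measured constants. They form Ruspini
partitions (adjacent ramps sum to 1):

| variable | universe | Small | Medium | High |
|---|---|---|---|---|
| Amplitude | [0, 4] | (0, 0, 0.6, 1.4) | (0.6, 1.4, 2.2, 3) | (2.2, 3, 4, 4) |
| Width (samples) | [0, 400] | (0, 0, 80, 160) | (80, 160, 240, 320) | (240, 320, 400, 400) |
| Severity | [0, 1] | (0, 0, 0.25, 0.45) | (0.25, 0.45, 0.55, 0.75) | (0.55, 0.75, 1, 1) |

The partition structure matters: with non-partition overlaps the
aggregate's mass dips at term handoffs and the Mamdani centroid
wiggles non-monotonically by up to ≈ 0.04, which would defeat the
intended "more stiffened ⇒ more severe" reading. With this
calibration the severity surface on a 41×41 grid over
[0, 4] × [0, 400] is monotone (nondecreasing in width, nonincreasing
in amplitude) to within 0.02 — the residual wiggle is the unavoidable
centroid shift as a single clipped term's height passes through a
crossover — and the worked feature pairs land clearly on either side
of mid-scale: severity(1.6, 105) ≈ 0.29, severity(0.6, 300) ≈ 0.81.

## Feature extraction

`detect_impulses` is deterministic and relative-threshold only:

* baseline = channel median (robust against the impulses themselves);
* deviation = |x − baseline| (sign-agnostic; gyroscope impulses may
  be bipolar);
* candidate peaks = local maxima of the deviation above
  α · max-deviation (α = 0.25), thinned greedily in descending height
  with a 10-sample exclusion radius (`scipy.signal.find_peaks` with
  `distance`);
* width between the nearest crossings of β = 5% of each peak's own
  height; impulses narrower than 5 samples are dropped; overlapping
  impulses merge keeping the taller peak (this absorbs noise-induced
  secondary maxima riding on a wide pulse);
* movement floor: a channel whose maximum deviation is under 8 robust
  noise sigmas (1.4826 × MAD) is movement-free and yields no
  impulses. The floor is a ratio, so the detector stays exactly
  scale-equivariant (amplitudes scale, widths don't) and
  shift-invariant, while a recording of pure sensor noise — whose
  maximum would otherwise trivially exceed any relative threshold —
  is flagged instead of producing phantom repetitions.

The per-impulse 5%-of-own-peak width convention keeps widths
comparable between impulses of very different amplitudes (2 vs 0.6),
which a single global threshold would not.

Because amplitude is defined as the maximum deviation within the
impulse, additive noise biases it upward by roughly the expected
maximum of the noise over the impulse's near-peak plateau — ≈ +0.04
signal units at the default noise level, negligible for the healthy
pattern (≈ 2) and ≈ +7% for the constrained one (≈ 0.6). This is a
property of the max statistic, not of any particular recording.

## Synthetic generator

`synthetic_imu` emulates the four-repetition protocol: stand up and
sit down naturally, rest ≈ 1 minute, repeat; then twice more with
head and back deliberately straight and stiff. Defaults:

| parameter | healthy | constrained |
|---|---|---|
| torso-Z amplitude (mean ± sd) | 2.0 ± 0.1 | 0.6 ± 0.05 |
| torso-Z width, samples (mean ± sd) | 100 ± 5 | 300 ± 10 |
| head-X lateral amplitude (mean) | 0.1 | 0.8 |
| noise sd (all channels) | 0.02 | 0.02 |
| sampling rate | 25 Hz | 25 Hz |
| inter-repetition gap | 1500 samples (≈ 1 min) | same |

Pulses are half-cosine arches s(t) = A·sin(π(t+1)/(W+1)) — smooth,
compactly supported, and analytically invertible so the nominal width
can be defined at the same 5% level the extractor measures: a drawn
nominal width W is realised with a support of (W+1)/(1−2·asin(0.05)/π)
− 1 samples, making the extractor's recovery unbiased by
construction. The lateral sd defaults to 10% of the lateral mean (the
protocol fixes only the means). Twelve channels (head/torso ×
accel/gyro × X/Y/Z) share length and rate; only torso-Z and head-X
carry structured signal by default — these are the channels the
screening features are read from — and all carry Gaussian noise.
Everything is driven by one `numpy` Generator, so recordings are
bit-identical given the seed.

What the generator does **not** emulate: multi-segment biomechanics,
gravity offsets and orientation drift, sensor bias/saturation,
magnetometer or other physiological channels, and pathology-specific
waveform differences beyond the amplitude/width/lateral contrast.
Passing tests therefore demonstrate that the pipeline recovers and
classifies the contrast the protocol is built around, not that the
detector is robust to every artefact of real wearable data.

Detection caveat: with mixed healthy + constrained sessions, the
candidate threshold α·max sits near 0.25·2 ≈ 0.5, close below the
constrained amplitude ≈ 0.6, so an unluckily weak stiffened
repetition can fall under it for some seeds. The default session seed
detects all four repetitions; session-level tests are therefore
seed-pinned, which the generator's determinism makes exact.

## Problem sizes

Test and acceptance runs use deliberately modest sizes — 20 seeds ×
2 repetitions per pattern for round-trip statistics, a 0.001-step
amplitude sweep (4001 policy evaluations), a 41×41 severity grid, and
10⁴ random triples for the dead-zone trichotomy — chosen because the
estimates they produce are already stable to well within the
tolerances being checked.

## Known limitations

* The fuzzy fixture is a calibration, not a fit: real cohorts would
  need membership parameters estimated from labelled recordings.
* Feature means (not per-impulse sequences) feed the policies; a
  per-impulse mode exists in the feature report but the shipped
  policies evaluate session means.
* The crisp policy's dead-zones make hard, discontinuous decisions at
  the tolerance boundary; the fuzzy policy is the graded alternative.
* The CSV dialect assumes a uniform time grid; irregular sampling is
  collapsed through the median time step.
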