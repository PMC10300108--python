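# spinescreen

Policy-based expert-system screening of spine conditions from
wearable IMU recordings.

People with spine problems (stiff neck, scoliosis, sagittal
imbalance...) move differently: standing up from a chair, they guard
the spine — the movement gets slower, shallower and drifts sideways.
`spinescreen` turns that observation into a testable screening
pipeline for engineers and researchers building IMU-based clinical
decision support:

1. **Recordings** — multi-channel 25 Hz IMU time series
   (`sensor.instrument.axis`, e.g. `torso.accel.z`) read and written
   as plain CSV, plus a seeded synthetic generator for the
   sit-to-stand protocol (two natural repetitions, two stiffened
   ones) so everything runs without hardware or patients.
2. **Features** — each repetition is one impulse on the torso
   vertical axis; the extractor measures its *amplitude* (max
   deviation from the median baseline) and *width* (samples between
   the 5%-of-peak crossings).
3. **Policies** — expert logic in human-editable XML, evaluated by
   two engines:
   * a **crisp engine** (AGILE policy-definition-language style):
     dead-zone checks of the form |value − reference| ≤ tolerance,
     chained through explicit actions to a named decision with a full
     execution trace;
   * a **fuzzy engine**: Mamdani inference (min conjunction, clipped
     consequents, max aggregation, centroid defuzzification) over
     Small/Medium/High linguistic terms, returning a disease-severity
     score in [0, 1].

The shipped crisp policy returns `SpineOK` iff Amplitude ∈ 2 ± 0.5
and Width ∈ 100 ± 10 samples; the shipped fuzzy policy encodes the
monotone 3×3 rule base — severity rises as impulses get wider and
falls as they get taller:

| | Amp Small | Amp Medium | Amp High |
|---|---|---|---|
| **Width Small** | Medium | Small | Small |
| **Width Medium** | High | Medium | Small |
| **Width High** | High | High | Medium |

See `docs/methods.md` for the model details and calibration.

## Worked example

```sh
$ spinescreen simulate --pattern session --seed 0 --out session.csv
wrote 5527 samples × 12 channels to session.csv

$ spinescreen features session.csv
torso.accel.z: 4 impulse(s); mean amplitude 1.333, mean width 197.8 samples

$ spinescreen simulate --pattern healthy --seed 0 --out healthy.csv
wrote 1904 samples × 12 channels to healthy.csv

$ spinescreen features healthy.csv
torso.accel.z: 2 impulse(s); mean amplitude 2.023, mean width 100 samples
```

The session recording contains all four protocol repetitions — two
tall narrow impulses (natural movement, amplitude ≈ 2, width ≈ 100
samples) then two shallow wide ones (stiffened, ≈ 0.6 / ≈ 300) — so
its channel means sit between the patterns. Screening uses one
pattern at a time:

```sh
$ spinescreen screen healthy.csv --policy <crisp-policy.xml>
decision: SpineOK

$ spinescreen screen session.csv --policy <crisp-policy.xml>
decision: SpineNOK

$ spinescreen screen healthy.csv --engine fuzzy --policy <fuzzy-policy.xml>
severity: 0.271052
```

`SpineOK` means both features sat inside their dead-zones (the
session's mixed means 1.333/197.8 do not, hence `SpineNOK`); a
severity of 0.27 on the 0–1 scale means the fuzzy system sees little
evidence of a spine issue. The shipped policy files live under
`src/spinescreen/policies/` and are returned by
`spinescreen.policies.agile_worked_example_path()` /
`fuzzy_reference_path()`. The same pipeline is available as a
library:

```python
from spinescreen import generate_recording, HEALTHY, extract_features
from spinescreen import policies, evaluate_policy_suite

rec = generate_recording(HEALTHY, n_reps=2, seed=0)
feats = extract_features(rec, "torso.accel.z")
suite = policies.load_agile_worked_example()
decision = evaluate_policy_suite(
    suite, {"Amplitude": feats.mean_amplitude, "Width": feats.mean_width})
print(decision.name)   # SpineOK
```

Every decision carries a trace (`spinescreen.render_trace`), one line
per evaluated object, e.g. for the worked inputs Amplitude 1.6 /
Width 105:

```
1. policy SpineScreeningPolicy → enter
2. template SpineThresholds → applied
3. action ActionCheckAmplitude → enter
4. trc TRC1 → in
5. action ActionCheckWidth → enter
6. trc TRC2 → in
7. action ActionSpineOK → enter
8. return SpineOK → SpineOK
```

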