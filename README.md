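# pulsecontour

Contour analysis of arterial pressure pulse waves recorded with an
occlusive-cuff sensor, for people studying cardiovascular stiffness and
building classifiers over pulse-wave morphology: biomedical-signal
engineers, hemodynamics researchers, and anyone who needs a fully seeded
synthetic stand-in for cuff hardware.

A single cardiac cycle of the cuff-pressure signal carries six
characteristic points:

* **A** — cycle onset (pre-systolic minimum),
* **B** — systolic peak (main pulse amplitude),
* **B′** — an often-invisible shoulder on the descent where left-ventricular
  ejection ends,
* **C** — dicrotic notch / incisura (end of systole, aortic valve closure
  onset),
* **D** — dicrotic wave peak (elastic recoil of the arterial wall),
* **E** — end of diastole.

From these, the package computes the standard amplitude–time parameters.
With `h(X)` the height of point `X` above the onset baseline and `t_X` its
time:

| parameter | formula | normative |
|---|---|---|
| pulse amplitude | `h(B)` | — |
| dicrotic wave amplitude | `h(D) − h(E)` | ≈ ½ pulse amplitude |
| incision height | `h(C)` | ≈ ⅔ pulse amplitude |
| dicrotic wave index (DWI) | `100·(h(D)−h(E))/h(B)` % | 63–73 % |
| rising wave index | `100·(t_B−t_A)/(t_E−t_A)` % | 15–24 % |
| filling time | onset → 90 % of the rising limb | 0.06–0.12 s |
| reflection time | `t_D − t_C` | 0.03–0.04 s |
| systole / diastole durations | `t_C − t_A`, `t_E − t_C` | — |
| heart rate | `60/(t_E − t_A)` bpm | — |

A low DWI marks a stiff vascular bed: an elastic young vessel shows ~44 %,
a stiff 60-year-old vessel ~22.7 %, and the share of the cycle spent on
vascular (diastolic) work drops from ~64 % to ~49 %.

Fiducial detection follows the classical derivative route: the beat is
smoothed with a Savitzky–Golay local polynomial filter whose analytic first
and second derivatives locate the extrema and the B′ curvature shoulder;
each landmark is then refined to sub-sample resolution with a cubic-spline
fit around its grid position. Before any of that, the slow respiratory
amplitude modulation of the oscillation train is estimated from per-beat
amplitudes (PCHIP envelope through the systolic anchors) and divided out.

Seven anthropometric values (age, gender, height, weight, waist and arm
circumference, BMI) joined with fourteen beat parameters form a 21-element
multiparametric feature vector. A from-scratch multilayer perceptron
(21 → H → K, logistic units, z-scored inputs) is trained on it by error
backpropagation, with per-output sensitivity/specificity evaluation and a
cross-validation helper for choosing the hidden-layer size.

Because cuff hardware is out of reach for automated testing, the
`synthwave` module generates beats as calibrated sums of smooth asymmetric
bumps: the requested systolic height, dicrotic-wave height, notch depth and
notch time are hit exactly by numerical calibration, and the generator
returns the continuous model's extrema as ground truth, so the whole
pipeline is tested against known answers.

## Worked example

```
$ pulsecontour simulate --preset young-normal --seed 7 --duration 20 --out yn.csv
wrote 10164 samples at 512 Hz to yn.csv
$ pulsecontour features yn.csv --out yn_features.csv --normative-report
24 beats -> yn_features.csv
  dicrotic_wave_index: 70.157 [normal]
  rising_wave_index: 18.500 [normal]
  filling_time: 0.124 [above]
  reflection_time: 0.064 [above]
  dicrotic_amplitude: 7.266 [above]
  incision_height: 6.233 [below]
```

Twenty seconds of the textbook elastic-vessel preset yield 24 analyzable
beats; the measured dicrotic wave index (70.2 %) sits inside the 63–73 %
normative band and the rising wave index inside 15–24 %. The same command
on the stiff-vessel preset (`--preset age60`) prints
`dicrotic_wave_index: 22.397 [below]` — the reduced-elasticity signature.

The other subcommands chain the full workflow
(`segment`, `fiducials`, `train`, `predict`), and

```
$ pulsecontour pipeline --workdir run1 --seed 3
```

runs simulate → segment → fiducials → features → train end-to-end, leaving
CSV artifacts, a JSON model and a manifest (seeds + SHA-256 hashes of every
artifact) in `run1/`.

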