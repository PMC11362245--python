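# usnav — freehand ultrasound biopsy navigation

`usnav` is a software toolkit for ultrasound-guided freehand needle biopsy of
small soft-tissue masses (e.g. suspicious lymph nodes in the head-and-neck
region, 8–10 mm in diameter). An optical tracking camera observes rigid
marker tools on the ultrasound probe and on the biopsy needle; once the
lesion is in view, the operator presses a button, the lesion centre found in
the 2-D frame is registered into the camera's 3-D world frame, and the probe
can be put down. The needle is then guided to the target by ear: a
three-tier acoustic feedback loop tells the operator whether the extended
needle line would miss the target (200 Hz), nearly hit it (350 Hz), or hit
it (440 Hz), so the surgeon keeps both hands free and their gaze on the
patient.

## The model

All frames are related by rigid transforms (4×4 homogeneous matrices,
column-vector convention, mm units). The lesion centre seen at pixel
`(x, y)` of the ultrasound frame is registered as

```
RF_world = world_T_image · RF_image,     world_T_image = world_T_sono · sono_T_image
```

where `world_T_sono` is the tracked probe-tool pose and `sono_T_image` comes
from probe calibration (a fiducial-based absolute-orientation fit that also
estimates the pixel spacing). The needle tip is

```
world_T_tip = world_T_needle · needle_T_tip
```

with `needle_T_tip` from pivot (tip) calibration — a linear least-squares
solve of `R_i·p + t_i = w` over poses rotating about the stationary tip.

The registered lesion is modelled as the sphere
`(x−m_x)² + (y−m_y)² + (z−m_z)² = r²`. At each feedback tick (20 Hz by
default) the perpendicular distance `d` from the extended needle line to `m`
classifies the alignment: hit (`d ≤ r`, target ahead of the tip), near
(`r < d ≤ 2r`), miss (otherwise), mapped to 440/350/200 Hz tone events. The
insertion depth — the along-shaft distance to the closest approach and, for
a hit, to the proximal sphere surface — is reported at navigation start.

Accuracy is assessed on an evaluation phantom: a water-filled hollow sphere
(16 mm inner diameter) containing an 8 mm spherical target, with two surface
notches 19 mm apart on a line through the centre. The needle-probed notch
midpoint defines the "true" reference; repeated navigated registrations give
per-trial Euclidean deviations, the mean position E, the surgical deviation
of E from the reference, and the hit count. A synthetic phantom simulator
(tracked poses with 0.25 mm Gaussian tracker noise, B-mode-like frames with
log-normal speckle) provides ground truth for end-to-end tests.

## Worked example

The package ships the ten navigated trial positions measured on the
evaluation phantom together with the probed marker positions:

```bash
usnav evaluate
```

```
reference centre : [   55.34    90.08 -1008.65]
mean position E  : [   54.8    91.1 -1006.4]
surgical deviation: 2.5287 mm
hits: 8 of 10 within 4 mm
  trial  1: deviation 3.0182 mm
  trial  2: deviation 3.4664 mm
  trial  3: deviation 1.9343 mm
  trial  4: deviation 1.7857 mm
  trial  5: deviation 3.0052 mm
  trial  6: deviation 3.4976 mm
  trial  7: deviation 3.1801 mm
  trial  8: deviation 1.7028 mm
  trial  9: deviation 4.1931 mm
  trial 10: deviation 4.8634 mm
```

The reference centre is the midpoint of the two probed notch markers; each
trial's deviation is its Euclidean distance to that reference; E is the
component-wise mean of the ten positions (1 decimal); the surgical deviation
is the distance from E to the reference; 8 of 10 registered centres lie
inside the 4 mm target radius. `--globe globe.json` exports the 3-D globe
model (hollow sphere, target, reference, measured points) and `--figure
globe.png` renders it.

The same library drives simulation and replay:

```bash
usnav simulate --seed 7 --trials 10 --out sim/     # synthetic accuracy trials
usnav replay --poses poses.csv --target target.json --tip-cal tip.json \
             --rate 20 --out events.jsonl          # acoustic-feedback replay
usnav calibrate probe --fiducials fid.csv --out probe.json
usnav calibrate pivot --poses pivot.csv --out tip.json
```

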