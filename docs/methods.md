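# Methods

## Coordinate frames and rigid algebra

All geometry lives in millimetre units in four frames: `world` (the optical
tracking camera), `sono` (the tracking tool on the probe), `image` (the
metric ultrasound image plane) and `needle`/`tip`. Transforms are 4×4
homogeneous matrices, column-vector convention (`p_parent = M · p_child`),
and every transform carries frame labels so that an ill-formed chain raises
instead of silently producing a wrong point. Quaternions in pose logs are
scalar-first `(w, x, y, z)`. Image pixels are 0-based with the origin at the
top-left; `col` grows laterally and `row` with depth, and the metric image
plane has `z = 0`. Rotation matrices are snapped to the nearest rotation
(polar decomposition via SVD) whenever their orthonormality error exceeds
1e-9, which bounds drift over long composition chains; the suite checks
orthonormality after 1000 random compositions.

## Probe calibration

`calibrate_probe` consumes fiducial captures `(pixel, world point, probe
pose)`. World fiducials are mapped into the probe-tool frame with the
inverse tracked pose, removing the probe pose from the problem (the result
is therefore invariant to rigid motions of the whole setup, which the suite
verifies). Because a rigid map preserves distances, the anisotropic pixel
scales satisfy `|Δs|² = sx²·Δcol² + sy²·Δrow²` for every fiducial pair; the
two squared scales are solved by linear least squares over all pairs, after
which the rigid part is a standard absolute-orientation (Kabsch/SVD) fit
between the scaled planar pixel points and the tool-frame points. The
residual RMS is the fiducial registration error (FRE). Degenerate inputs —
fewer than three fiducials, collinear pixels, no spread along one image axis
— raise `DegenerateGeometryError`. Noiseless synthetic fiducials are
recovered to better than 1e-9 (machine precision in practice), and the
translation error shrinks monotonically as fiducial noise drops over
σ ∈ {1, 0.1, 0.01} mm at n = 100.

## Pivot (tip) calibration

With the tip stationary at an unknown world point `w`, every tool pose
satisfies `R_i·p + t_i = w`; stacking `[R_i  −I]·[p; w] = −t_i` gives a
3n×6 linear system solved by least squares. The tip map `needle_T_tip` is
modelled as a pure translation: a point target needs no tip orientation, and
the needle direction is taken from the tool-frame shaft axis, configurable
and `(0, 0, 1)` by default. Observability is guarded by requiring the
smallest singular value of the stacked system to be at least 1e-6 —
identical rotations in all poses make the offset unobservable and raise.
The residual RMS is zero (within 1e-9) exactly when the poses are
noise-free and consistent.

## Lesion detection

The intended segmentation backend in the clinical system is a trained deep
network; this package ships a classical detector with the same contract
(binary mask, sub-pixel area centroid, circle-equivalent diameter), so a
network can drop in via `load_mask_as_result` without touching the
navigation chain. The detector smooths with a Gaussian (σ = 2 px), thresholds
dark regions at 0.5× the image median (the median is a robust background
estimate while the lesion covers a small fraction of the frame), filters
connected components by area (50–5000 px²) and circularity (4πA/P² ≥ 0.6),
and keeps the component with the highest contrast against the background.
Because the detection threshold sits inside the blurred lesion edge, the
selected component is refined to the half-amplitude contour — midway between
the component's median intensity and the background — which for a smoothed
step crosses at the true boundary; this makes the equivalent diameter of a
noiseless disc accurate to well under half a pixel. The centroid is the area
centroid (not a bounding-box centre), is translation-equivariant, and is
invariant to global linear intensity rescalings that keep the contrast sign.

## Target registration and acoustic guidance

Registration pushes the centroid through metric embedding
(`col·sx, row·sy, 0`) and the chain `world_T_sono · sono_T_image`. The
target radius is half the circle-equivalent diameter times the mean of the
two pixel spacings; in-plane anisotropy beyond that is ignored by the sphere
model. The alignment classifier computes the perpendicular distance `d`
from the extended needle line to the centre and returns 2 (hit) when
`d ≤ r` with the target ahead of the tip, 1 (near) when `r < d ≤
near_factor·r`, else 0. Design choices, each covered by tests:

- **Ray semantics.** An intersection behind the tip is classified 0 — a
  needle pointing away from the patient cannot be a hit. The tier-2
  predicate is verified against a brute-force oracle that samples the
  forward ray densely and tests sphere membership on 1000 random
  configurations (configurations within the oracle's sampling resolution of
  tangency, and the degenerate case of a tip already inside the target, are
  excluded).
- **Near band.** The middle tier has no published threshold; the band is
  `r < d ≤ near_factor·r` with `near_factor = 2.0`, configurable.
- **Inclusive boundaries.** A tangent line counts as a hit; `d` exactly at
  `near_factor·r` counts as near. Deterministic and testable.
- **Depth.** The announced insertion depth is the along-shaft distance from
  tip to the closest approach to the centre; for a hit the distance to the
  proximal sphere surface (the entry depth, from the line–sphere quadratic)
  is reported alongside, since "depth" could mean either surface.
- Squared distances are used internally; roots are taken for reporting.

Tiers map to fixed tone frequencies {0: 200 Hz, 1: 350 Hz, 2: 440 Hz}.
`run_session` replays a pose stream at a fixed rate (default 20 Hz, the
update rate of the guidance loop), evaluating the most recent pose at or
before each tick, emitting one alignment result and one tone event per tick
with transition markers; a 1 s stream at 20 Hz yields exactly 20
evaluations. Tone events are the product; WAV rendering is a convenience.

## Phantom simulator

The synthetic evaluation phantom places the 4 mm-radius target concentric in
an 8 mm-inner-radius hollow sphere with notch markers at ±9.5 mm along a
chosen axis (separation 19 mm, midpoint at the centre — both enforced as
construction invariants). Tracking noise is zero-mean Gaussian with
σ = 0.25 mm per translation axis, the manufacturer-quoted intrinsic error of
the tracker; rotational noise is off by default (the quoted figure is a
single translational scalar) but configurable in radians. Speckle is
multiplicative unit-mean log-normal (σ = 0.3 by default) — enough to
exercise the detector; attenuation, shadowing, beam width and the shell wall
are deliberately not modelled, so passing tests demonstrate the geometric
chain and the detector's robustness to multiplicative noise, not performance
on real B-mode anatomy. The renderer maps every pixel to world coordinates
through the calibration chain and compares against the sphere, and returns
the analytic projection of the in-plane disc centre as ground truth; the
chain is exactly invertible, so feeding the analytic centre back through
registration recovers the scene centre to 1e-6 mm. `simulate_trial` renders
from the true probe pose but registers with the noise-perturbed pose — the
tracker error enters exactly where it does in the physical system.

## Accuracy evaluation

`evaluate_table` reproduces the phantom analysis: reference centre =
marker midpoint; per-trial Euclidean deviation; mean position E; surgical
deviation = distance from E to the reference; hit count = trials whose
measured centre lies within the target radius (4 mm), i.e. inside the
target. Two rounding conventions matter and are implemented explicitly,
half-away-from-zero in both cases:

- The reference centre is rounded to 2 decimals (the precision at which
  tracker coordinates are reported) before deviations are taken; this is
  the arithmetic path that reproduces the shipped deviation column to
  4 decimals, and `reference_decimals=None` disables it.
- The surgical deviation uses E rounded to 1 decimal; the exact mean gives
  ≈ 2.488 mm instead of 2.5287 mm and is available via `unrounded=True`
  (`--unrounded` on the CLI).

The suite checks that deviations form a metric, that the hit count is
monotone in the radius, and that the whole analysis is invariant under a
common rigid motion of points and markers.

## Problem sizes and determinism

Default test/analysis sizes: 128×128 frames with 0.1 mm/px spacing, 5–100
fiducials, 30–50 pivot poses, 100 Monte-Carlo trials, 1000 oracle
configurations — sizes at which every closed-form recovery is
machine-precision and the stochastic bands are stable across seeds. All
randomness flows through explicit `numpy` generators seeded per operation;
identical seeds reproduce identical trials, streams and frames.

## Known limitations

No temporal (latency) calibration between image stream and tracker; no
speed-of-sound correction; no needle bending; no multi-lesion tracking; the
simulator's speckle is not a physical scattering model. The classical
detector assumes a single dominant hypoechoic blob with closed, roughly
circular shape — real anatomy needs the network backend.
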