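# Methods

This note records the models, parameter choices and numerical conventions
behind `fjordcam`, and what the synthetic experiments do and do not
demonstrate about real deployments.

## Synthetic deployment model

**Tide.** A single M2 constituent, level(t) = mean + A(t)·sin(2πt/T) with
T = 12.42 h, modulated by a sinusoidal spring–neap envelope of period
14.8 days: A(t) = amp·(1 − m·(1 + cos(2πt/T_sn))/2). The series starts at
the envelope minimum (neap), matching the deployment conditions the
generator emulates. Defaults: amp = 0.75 m (spring peak-to-trough 1.5 m),
m = 0.5, 60-s sampling. A single constituent is the minimal model that
produces semidiurnal reversal and a fortnightly range cycle; no constituent
mixture or phase lags are attempted.

**Scenes.** Frames are 8-bit RGB on a dark, red-dominant base
(R ≈ 12, G = B ≈ 2) emulating red-LED illumination at depth. Static
structures — a 3-px diagonal line (mooring rope) and a bright ellipse
(reflective recorder end-cap) — are identical in every frame. Particles are
Gaussian-profile discs, radius 1–4 px, peak brightness 80–255 added to the
red channel with a 15 % leak into G/B; per-particle radius and brightness
are fixed at birth. The per-segment particle count is one Poisson draw at
the configured density (default 85, the scale of a VGA seafloor scene);
particles persist within a segment — which is what gives PIV its
frame-to-frame correspondence — and are re-injected at the upstream edge
when they exit. Per frame, all particles advect by a spatially uniform
displacement flow_gain · dη/dt along the configured flow axis (default
20 px/frame per m/h along 90°, i.e. up-fjord image-up) plus independent
Gaussian jitter (σ = 0.3 px). Additive Gaussian pixel noise (σ = 3) is
applied before clipping to uint8. Elongated "fiber" particles exist behind
an off-by-default flag; their geometry is a design placeholder, not a site
estimate — as are the particle size and brightness distributions generally.

The generator renders only the frames the measurement stages consume
(default: the first 10 frames of each scheduled segment, the same number
analyzed per file downstream). Rendering full 10-minute files (18,000
frames each) is configurable but serves no measurement purpose.

**Ground truth** records, per frame: the particle count and positions, the
imposed (u, v) displacement, the true foreground area (pixels whose
particle-layer contribution exceeds 20 intensity counts — the same level the
matched-threshold recovery tests binarize at), the static-structure mask and
the anomaly log.

**What the scenes do not model:** perspective and defocus, turbidity and
light scattering, particle size/brightness distributions of any real site,
vertical or vortical motion, shear between near and far particles, animals.
Passing recovery tests therefore demonstrates the correctness of the
measurement implementations under the stated imaging model, not field
accuracy on real footage.

## Particle quantification

Background is the per-pixel temporal median over the segment's analyzed
frames (minimum window 3). Frame 0 is excluded from the background and from
segment summaries: the switch-on brightness spike is an instrument
artifact. The residual is max(gray(frame) − background, 0), where gray is
the red channel at the seafloor (the illumination is red; G/B carry almost
no signal) and luminance for descent footage.

Binarization is Otsu's threshold on the residual with a floor of 10/255 —
the floor prevents noise-only splits when no particle is present — or a
caller-supplied fixed threshold. Components use 8-connectivity with a
2-pixel minimum (single-pixel noise rejected); touching particles count as
one component, with no watershed splitting. The mean RGB triplet is computed
on the original frame, not the residual. Count and area are invariant under
adding a constant to both frame and background, and match an exhaustive
flood-fill enumeration on small frames (tested).

Anomaly flags operate on the per-frame feature series:

- FIRST_FRAME — frame 0's mean red exceeds the median of the rest by 5
  robust (MAD·1.4826) deviations.
- ATTACHMENT — area fraction elevated ≥ 3 robust deviations above the
  segment median for at least `glow_window` (default 30) consecutive frames
  while the largest component's centroid drifts < 25 px.
- GLOW — mean red rises over ≥ `glow_window` frames by more than
  max(10·σ_step, 2 counts), where σ_step is the robust SD of successive
  differences (so a slow ramp does not inflate its own threshold), with no
  single step contributing half the rise (a step is an attachment, not a
  glow) and no matching rise in particle count. The flagged run starts where
  the rise first clears the step noise.

Display smoothing uses a centered sliding median (3 h over the 20-min
segment cadence = 9 taps; shrinking windows at the edges).

## DPIV

Per interrogation window, both windows are mean-subtracted; the cyclic FFT
cross-correlation's peak (searched within the central third of the plane,
an implicit dynamic-range limit of ±w/3 px) gives the integer displacement,
refined per axis by a 3-point Gaussian fit on the log-correlation.
Windows with near-zero variance or a non-positive peak are invalid. The
first-to-second peak ratio (3×3 exclusion around the peak) is kept per
vector. Multipass refinement (window halving, second-frame windows offset
by the rounded previous-pass field) is available.

Defaults: 64-px windows, 50 % overlap, **one** pass. At the seeding density
of this footage (~85 particles per VGA frame ≈ 0.3 particles per 32-px
window) a 32-px final pass yields mostly ambiguous correlations; a single
64-px pass with quality filtering is markedly more accurate here, so that
is the pipeline default, with multipass exercised in tests on densely
seeded fixtures.

Validation rejects vectors with peak ratio ≤ 1.2, then applies the
normalized median test against the 8-neighbourhood (residual over median
neighbour fluctuation + ε, ε = 0.1, threshold 2.0, combined over u and v).
No in-fill: rejected vectors stay rejected.

The dominant flow of a segment is the arithmetic mean of valid vector
magnitudes × fps (speed, px/s — no px→m calibration exists, camera geometry
unknown) and the circular (resultant-vector) mean of vector angles
(direction, degrees CCW from image +x with y up; image rows are flipped
before angles are taken). Naive angle averaging would fail across the 0/360
wrap. A segment with zero valid vectors yields a flow marked *missing*,
never zero — slack water legitimately produces these when particles stop
moving and are absorbed into the background.

## Tidal coupling

Sea-level rate is the central finite difference of level in m/h, smoothed
by a centered 2-h sliding median (the display smoothing of features uses
3 h; both are configuration). Rates are linearly interpolated to flow
timestamps; missing flows are dropped, never imputed. The circular flow
direction is linearized for Pearson correlation by projecting onto the
deployment's flow axis — signed angle in (−180°, 180°], or equivalently the
signed speed s·cos(θ−θ_axis). The axis is estimated as the circular mean of
doubled angles (axial statistics, mod 180°), oriented toward the sample's
circular mean direction; in the synthetic recovery experiment the
generator's configured axis is used directly, since it is ground truth
there. p-values are two-sided from the t distribution, with no
multiple-testing correction (two correlations are reported).

Periodograms are raw (no taper, no detrend beyond the caller's), with
frequencies in 1/h and per-ordinate 95 % intervals from the χ²(2) sampling
distribution: [2P/χ²₀.₉₇₅, 2P/χ²₀.₀₂₅]. Coverage of a known flat spectrum is
verified by Monte Carlo in the tests.

## Recovery experiment design

`simulate_and_recover_flow` renders a 3-day deployment at 20-min cadence
(216 segments) and runs the full measurement chain per segment. To make
hundred-replicate experiments cheap the scenes are scaled down — 128×96 px,
3 frames per segment (2 PIV pairs), expected 40 particles per frame
(≈3 particles per 32-px window, adequate seeding), one 32-px pass — which
preserves the pipeline structure while running in a few seconds per
replicate. Across seeded replicates the sign of r(rate, signed flow) and the
~180° rising/falling direction separation are stable (tested over 100
replicates); the magnitude of r under these conditions (~0.95) reflects the
generator's high coupling and low noise, and is not a prediction for field
data, where the corresponding correlations are far weaker.

## Descent profile

Depth of frame k is rate·(k − k_drop)/fps, rate = bottom depth / descent
duration; the drop frame is a manual/config input (an optional
blue-decline heuristic exists but is never applied silently). Default depth
bin 1 m (≈16 frames per bin at 1.84 m/s and 30 fps). The reported
colour-transition depth is the shallowest bin below which both G and B
means stay under a configurable floor (default 5 counts) in every deeper
filled bin; the floor is a reporting choice, not a physical constant. Empty
bins are NaN, never interpolated.

## Acoustics

Each 10-s time bin averages Welch spectra (Hann, 1024-point FFT, 50 %
overlap, density scaling) and is restricted to 20 Hz–43 kHz (clipped to
Nyquist with a warning). Mean aggregation per bin is the default (median
would be the robust alternative). Power is dB re digital full scale; no
hydrophone sensitivity is applied, so absolute levels are uncalibrated.

## Detections

Taxon labels are normalized case-insensitively through a common-name alias
map (e.g. "snailfish" → Liparidae). Percentages round to integers; the mean
detection interval divides *recorded* video hours (not deployment
wall-clock) by the number of detections. Track kinematics apply no
smoothing: step speed is the Euclidean step length over the step's frame
interval.

## Orchestration and determinism

`run_simulate` writes a bundle (PNG scenes + sidecars, truth CSV, tide and
sensor CSVs, WAV audio, detection CSV, config YAML) and a manifest of
SHA-256 checksums; a rerun with the same seed is verifiably identical. The
bundle's detection table scales its row count with recorded hours at
roughly one detection per five minutes. `run_analyze` logs and skips a
failing segment rather than aborting, and fails only when no segment is
readable. All analysis stages are deterministic given the inputs.

## Known limitations

- No px→m velocity calibration; speeds are comparative only.
- Touching particles merge; counts are component counts, and fibers (when
  enabled) count as single particles.
- The attachment/glow flags are tuned to the generator's anomaly shapes;
  real lens fouling is more varied.
- Container decoding depends on an imageio backend being present; the PNG
  directory format is the only fully supported round-trip.
- The synthetic tide has one constituent; phase relationships between flow
  and level beyond simple proportionality to dη/dt are out of scope.
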