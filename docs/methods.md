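# Methods

This note documents the models behind `flossguard`, the parameters that
matter, the design choices made where the physical system leaves the design
open, and what the synthetic tests do and do not demonstrate.

## 1. Emission model

Each material's fluorescence under a given UV excitation is a sum of
Gaussian components in wavelength:

    I(λ) = Σ_k  A_k · exp( -4 ln2 · (λ − c_k)² / w_k² )

with center `c_k` (nm), full width at half maximum `w_k` (nm), and
amplitude `A_k` in spectrum-analyzer counts.  Amplitudes share one scale
with the abnormality criterion of 10,000 counts.  Spectra are evaluated on
a uniform 400–800 nm grid at 1 nm (configurable); peak lookup returns the
grid argmax with ties broken toward the shorter wavelength.

The packaged library (`data/fluorophores.yaml`, versioned) covers four fish
species × {raw, steamed, floss} plus their bones, calcium carbonate powder,
human fingernail, and three glove plastics, each with 310 nm and 365 nm
entries.  A requested excitation snaps to the nearest packaged entry within
30 nm; anything farther is an error naming the available excitations.

Component values are a frozen calibration, not measurements: they were
chosen once so that the library jointly reproduces the known qualitative
behaviour of these materials —

- every bone peaks at 410 nm under UVB and exceeds 10,000 counts in the
  400–500 nm band;
- meats and floss peak at 560 nm under UVB with sub-threshold short-band
  intensity, except the calcium-rich raw fillets (salmon 7, cod
  16 mg/100 g) whose peaks move into the short band;
- of those two, only raw cod carries appreciable intensity at 405 nm, so
  only raw cod registers on the imaging side — raw salmon's short-band peak
  sits near 490 nm, far outside the filter window;
- under 365 nm UVA everything peaks at 560 nm;
- the bone-vs-floss integrated contrast for swordfish is maximal in the
  400–410 nm window (this constrains the floss model's weak violet shoulder
  at 430 nm and the bone peak's width).

Calcium contents: meats use published-range values (swordfish 4, tuna 5,
salmon 7, cod 16 mg/100 g; steamed/floss states carry reduced values since
cooking leaches calcium), bones 18–26 g/100 g, calcium carbonate
39.2 g/100 g, fingernail 0.1 g/100 g.  The band predicted from composition
(`expected_band_from_calcium`) is SHORT for bone/powder/fingernail/plastic,
SHORT for raw meat at ≥ 6 mg/100 g, LONG otherwise.  Band intervals are
half-open ([400, 500), [500, 600)) so classification is exhaustive and
unambiguous.

## 2. Filter and in-band signal

The camera filter defaults to 405 nm center, 10 nm FWHM, peak transmission
0.9, with a Gaussian profile (which satisfies the half-maximum-at-edge
definition exactly); a rectangular profile is selectable.  The scalar that
drives pixel values is the trapezoidal integral of the transmitted spectrum
over the grid (counts·nm).  At 1 nm resolution this agrees with a 0.1 nm
Riemann sum to well under 1% for every packaged material.

## 3. Scene generator

A scene is rendered at 0.125 mm/pixel by default.  This pitch makes the
smallest bone of interest (1 mm × 5 mm, drawn as an ellipse) cover ≈ 250
pixels — just above the detector's 200-pixel area rule — while a 1–3 mm
floss grain stays far below it; the real system's magnification is not
public, so the pitch is a documented assumption chosen to make the area
rule meaningful at the plant's stated bone sizes.

Per-pixel signal is additive:

    pixel = floss_background + Σ_objects exposure_fraction · S(material) + ε

where `S` is the in-band signal scaled by 0.1 counts per count·nm (placing
a fully exposed bone near 40% of the 16-bit scale and the floss layer near
3%), and ε ~ N(0, 100 counts).  The floss layer is the floss material's own
in-band signal modulated by a smoothed, unit-variance granularity field
(texture scale 2 mm, relative amplitude 0.35); outside floss regions the
black vinyl sheet is mean 0.  Values are clipped at zero and full scale and
quantized to 16 bits (8-bit selectable).  Coverage is a scalar
`exposure_fraction` multiplying the signal — the physical process treats
bones as exposed or covered, and the scalar generalizes that binary state.
Rendering is a pure function of (scene, seed): frames are bit-identical
across repeated renders, and raising an object's exposure never lowers any
pixel.

Ground truth labels an object `expected_detectable` when it is exposed, its
rendered area strictly exceeds 200 px, and its exposure-scaled signal
clears the background by 5 noise standard deviations plus the texture
amplitude.  On the canonical fixture suite the detector's hits equal these
labels exactly, which is the generator/detector contract the test suite
enforces.

What the generator does **not** emulate: optics (blur, vignetting,
perspective), motion blur of vibrating material, depth-dependent absorption
or scattering in the floss layer, specular reflections, and spatially
varying illumination.  Passing tests therefore demonstrate the correctness
and self-consistency of the detection logic under the stated signal model,
not performance on real camera frames.

## 4. Detector

The pipeline follows the camera firmware's order: grayscale (BT.601 weights
for multichannel input), ×4 linear enhancement with rounding and clipping
at full scale (real sensors saturate), global threshold, bright-region
extraction.  Thresholding is Otsu's criterion computed exactly on the
integer histogram (the level maximizing between-class variance of the
{v ≤ t}/{v > t} split, first maximum on ties, so the result is
deterministic); a fixed-level dialect is available.  Regions are
8-connected by default (bones are compact; 4-connectivity is configurable),
the area rule is strict (> 200 px), bounding boxes are tight, 0-based,
half-open, and overlapping markers are never merged.  A constant frame is
flagged degenerate.

Otsu always proposes a split, including on frames containing only floss
texture, where roughly half the pixels would land above the level and
percolate into one giant false region.  The detector therefore rejects a
frame as foreground-free when the proposed split's *class contrast* — the
gap between foreground and background class means as a fraction of full
scale — falls below `min_contrast` (default 0.15).  On generator scenes,
background-only frames score ≤ 0.07 (floss texture) and ≤ 0.01 (dark-frame
noise, weak raw fillets), while the weakest genuine signal (a rubber glove
finger) scores ≈ 0.39 and bones ≈ 0.89, so the floor sits with better than
a two-fold margin on both sides.  A global variance-ratio guard (Otsu's
separability measure) was considered and rejected: it penalizes small
bright objects, whose few pixels contribute little between-class variance
against frame-wide texture, and would miss the smallest bones.

The 10,000-count spectral criterion and image-domain thresholds are
deliberately decoupled: the first lives on the spectrum-analyzer scale, the
second on the camera scale, and no counts-to-gray conversion is assumed.

## 5. Workstation simulation

Time advances in imaging passes; there are no real waits.  A run of
`run_full_test(n_bones, floss_g)`:

1. partitions the mixture into ⌈floss_g / 300 g⌉ scoops (300 mL dipper,
   bulk density 1 g/mL assumed) and assigns bones to scoops multinomially
   by scooped mass — the mixing process is not described physically, so
   uniform-by-mass is the natural null model;
2. draws the per-test downstream-exposed count uniformly from
   [1, min(5, n_bones)] and marks those bones exposed when their scoop is
   poured (the physical tests always surfaced between one and five bones
   downstream, with no finer statistics to fit);
3. on each vibrating step, advances material one stage
   (upstream → under box → collection box) and air-exposes every
   not-yet-air-exposed bone under the box with probability `p_air_expose`
   (default 1.0 — the physical air separation exposed every bone in every
   test; lower values enable sensitivity studies);
4. renders the under-box region (320 × 320 px; exposed bones at exposure 1,
   covered at 0, floss layer always present) and runs the detector;
5. stops the motor iff markers are present (the controller is a pure
   function of the detection result), removes every bone whose ground-truth
   box intersects a marker — except that with `p_inertial_loss` a detected
   bone slides off the plate into the collection box first — and restarts
   when the markers are gone.

Bone sizes are drawn uniformly from the plant's stated range (width
1–10 mm, length 5–20 mm), so every rendered bone clears the area rule at
full exposure.  Accuracy counts *detection*, not retention:
`accuracy_pct = 100 · detected / total`, with inertially lost bones still
counted as detected (they were found; they just could not be grabbed).  A
zero-bone run reports accuracy as undefined rather than 0 or 100.  All
randomness derives from the run seed through five named substreams
(mixture, downstream, air, scenes, removal), so reports and timelines are
exactly reproducible.

Separation efficiency is `Ia/I0` with `I` the mean in-band pixel intensity
over the bone mask on noise-free renders; the ratio is clamped to 1 with a
warning when measurement noise pushes it above.  Under the noise-free
generator the measured efficiency equals the exposure fraction up to
quantization.

## 6. Problem sizes and runtimes

The shipped configuration is the plant-scale test itself: 20 bones in 2 kg
(seven scoops, ~20 imaging passes of 320 × 320 px), which simulates in
under 0.2 s, so the ten-repetition study and the seed-robustness scans in
the test suite are cheap.  Fixture scenes are 512 × 512 px.  No quantity in
the package is precomputed; every reported number is recomputed at call
time.

## 7. Known limitations

- Spectral curves are calibrated to qualitative facts (peak positions,
  threshold crossings, contrast window), not to digitized spectra; absolute
  counts between materials are plausible but invented.
- The counts-per-signal scale, noise level, and texture amplitude of the
  generator are stylized; the detector's contrast floor is calibrated to
  this family of scenes and would need re-calibration against real frames.
- The plate model has no granular physics: exposure is Bernoulli, transport
  is a three-stage pipeline, and scoop timing is event-based.
- Operator behaviour is reduced to instantaneous removal with an optional
  loss probability; glove/hand imaging during removal is not simulated
  beyond markers keeping the motor stopped.
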