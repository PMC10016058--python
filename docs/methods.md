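# Methods

## The measurement being emulated

Transcranial intrinsic-signal imaging records the small (~0.1–1 %)
darkening of active cortex under red illumination. Presenting pure tones
at 3, 10 and 30 kHz evokes spatially localised reflectance decreases in
each tonotopic field of auditory cortex; imaging through the intact
skull, together with three ink marks placed at known stereotaxic
coordinates, lets the functional map be expressed in millimetres from
bregma and compared across animals and against an atlas parcellation.

The analysis chain is: per-trial fractional-change images → trial
average → Gaussian filter (σ = 2 px) → Richardson–Lucy deconvolution
against a 2-D Gaussian hemodynamic point-spread (σ = 200 µm) → seeded
parcellation into frequency domains and areas → mark-based registration
into stereotaxic coordinates → population statistics on a shared 10-µm
raster grid.

## The synthetic forward model

Each synthetic animal is a `GroundTruthLayout`: twelve frequency-domain
centres (four areas × three tones) drawn from a canonical geometry that
encodes the field's identification rules — A1's low→high gradient runs
rostrodorsally, VAF's rostroventrally, AAF's caudoventrally, A2 sits
between VAF and AAF with a weak ventral gradient, and the A1 and VAF
3-kHz domains converge at their low-frequency poles. Per-animal
variation comprises:

| parameter | default | rationale |
| --- | --- | --- |
| whole-cortex translation SD | (300, 150) µm (AP, DV) | inter-animal position scatter of the functional map relative to bregma |
| strain AP shift | CBA −0.285 mm | CBA maps sit posterior of B6 |
| axis rotation | N(0.370, 0.011) rad, posterior down | orientation of the imaged plane |
| bregma–lambda distance | N(4.2, 0.15) mm | skull-size variation around the reference skull |
| A1–AAF border gap | N(250, 150) µm, clipped ≥ 0 | controls whether a tone low-responsive centre region (CTR) fits between A1 and AAF |
| domain Gaussian σ | 110 µm | compact tone domains ~220 µm across at the 60 % level |
| per-domain amplitude jitter | ×U(0.8, 1.2); area scale A1 1.0, AAF 0.9, VAF 0.75, A2 0.65 | A1 strongest, A2 weakest |

Domains are isotropic Gaussian bumps (peak = centre of mass, so the
ground-truth centroid is analytically known), rendered as reflectance
*decreases*, convolved with the hemodynamic blur (σ = 200 µm), modulated
by a gamma-shaped time course peaking 1.5 s after tone onset, and
embedded in trials (1 s baseline, 1 s tone, 16 Hz, 48 frames) with
i.i.d. per-pixel Gaussian noise.

Acquisition defaults are a scaled-down 3.3 × 3.3 mm field of view at
256 × 256 px (12.9 µm/px), 16 trials per tone, response amplitude 0.3 %
and per-frame noise SD 0.5 %. The trial count sits in the conventional
6–20 range and represents a session in which every frequency domain is
clearly visualised — the inclusion standard for this kind of mapping;
image size is chosen so the full studies run in minutes on one CPU while
keeping the pixel (12.9 µm) far below the effects measured (hundreds of
µm). Problem sizes used by the validation studies: 50 mice for recovery,
41 for the population study, 40 × 50 layouts and 1 500 mark pairs for
the closed-form checks.

**Skull-mark error model.** The marking procedure aligns the head in a
stereotaxic frame and then places three dots with a motorised
manipulator. The manipulator's relative positioning is far more precise
than the human identification of bregma/lambda, so the human error is
modelled as a *common* translation of the whole mark triplet (SD
`human_error_sd_um`, default 100 µm per axis) plus an optional
independent per-mark term (default 0). Every closed-form property of the
error metric (mean per-axis |Δ| = 2σ/√π between two markings) is
unchanged by this choice, but its consequences are physical: rotation
and scale recovered from the marks are essentially exact, while absolute
coordinates carry a coherent ~100 µm offset per animal.

### What the generator does not emulate

Vasculature, breathing/motion artifacts, awake-state hemodynamics,
skull-curvature distortion of the marks, non-Gaussian domain shapes, and
spatially correlated noise. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated model,
not the biological fidelity of intrinsic signals themselves.

## Numerical and design choices

* **Richardson–Lucy.** Own FFT implementation with exactly reflective
  boundaries (the image is mirrored to 2H × 2W and convolved
  circularly, so a flat image is an exact fixed point) and a
  per-iteration convergence log. The module default is 20 iterations;
  the pipeline driver uses 60, because at 20 iterations the residual
  blur biases the centroids of neighbouring domains ~100 µm at
  350–400 µm separations, while 60 iterations resolve them to <25 µm on
  noiseless fields. Intrinsic responses are negative, so maps are
  negated and clipped at zero before deconvolution (the algorithm
  assumes a non-negative intensity model) and restored afterwards. A
  mild post-deconvolution low-pass (σ = 2 px) damps the pixel-scale
  noise that the iterations amplify.
* **Seed ROIs.** Drawn manually in the real workflow; the automatic
  proposer emulates that step by hierarchical template matching: a
  whole-map translation is estimated from strong response peaks
  (Hungarian assignment, iteratively with a wide then a tight gate),
  each area's own shift is refined from an isolated anchor domain
  (AAF's anchor box is AP-asymmetric because the A1–AAF gap moves all
  AAF domains together), and every domain's seed is the map maximum in
  a 260-µm stereotaxic box around its predicted position (110-µm disk
  ROI). When the converged A1/VAF 3-kHz pair forms a single blob, the
  two seeds share it: the weaker template's ROI is placed at its
  anchor-predicted pole and both ROIs are clipped to half-disks facing
  away from each other — unless a re-search finds a genuine second
  local maximum with a clear saddle between the peaks.
* **Morphology.** Disk opening/closing via Euclidean distance
  transforms (erosion = EDT > r), exact for disk elements and fast at
  the 150-px closing radius; closing pads the frame so the intermediate
  dilation is never clipped. Radii are defined at the reference pixel
  scale (3.21 µm/px) and rescaled to the working grid.
* **Dividing lines.** Amplitude-weighted splits are placed perpendicular
  to the centroid–centroid segment (the orientation is otherwise
  unspecified); the inter-area split uses the chord through the two
  outline intersection points, falling back to the amplitude-weighted
  line (logged) when the outlines cross more than twice; masks are
  clipped to half-planes, documented behaviour when the chord exits the
  union. A1/VAF overlap is never removed.
* **DP/CTR.** Computed after rotation into stereotaxic axes, so
  "dorsal"/"posterior" are well defined. CTR is bounded by the convex
  hull of the four tonotopic masks, the iso-DV line through A1's most
  dorsal point, and a total-least-squares fit to the AAF tonotopic axis
  (keeping the A1 side); an empty CTR is a valid result.
* **Thresholding order.** The 60 %/40 %/20 % thresholds are applied to
  the deconvolved (and mildly re-smoothed) map; this is configurable.
* **Registration.** Adjusted mark 2 is the foot of the perpendicular
  from mark 1 onto the mark 2–3 line; the frame is rejected if the raw
  segments meet outside 80–100° or with flipped handedness. Scales are
  set by the known scaled mark spacings, so mark 1 maps exactly onto its
  scaled nominal coordinates. B–L normalization multiplies AP by
  4.2/BLdist (lambda lands at −4.2 mm for every animal); DV is never
  rescaled.
* **Masks to millimetres.** Mask outlines are traced at sub-pixel
  precision and mapped as polygons through the affine transform (no
  raster resampling), then rasterized onto the shared 10-µm analysis
  grid for overlap statistics; polygon and raster kernels agree to
  within a perimeter's worth of cells and both are exposed.
* **Statistics.** Cross-animal mask overlap uses ordered pairs (n mice
  → n(n−1) pairs); centroid distances use unordered pairs, with the
  realized pair count reported when domains are missing. Variance
  decomposition is sequential (Type I) ANOVA in the order strain, sex,
  age (age continuous), so factor shares plus the residual sum exactly
  to 100 %; constant factors are kept with a zero share; a Type III
  option exists. Rank-sum p-values are exact for small tie-free samples
  and normal-approximate otherwise, multiplied by the Bonferroni count
  and capped at 1. Per-mouse fractions are summarised with SEM over
  mice, not pairs.

## Validation studies and their logic

* **Recovery (50 mice, noise and 100-µm marking error on).** Every
  rendered domain is scored by mapping the recovered centroid and the
  true centre through the *same* fitted transform; the coherent
  mark-offset cancels, so the score isolates segmentation + registration
  accuracy. Rotation errors are reported per mouse.
* **Closed forms.** The pairwise-distance statistic of an n = 50
  population with pure translation jitter has ~11 % relative SE in a
  single draw, so its *expectation* is estimated by averaging over 40
  replicate populations; the marking-error metric is averaged over
  1 500 animals. Both are compared against 2σ/√π.
* **Population study (41 mice).** The full chain against the synthetic
  atlas. The resulting numbers (centroid variability of a few hundred
  µm along AP, ~200 µm along DV; classification accuracy well below
  100 %; targeting accuracy far below classification accuracy) show the
  same qualitative structure as real atlas-vs-function comparisons; the
  absolute overlap percentages depend on the synthetic atlas geometry
  and the compact synthetic areas and are not calibrated to any real
  dataset.

## Known limitations

* Finite-iteration deconvolution slightly repels closely spaced
  domains; at the default geometry this bias is ≪ the 50-µm reporting
  tolerance, but it grows quickly once domain σ approaches half the
  inter-domain spacing.
* In ~2 % of synthetic animals, noise inflates a weak domain's ROI-peak
  estimate enough that its 60 % mask shrinks below the opening radius
  and an area mask comes out empty; all population statistics handle
  absent areas gracefully (NaN rows, skipped pairs, logged), mirroring
  how real sessions with undetectable domains are treated.
* Extreme whole-map translations (>3σ) can defeat the template
  matcher's gates; such animals keep whatever domains were matched.
* The shipped atlas table is synthetic: comparisons against it validate
  the machinery, not any real atlas's accuracy. Real border tables with
  the same schema are accepted by `tonomap.atlas.load_section_table`.
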