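# Methods

This note documents the models, parameter choices and numerical conventions
behind each pipeline, what the synthetic generators do and do not emulate,
and the design decisions taken where the underlying protocols left the
implementation open.

## Eye-specific segregation (`neuroquant.segregation`)

**Procedure.** A two-channel dorsal-LGN image (ipsilateral, contralateral;
8-bit scale) is optionally background-subtracted with a rolling ball, then a
single ipsilateral mask is formed at one threshold (default 40, admissible
35–45) inside a hand-drawn dorsal-LGN outline. The contralateral threshold t
is swept over levels 0–150 in steps of 5; at each level the fraction of
ipsilateral mask pixels not covered by the contralateral mask is the
*fraction of segregated ipsilateral inputs*. Because contralateral masks are
nested in t, the curve is non-decreasing — this is asserted, not enforced.

**Conventions.**
- The 0–150 sweep is read as intensity levels (thresholds apply to 8-bit
  intensities, so "pixel steps" can only mean intensity steps).
- The rolling-ball parameter is the ball *radius*, default 100 px (a
  200-pixel ball diameter); it is configurable because protocols citing a
  "radius filter set to a diameter" are ambiguous.
- Zero-valued pixels never enter a contralateral mask. On
  background-subtracted images the background is exactly zero, so the t = 0
  point measures overlap with the labeled contralateral region rather than
  trivially with the whole outline.
- ROI polygons use 0-based (row, col) pixel coordinates rasterized with
  scikit-image's polygon filling; masks are therefore deterministic.
- Quality control: the ventral LGN receives no contralateral retinal input,
  so the mean contralateral intensity in a ventral ROI divided by the mean
  outside the LGN outline must not exceed `qc_tolerance` (default 1.5; the
  underlying requirement, ventral fluorescence comparable to background, is
  qualitative, and a concrete default makes it testable). Failing images
  are rejected.
- Whether background subtraction preceded ROI cropping is unknowable from
  the protocol; here subtraction operates on the full image, cropping after.
- Group comparison (`compare_curves`) averages animal-level curves per group
  and delegates a two-factor (group × threshold) ANOVA to statsmodels OLS;
  animals are the replication unit.

**Generator.** Scenes render two elliptical territories, the ipsilateral one
displaced horizontally until the rasterized overlap-to-ipsi-area ratio hits
the requested fraction (48 bisection steps on the pixel masks, so achieved
overlap is exact at pixel resolution and emitted with the scene). Signal
defaults: ipsi 180, contra 120, background 3, Gaussian noise SD 2 — bright,
well-separated labeling typical of lipophilic-dye fills. The bottom 15% of
the image is a reserved background-only ventral strip for QC. The generator
does not emulate optics (no point-spread blur), dye bleed-through, or
section-to-section registration; recovery tests therefore show correctness
of the measurement, not robustness to those artifacts.

## 3D engulfment (`neuroquant.engulfment`)

**Procedure.** Two-channel confocal stacks (astrocyte marker, synaptic
marker) at anisotropic voxels (defaults 0.12 µm z, 45 nm xy):

1. per-channel robust-percentile normalization to [0, 1]; the puncta channel
   gets particle sharpening (0.05-µm Gaussian denoise then an unsharp mask,
   radius 0.135 µm, amount 1 — all scales physical, so kernels are
   anisotropic in voxels); the astro channel gets a 0.09-µm Gaussian.
2. per-voxel three-class labeling: a random forest (sklearn, features = raw
   intensity, local Gaussian mean, local SD and gradient magnitude at 0.09
   and 0.27 µm for both channels) trained on annotated z-sections, or a
   deterministic per-channel threshold fallback (default 0.5/0.5; puncta
   take precedence when both channels pass). Synthetic validation uses the
   fallback so results do not depend on training variance.
3. astro cleanup: one erosion with the 6-connected cross (a minimal z-aware
   element counteracting z-stretching), morphological closing, then removal
   of components under 10 µm³ (closing alone cannot remove whole
   components, so the volume filter is explicit).
4. puncta: 26-connected components filtered to 0.01–1 µm³, the presynaptic
   bouton volume range (a figure-legend paraphrase in diameters is treated
   as secondary to the operational volume window).
5. engulfment: in a single-label segmentation, engulfed puncta are holes in
   the astro label; the *astro interior* is therefore the hole-filled astro
   mask, and a punctum voxel counts as inside when its Euclidean distance
   (physical units) to the interior is ≤ `distance_tolerance_um` (default
   0 — whether a positive tolerance was used originally is not stated, so
   the strictest reading is the default and the parameter is exposed). A
   punctum is *fully engulfed* when every voxel passes; the report carries
   the fully-engulfed count, astro volume, astro % of stack volume and
   engulfed puncta per µm³ of astro mask.

Hole-filling makes the interior monotone under astro-mask dilation, so
engulfment fractions can only grow when the mask grows. One consequence of
the single-label construction: a punctum straddling the astro surface
carves an open bite, is not enclosed, and scores fraction ~0 rather than
its geometric overlap; this does not affect the fully-engulfed count, which
is the quantity reported.

Surface meshes use marching cubes at the 0.5 isosurface with physical
spacing; the binary indicator is pre-smoothed by 0.8 voxels because the raw
staircase overestimates curved areas (a 1-µm sphere meshes to within 0.3%
of 4π with smoothing versus ~9% error without; tiny objects whose smoothed
peak falls below the isolevel fall back to the raw indicator).

**Generator.** The arbor is a connected union of capsules (main tube radius
1.3 µm plus a branch), rasterized at the true voxel size. Puncta are
spheres planted *inside* the arbor (≥ 0.85 µm clearance), *straddling* its
surface (center on the surface, hence ~half the voxels inside), or
*outside* (≥ 2 voxels clear of the arbor), with radii 0.18–0.4 µm in the
bouton window plus planted out-of-window objects (≈ 0.003 µm³ and
≈ 1.44 µm³). A 4-µm³ distractor blob exercises the astro volume filter.
Ground truth (rasterized volume, voxel-exact engulfment fraction) is
computed from the masks before noise and validated against the planted
class — an inconsistent plan raises rather than emitting wrong truth.
Noise is white Gaussian at SD = level/SNR per channel; there is no
point-spread anisotropy, autofluorescence or intensity gradient, so the
SNR-5 recovery demonstrates tolerance to sensor-like noise only. Test and
validation stacks are 48×160×160 voxels (5.8 × 7.2 × 7.2 µm), sized so that
twenty full-pipeline runs remain a desk-scale computation.

## LFP spectra and coherence (`neuroquant.lfp`)

**Conditioning.** Second-order Butterworth band-stops (±2 Hz, the protocols
state only center frequencies) at 50/100/150/200 Hz at the raw rate
(20 kHz), FIR anti-aliased downsampling to 2 kHz (`resample_poly`; rational
factors with a warning when the ratio is not integral), then a second-order
Butterworth band-pass 0.5–500 Hz. All filtering is zero-phase
(forward–backward), standard for coherence work because cross-site phase
must be preserved; "second-order" refers to the designed section and the
effective attenuation is doubled.

**Epoching.** One candidate window per trial: 5 s ending 0.5 s before the
reward. A window is kept when the mean of its 50-Hz speed samples lies in
5–10 cm/s and the gate channel's theta (6–10 Hz) to delta (2–4 Hz) ratio of
mean Welch PSD *density* (not band sums — the gate is stated on mean
spectral density) exceeds 4. "Running speed was 5–10 cm/s" is read as a
condition on the window's mean speed; the scripted acceptance session uses
windows of constant speed, where any per-sample reading coincides. Rewards
arriving before 5.5 s are skipped and logged. Selection is independent of
reward-list order.

**Spectra.** Welch PSD and magnitude-squared coherence with 2-s Hann
windows at 50% overlap, detrended per segment, density scaling. Segments
are pooled across all kept epochs into one averaged estimate per session —
matching one-value-per-animal reporting; per-epoch estimation can be had by
calling the estimators on single-epoch sets. Coherence requires ≥ 2
averaged segments (one segment is identically 1). Band summaries integrate
PSD over in-band bins (sum × bin width, resolution-independent); a raw-sum
mode reproduces strict sum-of-PSD conventions. Relative power normalizes by
the total over the analysis range; band coherence is the unweighted mean of
in-band bins. Two gamma definitions coexist by design: 30–80 Hz for
relative power, 26–70 Hz for coherence, each attached to its output.

**Generator.** Channels share narrowband components realized as white noise
shaped by order-2 Butterworth band-passes (pure tones would make the Welch
coherence estimator degenerate), plus independent white noise and common
line-noise sinusoids. The one-sided model densities give the closed form

    C(f) = P_s(f)² / ((P_s(f) + P_n1)(P_s(f) + P_n2)),

with P_s from the designed |H(f)|². The reference scene sets the private
noise density equal to the shared density at 8 Hz, giving C(8 Hz) = 0.25
exactly; the estimator check uses the large-sample coherence variance
2C(1−C)²/K for its 95% interval. Line noise is excluded from the closed
form (it is deterministic and common; the formula describes the stochastic
part away from the harmonics). Electrode drift, 1/f background and
non-stationarity are not emulated. Validation sessions are 45–60 s.

## Morphometry (`neuroquant.morphometry`)

Sholl distances are 3D Euclidean from the soma centroid by default —
reconstructions are 3D, and whether published profiles used projected
distances is not stated, so a projected (`"xy"`) mode is provided.
Crossings are exact sphere–segment intersections: roots of the per-edge
quadratic on the half-open parameter interval (0, 1], so a crossing at a
node belongs to the incoming edge, collinear edge refinement cannot change
counts, and a tangential graze (double root) counts once. Shells default to
every 20 µm. Path orders increment at branch points; orders above 3 fold
into tertiary in both counts and lengths, so lengths always sum to the
total cable length. Spine densities are counts per µm with the aggregation
convention segments → cell mean → animal mean. SWC I/O is the standard
7-column dialect with 1-based ids; type codes map to compartment tags via a
configurable table.

The tree generator grows segments whose direction always makes an angle
< 90° with the outward radial direction at the segment start, which makes
soma distance strictly increasing along every segment; the shell-crossing
ground truth (segments with d_start < r ≤ d_end) is then exact by
construction, and matches the analysis module's half-open convention.

## Nested statistics (`neuroquant.nested`)

The nested Student's *t*-test treats genotype as fixed and animals as
random within genotype; the group effect is tested against the
between-animal mean square with df = (1, n_animals − 2) — the convention
that reproduces published legend df for any replicate counts. Unbalanced
designs use the unweighted-means formulation (one-way ANOVA on per-animal
means), which coincides with the classical balanced nested ANOVA F and
collapses exactly to the two-sample equal-variance *t*-test at one
replicate per animal. No Welch correction is applied inside the nested test
(that correction belongs to plain *t*-tests). All p-values are two-sided.
Variance components are method-of-moments (between-animal floored at zero;
the within-animal component is NaN when no animal has > 1 replicate). A
degenerate between-animal mean square of zero is reported as F = 0, t = 0,
p = 1 with a flag rather than an infinite statistic. Because the exact
published formulation (nested ANOVA versus mixed model) is not stated, a
REML mixed-model mode (statsmodels `MixedLM`, same df convention) is
provided and cross-checked in tests.

`type1_simulation` validates calibration: under a null generator spec the
rejection rate at α = 0.05 over 2000 simulations must lie in the 99%
binomial band (the generator's balanced default makes the test exact, so
this is a check of the implementation, not an asymptotic approximation).

## Generator defaults and determinism

Every generator is a pure function of its spec; the seed is part of the
spec and one `numpy` Generator is derived from it per call, so identical
specs give bit-identical outputs across module boundaries. Ground truth is
always emitted with the rendered data, never re-measured from it. Where the
source protocols state no distributional parameters (signal levels, noise
SDs, tube radii, oscillation amplitudes), the defaults above were chosen
once as values a practitioner would call realistic for the corresponding
preparations, and are documented rather than revisited.

## Known limitations

- Synthetic scenes are geometrically ideal; passing recovery tests shows
  the measurement code is correct, not that it is robust to optical
  artifacts, drift or biological heterogeneity absent from the generators.
- The engulfment fraction of partially engulfed puncta reflects the
  interior-distance definition (holes versus bites), not geometric overlap;
  only the fully-engulfed count is comparable across definitions.
- The mixed-model mode uses a Wald t with the n_animals − 2 df convention
  rather than a Satterthwaite approximation.
- The CLI covers single-dataset runs; group-level comparisons
  (`compare_curves`, spine-density group tables) are library calls.
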