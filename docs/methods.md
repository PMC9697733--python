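# Methods

## The grading model

A hyperreflective dot on a single B-scan is ambiguous: it can be the
cross-section of a quasi-spherical granule or of a string-like (filiform)
capillary running roughly perpendicular to the scan plane. The pipeline
resolves the ambiguity in three steps, each a direct automation of the
manual grading it models:

1. **Per-scan detection.** Dots are local contrast maxima inside the
   nuclear-layer bands, where they stand out against a hyporeflective
   background. The inner nuclear layer (INL) is graded in the parafoveal
   window 500–1500 µm temporal of the fovea center (excluding the foveal
   avascular zone); the outer nuclear layer (ONL) over the full field, with
   dots kept only when their axial diameter exceeds 15 µm *and* their
   distance to the adjacent layers exceeds their own width (this removes
   local thickenings of the outer plexiform layer and the outer limiting
   membrane).
2. **Cross-scan tracing.** Detections on strictly consecutive scans are
   linked by nearest-neighbour matching. The conservative transverse extent
   of an element seen on *n* adjacent scans at spacing Δ is Δ·(n−1): the
   element could extend almost Δ beyond each terminal scan, so the true
   length may be nearly 2Δ longer, and the deliberate underestimate is
   preferred. Elements on ≤3 adjacent scans (extent ≤22 µm at Δ = 11 µm) are
   granules; >3 scans (≥33 µm) are elongated.
3. **Perfusion reading.** The motion-contrast channel of the angiographic
   stack indicates blood flow. After rigid en-face alignment, each element's
   footprint is looked up on its mapped angiographic B-scan and the ±1
   neighbours (the tolerance the manual alignment achieved). An elongated
   element with interior flow signal on at least half of its scans is a
   perfused filiform element; without it (including flow consistently
   *beside* the dot) a non-perfused filiform element. A granule-shaped
   element without flow is a granule. Elements with no structural correlate
   on the angiographic scans, outside the narrower angiographic field, or —
   contradictorily — granule-shaped with interior flow, are unclassifiable.
   Flow directly anterior to the footprint raises a projection-artifact
   flag; it never changes the class.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `granule_max_scans` | 3 | shape-class boundary in adjacent B-scans |
| `onl_min_diameter` | 15 µm | strict ONL size threshold |
| `roi_inner`, `roi_outer` | 500, 1500 µm | parafoveal INL window, temporal side only |
| `alignment_tolerance_scans` | 1 | ±scans checked in the angiographic stack |
| `perfusion_overlap_fraction` | 0.5 | fraction of an element's scans that must show interior flow; 0.5 tolerates single-scan dropouts of the 7-frame motion channel |
| `adjacency_window` | 15 µm | "flow beside the dot" search ring (≈ one capillary diameter) |
| `contrast_threshold` | 1.5 | peak over local background; the grading literature gives no numeric cutoff, this is the package's operating point |
| `link_gate_lateral/depth` | 20, 15 µm | scan-to-scan association gate (capillary tilt ≤20° drifts ≤4 µm per 11 µm step) |

Attachment ("near IPL" / "near OPL") means the dot's measured axial extent
reaches within one axial pixel (≈4 µm) of the boundary; measurement jitter
from FWHM quantization and point-spread broadening is 2–3 µm, so a
half-pixel tolerance would flip labels of genuinely attached dots. Contact
with both boundaries resolves to the nearer one.

## Detection details

The structural stack is median-filtered (3 px axially) and divided by a
local background estimated as the 25th percentile over a window short in
depth and long laterally. The low quantile — rather than the median — keeps
the estimate anchored to the hyporeflective band even when the window
reaches into a bright plexiform layer, which would otherwise deflate the
contrast of boundary-attached dots. Candidate maxima are taken in the band
eroded by 4 µm (INL) / 8 µm (ONL) at 0.92× the contrast threshold and
promoted to the local full-band peak, which must clear the full threshold:
dots attached to a boundary often have their apparent peak inside the
blurred boundary transition, while the transition itself (a lateral ridge
along the whole boundary) rarely crosses the threshold away from the
eroded zone. Axial diameters are full-widths-at-half-maximum of the per-row
maximum over the peak column and its two lateral neighbours (a single
column can sample an off-center chord of a small dot); profiles that do not
come down inside the band are capped at the boundary and flagged. Measured
FWHMs below 6 µm are discarded as sub-resolution speckle blobs. On a
noiseless phantom, detection of planted cross-sections in the region of
interest is complete with zero false positives; at full speckle, isolated
boundary blobs appear at a rate of about one per stack and classify as
granules.

## The phantom

The generator emulates the statistical structure the grading relies on, not
the wave optics of the instrument:

* five smooth layer surfaces with a foveal pit (INL and IPL thin centrally,
  ONL thickens), each carrying a small seeded perturbation (±2.5 µm) that
  preserves strict ordering and gives the en-face projection texture;
* granules (spheres, 10–25 µm) in INL and ONL; capillaries (tubes,
  diameter 10–22 µm, length 51–183 µm) only in the INL, oriented within a
  20° cone of the scan axis, tangent to their attachment boundary or free
  inside the band with ≥8 µm clearance; the ONL receives no vessels;
* a deterministic round(fraction × n) of the capillaries are flagged
  non-perfused (default fraction 1/6: 2 of 12, as in a diseased eye;
  0 gives the healthy phantom);
* superficial vessels anterior to the IPL serve as alignment landmarks and
  cast speckly projection-artifact columns into the motion channel. They
  are confined to the nasal margin of the field so the planted perfusion
  state of every ROI object stays unambiguous — in real eyes the
  superficial plexus overlies everything, which is why projection
  susceptibility is reported as a flag;
* rendering uses partial-volume (anti-aliased) voxelization, an in-plane
  Gaussian point-spread of 7 µm axial × 14 µm lateral FWHM, and
  multiplicative gamma speckle of mean 1 and variance 1/(shape × frames):
  100-frame structural vs 7-frame angiographic averaging reproduces the
  ≈14× variance contrast between the two acquisitions. No back-shadow is
  cast behind dots. Scans are rendered as ideal planar slices (no
  cross-scan blur);
* the angiographic stack is rendered in a frame displaced by a rigid
  en-face misregistration (default 15 µm lateral, 8 µm along the scan
  axis, 0.5° about the fovea) — small enough that ±1-scan alignment is
  achievable, non-zero so alignment is genuinely exercised.

Stacks cover a parafoveal sub-field (43 structural scans at 11 µm, 89
angiographic at 5.9 µm, lateral −300…1800 µm, 390 µm depth window) at the
reference acquisition pitches; this contains everything the grading
touches, and the full-field scan counts remain expressible through
`ScanProtocol`. Planting pre-checks that every object's kind is recoverable
from its own geometry (granules intersect ≤3 structural scan planes with a
plane near the equator; capillary barrels ≥4), so recovery failures measure
the pipeline, not the scene.

What the phantom does **not** model — and hence what passing tests do not
show about real data: curved or branching-rich capillary geometry (a single
optional branch per capillary is supported), flow-speed-dependent motion
dropout (non-perfusion is zero signal), eye-motion artifacts within a
stack, axial misalignment between the two stacks, pathology other than
capillary non-perfusion, and realistic inter-subject variation in layer
reflectivity.

## Alignment

Both depth-mean projections are high-pass filtered (60 µm Gaussian), 
resampled onto a common 5 µm grid, and split into two lateral halves that
are registered independently by subpixel phase correlation; the difference
of the scan-axis shifts over the halves' intensity-weighted lever arm gives
the rotation, iterated to convergence. On default phantoms the planted
displacement is recovered to ≈1 µm and <0.1°, and the structural→
angiographic scan mapping stays within ±1 scan of truth. A registered
normalized cross-correlation below 0.2 raises an alignment error
(downstream classes would be unclassifiable).

## Statistics

Group summaries are medians with the even-count midpoint convention.
Subjects with no ONL dots carry an explicit absent marker; ONL extent
medians treat absent as zero, the convention that reproduces the published
group cells exactly. The published location-percentage summary cells
reproduce as the *mean* of the per-subject integer percentages (rounded
half away from zero), not their median; the package computes them that way
and verifies all 24 printed cells. The rank-sum test is the two-sided
unpaired Wilcoxon: exact enumeration of the rank-sum distribution (dynamic
programming) for tie-free samples with combined n ≤ 20, otherwise a normal
approximation with tie correction and no continuity correction. The exact
variant behind the study's printed p-values is not stated and cannot be
uniquely reverse-engineered, so p-values are reported descriptively and not
contract-tested.

## Problem sizes

The default test-suite conditions are the phantom defaults above: 16 INL
objects and 2 ONL granules per scene, five seeds for recovery, ten for the
healthy-phantom null. A full simulate–detect–trace–align–classify cycle
takes ~1.5 s on one CPU.

## Known limitations

* Diameters of boundary-attached dots are measured with one side capped at
  the boundary, which inflates them by a few µm; shape classification does
  not use diameters, so classes are unaffected.
* Detection at the smallest planted sizes (10 µm, the instrument resolution
  limit) is marginal by construction; a single 10 µm granule lying midway
  between two scan planes can be missed, which mirrors the physical
  situation.
* Linking is greedy per scan pair, matching the manual follow-the-dot
  procedure; it is deterministic but not a globally optimal assignment.
* The nasal side of the fovea is not analyzed (the grading window is
  temporal only).
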