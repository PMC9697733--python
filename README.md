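# hrdot — hyperreflective dots in structural and angiographic OCT B-scan stacks

Hyperreflective dots are small bright foci seen in the nuclear layers of the
retina on optical coherence tomography (OCT) B-scans. In the vascular inner
nuclear layer (INL) most of them are capillaries of the deep plexus seen in
cross-section; in the avascular outer nuclear layer (ONL) they are granular
structures. Distinguishing the two — and, with OCT angiography, telling
perfused capillaries from non-perfused ones — offers a non-invasive window on
capillary drop-out in diabetic retinopathy.

`hrdot` implements that grading procedure as an automated, tested pipeline:

1. **Detection** — per-B-scan detection of dots inside layer-defined bands
   (the parafoveal INL, 500–1500 µm temporal of the fovea, and the
   full-field ONL), with axial full-width-at-half-maximum diameters and
   location labels (attached to the IPL, attached to the OPL, or free inside
   the INL). ONL dots are kept only when wider than 15 µm and farther from
   the adjacent layers than their own width.
2. **Tracing** — greedy scan-to-scan linking of detections into 3D elements.
   An element followed over *n* adjacent B-scans at spacing Δ gets the
   conservative transverse extent Δ·(n−1); elements on at most three
   adjacent scans are granules, longer ones elongated (filiform).
3. **Perfusion** — rigid en-face alignment of the structural stack (11 µm
   scan spacing, 100-frame averaging) with the angiographic stack (5.9 µm
   spacing, 7-frame averaging), mapping each element's footprint into the
   angiographic frame (±1 B-scan tolerance) and testing for motion-contrast
   signal inside it. Final classes: granule, perfused filiform,
   non-perfused filiform, or unclassifiable; projection artifacts from
   superficial vessels are flagged, never reclassified.
4. **Statistics** — per-subject grading rows, group medians, and a two-sided
   unpaired Wilcoxon rank-sum test (exact enumeration for small tie-free
   samples, tie-corrected normal approximation otherwise). The per-subject
   grading table of the reference study (8 diabetic patients, 8 healthy
   controls) ships as a packaged fixture.
5. **Phantom** — a synthetic OCT phantom with layered reflectivity, a foveal
   pit, planted granules and capillary segments with known perfusion flags,
   multiplicative speckle whose variance scales as 1/(frames averaged), and
   a small rigid misregistration between the two stacks. Every pipeline
   stage is validated against this planted ground truth.

## Worked example

```bash
python analysis/01_simulate_phantom.py --seed 0
python analysis/02_detect_and_trace.py --seed 0
python analysis/03_classify_perfusion.py --seed 0
python analysis/04_group_statistics.py
```

prints (seed 0):

```
phantom seed 0: 21 objects (12 capillaries, 2 non-perfused), structural (43, 100, 368), angiographic (89, 100, 368)
seed 0: 17 INL elements (5 granules, 12 elongated), 2 ONL elements after filtering
alignment: estimated (14.2 µm, 8.6 µm, 0.43°) vs planted (15.0 µm, 8.0 µm, 0.50°)
final classes: {'perfused_filiform': 10, 'granule': 5, 'nonperfused_filiform': 2}
recovery: 16/16 planted INL objects (100%) with matching shape, perfusion and location
summary reproduction: 24/24 printed cells match exactly
```

Reading: the phantom planted 12 INL capillaries (2 of them non-perfused) and
4 INL granules; the pipeline detected and traced them, recovered the planted
rigid misregistration to within ~1 µm and 0.1°, called exactly the two
occluded capillaries non-perfused filiform, and reproduced every published
group-summary cell of the study's grading table (e.g. median INL dot counts
13 in patients vs 9.5 in controls, elongated extents 73 vs 81.5 µm) from the
per-subject values. The tables land in `results/`.

As a library:

```python
from hrdot import phantom, pipeline

pair = phantom.generate_pair(phantom.PhantomConfig(seed=0))
classified, transform = pipeline.run_inl_pipeline(pair)
for c in classified[:3]:
    print(c.element.n_scans, c.element.conservative_extent, c.final_class)
```

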