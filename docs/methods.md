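# Methods

## Coordinate and measurement conventions

Boxes are stored 0-based and half-open, `[x_min, x_max) × [y_min, y_max)`,
so areas and IoU are exact integer arithmetic on integer boxes.  The
LabelImg dialect of Pascal VOC is 1-based inclusive; the reader subtracts
1 from the minima and leaves the maxima, the writer inverts this, and the
round trip is exact.  YOLO normalized coordinates round-trip to within one
pixel at the stated image size.

Diameters are pixel-center column differences (`max_col − min_col`), not
pixel counts; a structure occupying columns 35..64 has a horizontal
diameter of 29. All raster positions are `(row, col)` with row 0 at the
top, matching image-array indexing.

## CTR pipeline

The cardiothoracic ratio is measured at the level of the right
hemidiaphragm dome: `L` is the thoracic width along the horizontal tangent
through the dome, `L1 + L2` the horizontal cardiac extent split about the
midline, `CTR = (L1 + L2)/L`, with cardiomegaly declared strictly above
0.55.  The pipeline assumes a PA view (the patient's right lung on the
viewer's left, configurable) and an isotropic raster; the CTR is
dimensionless, so pixel spacing is metadata only.

**Cleaning.**  Each structure is smoothed by a morphological closing
followed by an opening with the same disk.  Closing alone fills holes but
cannot remove protruding burrs, and single-pixel burrs on the boundary
corrupt the dome scan; the opening shaves them.  The disk radius is 3 px
at a 512-px mask and scales proportionally with mask size — segmentation
artifacts scale with resolution while anatomy keeps its proportions.
After smoothing, exactly the two largest 8-connected lung components and
the largest heart component are kept.  Fewer than two lung components is
a hard failure ("lungs not separable"), as is an empty heart ("heart
absent" — the case where the cardiac margins are invisible and the CTR is
undefined by convention).

**Boundary extraction.**  The contract is a single-pixel, 8-connected
contour per structure, realized as the structure minus its 4-connected
erosion.  On a binary raster this satisfies the same contract as an edge
operator while introducing no free thresholds.  Structures thinner than
two pixels in either direction cannot carry a contour and are rejected.

**Dome detection.**  Scanning upward from the lowest right-lung boundary
row, each row's boundary pixels are grouped into maximal column runs; the
width is the distance between the first two runs from the left.  Below
the dome these are the lateral chest wall and the diaphragm arc; on the
line grazing the dome the arc vanishes and the width expands to the full
lung width.  The returned tangent row is the lower row of the pair
maximizing the **signed width increase**, with ties broken toward the most
inferior row.  Two choices here deserve justification:

* *Signed, not absolute, differences.*  Near the costophrenic recesses
  the first-two-crossings width can collapse abruptly for bookkeeping
  reasons (at the lowest scanned row the first two runs are the two
  diaphragm slivers; one row up they are a single sliver's own edges).
  Such decreases are not dome evidence and, taken absolutely, can exceed
  the true dome jump.  Only width *increases* identify the tangent.
* *Scan restricted to the inferior half of the contour* (configurable
  `scan_fraction`).  The superior lung apex also narrows row by row and
  would otherwise compete with the diaphragm signature; the dome is
  inferior by anatomy.

Rows with fewer than two runs are skipped (a tangent line above the lung
base can exit the structure); three consecutive skipped rows above the
last measurable one end the scan.  A trace that never increases means a
flat diaphragm and is reported as a failure rather than an arbitrary row.

**Diameters and midline.**  `L` spans the extreme intersections of the
tangent row with both lung contours.  The midline is the midpoint of the
two lung centroid columns — a proxy for the spinal midline, which a
lung/heart mask does not encode.  The choice is immaterial in normal
anatomy: whenever the midline falls strictly inside the cardiac extent,
`L1 + L2` equals the heart's horizontal extent regardless of the exact
midline column (verified as a property test).  If the heart lies entirely
to one side of the midline, the sum exceeds the cardiac width and the
measurement carries a quality warning, as does a CTR above 1.0
(geometrically possible on pathological masks, so a warning rather than
an error).

The orchestrating `compute_ctr` is deterministic, records all
intermediates (tangent row, endpoints, midline), and converts stage
failures into a machine-readable `failure_reason` instead of raising —
mirroring how unmeasurable radiographs are excluded rather than crash a
batch.

## Detection evaluation

Matching is per image and per category: predictions in descending
confidence each claim the unmatched ground-truth box of highest IoU at or
above the threshold (ties on confidence break toward larger IoU, then
input order).  This is the Pascal-VOC protocol; it is stated rather than
asserted as the only option, and the PR sweep derives from the same
verdicts by prefix sums, so curve and operating point cannot disagree.
AP defaults to all-point interpolation (non-increasing precision envelope
integrated over recall) with the 11-point variant available; mAP averages
only categories with ground truth, since recall is undefined without
positives, and excluded categories are reported.  Precision and recall at
an operating point carry 95% Wilson score intervals (clamped to exact 0/1
at the boundary counts).  FP-per-image is the mean unmatched-prediction
count per radiograph, the reviewer-workload proxy.

## Agreement statistics

Reader boxes carry no confidence, so two readers' boxes are paired per
category by the assignment maximizing total IoU (Hungarian algorithm);
surplus boxes are singletons with IoU 0.  The two IoU = 0 situations are
tallied separately: a category annotated by one reader only (singleton)
versus both readers annotating without overlap (assigned pair with zero
IoU).  Mean IoU is reported both including and excluding zero entries,
since published summaries are ambiguous on this point.

Bland–Altman reports the mean difference (algorithm − reference) with
limits of agreement at ±1.96 sample SD.  The ICC is computed from the
two-way mean squares of the n×2 layout; the default form is ICC(2,1)
(two-way random effects, absolute agreement, single measurement), the
appropriate form for comparing an algorithm against a reference standard,
with ICC(3,1) available.  The implementation is cross-checked against an
independent statistical package in the test suite.

## Synthetic generators

**Phantoms.**  Each lung is an ellipse minus a circular "diaphragm" disk
whose top row is the dome apex — an exact spec parameter — and the heart
is an ellipse.  The true dome row, the thoracic width at that row, the
cardiac extent and hence the true CTR are read off the noise-free raster
geometry, never from the measurement pipeline, so phantom batches form an
honest parameter-recovery surface.  Optional noise imitates imperfect
segmenter output: boundary-band pixel toggling (burrs) and small interior
holes, both seeded.  Random phantoms default to mild noise (toggle scale
0.6, 3 holes) because perfectly clean masks would leave the cleaning
stage untested.  A rectangular (flat-bottomed) family exists solely to
exercise the flat-diaphragm failure path.  What phantoms do **not**
model: real diaphragm asymmetry, costophrenic-angle blunting,
gastric-bubble confusion, or segmentation errors correlated with
pathology — recovery results bound algorithmic error on well-formed
masks, not clinical accuracy.

**Detection scenarios.**  Ground-truth boxes are drawn with category
frequencies proportional to a large annotated CXR collection's label
distribution (nodule-heavy at ~18% of boxes, atelectasis-poor at ~0.14%;
the full table ships as a module constant and can be reproduced exactly
by the deterministic manifest builder).  The detector model is: each GT
box independently detected with probability `p` (localization jittered by
a Gaussian SD, confidence uniform on 0.5–0.95), plus per-category Poisson
false positives (confidence uniform on 0.05–0.5).  Closed forms returned
with the sample: recall = `p` exactly; precision as the ratio of
expectations E[TP]/(E[TP]+E[FP]), which Monte-Carlo precision approaches
at large n but is not an exact finite-n expectation.

**Stress transform.**  Brightness multiplies intensities; contrast
rescales about the (brightened) image mean, `(p − mean)·c + mean`; output
clips to the dtype range (or [0, 1] for floats) and factors of exactly
1.0 return a bitwise-identical copy.  The named factors admit several
formulas in the literature; this multiplicative/affine pair is the
documented choice and a contrast of 0 degenerates cleanly to a constant
image at its mean.

## Problem sizes and tolerances

The test suite and acceptance script use: 100 random 512-px phantoms for
CTR recovery (observed mean |ΔCTR| ≈ 0.002, asserted < 0.01; max ≈ 0.009,
asserted < 0.03), scale (2×, 3×) and translation invariance within 0.01;
IoU checked exactly against pixel enumeration on integer boxes up to
50×50; AP checked exactly (1e-12) against brute-force threshold
enumeration on instances of up to 20 predictions; scenario closure at
≥1000 GT boxes within 3 binomial SE; ICC recovery within 0.03 of the
variance-component reliability at n = 800 pairs, Bland–Altman offset
within 3σ/√n at n = 500.  These sizes keep the whole suite under a minute
while leaving the Monte-Carlo assertions ~3-sigma safe.

## Known limitations

* The midline proxy (mean lung centroid column) can drift on grossly
  asymmetric lung fields; the midline-invariance property bounds but does
  not eliminate the effect.
* The dome scan assumes the right lung extends below the dome apex
  (costophrenic recess visible); masks cropped above the recess yield
  "dome undetectable".
* Sub-pixel positions are not modelled anywhere; all arithmetic is
  pixel-center, which bounds scale-invariance error at ~1 px per edge.
* AP-versus-reader comparisons treat readers as single operating points;
  no confidence calibration is attempted.
* The deterministic reference-table manifest reproduces count-level
  structure (boxes, abnormal/no-finding, patients), not the per-image
  multiplicity distribution, which is defined here as distinct categories
  per image.
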