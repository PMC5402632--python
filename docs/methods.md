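# Methods

## Problem and model

Early erosive damage in inflammatory arthritis manifests as small
interruptions of the cortical shell of the finger-joint bone ends:
channels of resorbed bone connecting the periosteal surface to the
endosteal/trabecular compartment. On HR-pQCT (isotropic voxels, 82 µm for
generation-1 scanners, 61 µm for generation 2) these appear as void
pathways a few voxels wide. The package detects them with pure binary
morphology on two derived volumes: a filled periosteal solid and a
binary bone model.

The detector deliberately analyzes a **constant-thickness cortical
mask** rather than the anatomical cortex: the filled periosteal solid is
eroded by a fixed number of voxels and subtracted from itself, giving a
shell of exactly that thickness everywhere. This makes "through the
cortex" a well-defined, reproducible criterion independent of local
cortical thinning, and makes the interruption surface a simple quotient
(volume / mask thickness).

## Pipeline steps and parameters

All morphological "steps"/"voxels" of dilation and erosion in the
detection stage use the face-connected 3D cross (city-block unit ball),
one iteration per voxel of distance. Component labeling defaults to
face (6-) connectivity, consistent with that element.

### 1. Periosteal contour (`contouring`)

* Structure approximation: truncated Gaussian smoothing, sigma 0.8
  voxels, kernel radius 1 voxel (3×3×3, weights sampled from the
  Gaussian and renormalized), threshold at **105 per 1000 of the maximum
  possible voxel value** (`intensity_max`). The finger-joint cortex is
  thinner and less mineralized than radius/tibia cortex, hence the low
  threshold.
* Closing: dilation by **7 steps**, cavity fill (every background
  component not connected to the lattice border becomes foreground),
  erosion by 7 steps. The volume is padded before and cropped after, so
  closing never clips at the border.
* **Metric of the closing.** The closing uses the *Euclidean* ball of
  radius `closing_steps` (+0.5 voxel for lattice discretization),
  implemented by distance transform, not the iterated cross. The reason
  is geometric: a closing with the cross (a diamond) provably cannot
  restore a flush surface over the mouth of a 3-voxel-wide channel — it
  leaves a 1–2-voxel dimple, the shell below is locally shifted, and the
  restored void of a minimal interruption loses 4 of its 20 voxels,
  breaking the size floor the detection criteria define. The Euclidean
  closing bridges channel mouths flush, so the cortical mask keeps its
  constant thickness across interruption openings. Detection-stage
  dilations keep the cross, which *is* the minimal-opening criterion
  (below).
* Per-mille thresholds are interpreted against `intensity_max` — the
  acquisition's maximum possible value (e.g. the integer-type maximum) —
  not the observed maximum, so thresholds do not drift with image
  content.
* The semi-automated pathway loads an externally edited binary solid in
  place of the automatic one; it is sanitized only by cavity fill.
  Interactive editing itself is out of scope.

### 2. Bone segmentation (`segmentation`)

The scanner vendor's standard protocol (Laplace–Hamming filtering plus a
constant threshold) is not published at coefficient level, so the filter
here is explicit module policy, fully exposed through
`SegmentationParams`:

    H(k) = (1 − ε) + ε · W(r) · (1 + r²),   r = |k| / k_Nyquist

a convex blend of the identity with Laplacian sharpening band-limited by
a Hamming window `W` (cutoff as a fraction of Nyquist; `W = 1` at or
above cutoff 1). `H(0) = 1`, so flat regions keep their intensity and the
filter only sharpens edges against partial-volume blur. With ε = 0 the
operation reduces to plain thresholding. Defaults: cutoff 0.4, ε = 0.5,
threshold 400/1000 of the filtered volume's dynamic range (min/max
clamped to `[0, intensity_max]`). Correctness is asserted against
phantoms with known true structure, not against the vendor filter;
detection results depend on these parameters and any substitute protocol
should be stated alongside results.

### 3. Cortical mask (`detection.build_cortical_mask`)

`shell = solid ∧ ¬(solid ⊖ T)` with `T = mask_thickness_voxels`
(default 4 ⇒ 0.328 mm at 82 µm; use 5 at 61 µm ⇒ 0.305 mm). The mask
thickness deliberately undercuts the ~0.39 mm mean cortical thickness of
these joints because the juxta-articular rim, where interruptions
concentrate, is thinner. The periosteal face is the set of shell voxels
face-adjacent to the outside of the solid; the endosteal face those
face-adjacent to the eroded interior. A solid thinner than `T`
everywhere has no interior: the shell equals the solid, the endosteal
face is empty, and a warning is emitted (detection is impossible there).

### 4. Interruption detection (`detection.detect_interruptions`)

On `bone ∧ shell`:

1. dilate the cortical bone by 1 voxel (equivalently erode the void) —
   this erases any opening narrower than 3 voxels in either in-plane
   direction or shorter than 3 consecutive slices;
2. invert; label the remaining void (face connectivity);
3. keep components **containing** at least one periosteal-face voxel and
   at least one endosteal-face voxel. Containment, not mere adjacency,
   is required: adjacency to a *bone* voxel of a face would falsely
   select large intra-cortical cavities that do not actually reach the
   boundary;
4. dilate the kept components back by 1 voxel, clipped to
   `shell ∧ ¬bone` — the restored void never claims bone voxels and
   never leaves the mask. At concavities the restored set can slightly
   exceed or miss the pre-erosion void; components merged by this
   dilation stay merged (they are closer than 2 voxels apart,
   indistinguishable at the stated precision);
5. relabel and drop components below `min_component_voxels`
   (default 20 = 5-voxel opening × 4-voxel depth, 0.011 mm³ at 82 µm);
   records are sorted by descending voxel count, ties broken by
   lexicographic centroid.

The cross structuring element is what makes "an opening of at least
5 voxels through the cortex" concrete: the smallest void surviving
step 1 has a plus-shaped cross-section (center + 4 face neighbors),
i.e. ≥ 3 consecutive slices and ≥ 3 voxels width. Whether the original
implementation enforced the 20-voxel floor explicitly or it emerged from
morphology is not documented; this package enforces it explicitly.

Per interruption: volume = voxel count × voxel³; surface = volume /
(T × voxel size). The identity surface × thickness = volume is exact by
construction.

## Reliability statistics (`reliability`)

Two interruption label maps are matched one-to-one by voxel overlap
≥ 20 voxels (the minimal detectable volume), greedily by descending
overlap with deterministic tie-breaks; the test suite bounds the greedy
assignment against an exhaustive-assignment oracle. From the counts:
proportion of matching interruptions (a count-level Jaccard × 100), PPV
and sensitivity against a gold standard. Joint-level reliability is
ICC(2,1) — single measures, two-way random effects, absolute agreement —
computed from the two-way ANOVA mean squares with the standard
F-distribution confidence interval (Satterthwaite degrees of freedom).
A zero-variance table has no defined ICC and raises. Friedman/Wilcoxon
comparisons are not re-implemented; the summary tables contain the
per-joint values any statistics environment needs.

## Phantoms (`phantom`)

The generator emulates the geometry the detector cares about, with exact
ground truth computed from channel metadata alone (no shared logic with
the detection code):

* **Geometries**: spherical shell, ellipsoid shell, and the default
  capped cylinder (shaft + hemispherical head + flat closed base) as a
  cartoon metacarpal bone end. Cortex = solid voxels within
  `cortical_thickness_voxels` (default 5 ≈ 0.41 mm) of the surface by
  Euclidean distance.
* **Channels**: carved along a lattice axis from a chosen side,
  plus-cross / square / circular cross-section, through or blind
  (periosteal/endosteal) or intra-cortical. Each column is carved
  relative to its own local entry surface so the channel follows the
  curved cortex. Channels reaching the interior drain through a *vent*
  (cross-section widened by 1 voxel, subcortical only) so a trabecular
  strut cannot seal the exit by partial-volume blur — without it the
  phantom, not the detector, would decide the outcome.
* **Trabecular interior**: an axis-aligned rod lattice, giving the
  inversion step a realistic endosteal neighborhood without modeling
  true trabecular architecture.
* **Image formation**: bone at 40 % of `intensity_max` on a dark
  background, optional Gaussian blur (partial-volume surrogate) and
  additive Gaussian noise truncated at 0; deterministic per seed.
* A channel *qualifies* (ground-truth detectable) iff it is through and
  its width is ≥ 3 voxels.

Two standard galleries: the six-configuration noise-free gallery
(3 qualifying channels including the minimal width-3 plus, plus a
2-voxel channel, a blind pit and an intra-cortical cavity that must be
rejected), and a five-channel noisy gallery with compact cross-sections
(square/circle widths 3–5). The minimal plus-cross appears only in the
noise-free gallery: its arms are 1-voxel slits that genuinely seal under
0.5-voxel blur — at the resolution limit this is physics, not a detector
failure — whereas compact lesions of the same nominal width survive.

**What phantom results do not show**: beam hardening, motion artifacts
(a known false-positive source for the automatic contour in vivo — scans
should be quality-graded before analysis), real trabecular
architecture, or density calibration. Passing phantom tests demonstrates
the morphology and statistics are implemented correctly, not clinical
performance.

## Numerical and interface choices

* Axis 0 is the transverse slice index; "consecutive slices" means
  consecutive indices along axis 0. Voxel coordinates are 0-based;
  physical positions are voxel centers.
* Thresholds are inclusive (≥). Outside the lattice counts as background
  for every morphological operation.
* I/O: NIfTI (nibabel), MetaImage (SimpleITK), multi-page TIFF
  (tifffile); binary/label volumes round-trip as lossless integers; a
  JSON sidecar carries voxel size and `intensity_max` where the
  container cannot. Proprietary scanner formats (ISQ/AIM) are not
  parsed; anisotropic volumes are rejected unless an explicit isotropic
  override is given. DICOM assembly and density calibration are out of
  scope.
* Problem sizes in the shipped tests and the acceptance script — 48–72
  voxel phantom lattices, ~100-configuration oracle sweeps, 6-joint
  reliability series, n = 1000 ICC simulations — were chosen as the
  smallest sizes at which every geometric regime of the algorithm
  (curved and flat cortex, all channel types, both scanner-generation
  parameter sets) is exercised; results are deterministic per seed.
* The whole pipeline is deterministic: identical configuration and
  inputs give byte-identical tabular outputs and voxel-identical
  volumes.

## Known limitations

* Detection output depends on the segmentation filter parameters; only
  the phantom ground truth, not a vendor implementation, anchors them.
* The greedy overlap matcher can in principle (rarely, for heavily
  overlapping lesion sets) return one pair fewer than the maximum
  matching; the exhaustive oracle in the test suite quantifies this.
* One periosteal solid is contoured per volume (possibly with several
  connected components); separating metacarpal head from phalangeal base
  is not attempted.
* The restored void volume is approximate at concavities (clipped
  re-dilation), so surfaces of irregular interruptions carry a
  voxel-scale uncertainty.
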