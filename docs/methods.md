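# Methods

## Setting and model

`contourqa` treats contour QA as a two-class decision problem. For each
structure on each scan there are two binary masks on one CT grid: a
*reference* contour (the one that would be used clinically) and a
*verification* contour from an independent segmentation system. The working
assumption is that two independently produced contours rarely fail in the
same way, so when the reference contour is unusable ("needs major edits"),
the pair's similarity metrics move far from their values for sound pairs.
The decision rule is learned per structure from labelled pairs; the positive
(flagged) class is *unacceptable*.

## Grid and surface conventions

* Arrays are indexed `(z, y, x)`; spacing and origin are stored in the same
  order, in millimetres; voxel `i` has its centre at `origin + i * spacing`.
* Pairs whose shape, spacing or origin differ (beyond 1e-4 mm) are rejected,
  never resampled: interpolation changes every metric, and the method is
  defined on a common grid.
* The surface of a mask is the set of *border voxel centres*: foreground
  voxels with at least one background face-neighbour (6-connectivity), with
  out-of-grid neighbours counted as background, so a structure cut off by
  the field of view has surface at the cut. Surface Dice counts these
  points unweighted. This is deliberately simpler than sub-voxel
  area-weighted surfel surfaces used by some mesh-based implementations; at
  CT-scale voxels the two agree closely, and the point-set definition can be
  verified exactly against a brute-force all-pairs computation, which the
  test suite does on hundreds of random anisotropic grids (agreement to
  1e-9 mm / 1e-12 in fractions).
* Nearest-surface distances are computed with an exact Euclidean distance
  transform (`scipy.ndimage.distance_transform_edt`) with the anisotropic
  spacing as sampling, evaluated at the other surface's voxels. Percentiles
  (for HD_95) use linear interpolation; the symmetric value is the maximum
  of the two directed percentiles. MSD pools both directed lists (a
  count-weighted mean), summed per direction before division so the result
  is exactly symmetric in floating point.
* Degenerate pairs (exactly one empty mask) are not an error: they receive
  DSC = SDSC = 0, infinite distances and a `degenerate_flag`, and every QA
  rule flags them unconditionally — an empty autocontour is itself the
  failure the method exists to catch. When degenerate rows enter SVM
  training, the infinite distances are capped at the grid diagonal (the
  largest realisable distance). Both masks empty raises.

## Decision rules

* **Single metric.** A linear soft-margin SVM (the only meaningful kernel in
  1-D) is fitted on the standardised metric; the boundary is mapped back to
  metric units as a scalar threshold, with the flag direction inferred from
  the class means (below-threshold flags for similarity metrics,
  above-threshold for distances). The threshold agrees with direct primal
  minimisation of `0.5 w² + C Σ hinge` to ~1e-3 (tested). A value exactly at
  the threshold passes — the tie-break must be fixed for reproducibility,
  and this direction keeps the rule conservative about flagging only genuine
  departures while degenerate pairs are flagged by their flag, not the
  threshold.
* **Metric combinations.** Named panels (`DSC_HD`, `Three_SDSC`,
  `Five_SDSC`, `Four_metrics`, `Five_metrics`, `Seven_metrics`,
  `Nine_metrics`, `All_metrics`) or arbitrary subsets, with linear,
  polynomial (degree 3), RBF and sigmoid kernels. Features are centred and
  scaled on the training data — without this, millimetre-scale distances
  dominate the unit-scale Dice fractions for any non-linear kernel. The
  kernel coefficient follows the `1/(n_features · Var)` rule; these defaults
  are fixed rather than tuned per structure.
* **Penalty parameter.** `sweep_C` cross-validates a grid (default 1–50);
  exact accuracy ties resolve toward C = 10 and then the smaller C. All
  shipped analyses use C = 10. Hinge loss is unweighted: class balance is
  expected to come from the composition of the training set (deliberately
  enriched with unacceptable examples), not from reweighting.
* **Cross-validation.** Threefold by default, stratified *within each source
  set*: each set's rows are shuffled (seeded) and dealt round-robin, so
  every fold contains the same mix of internal/external/manual pairs and
  fold sizes within a set differ by at most one. Reported values are
  fold means ± sd.
* **Operating points.** `fixed_sensitivity_threshold` sweeps every
  achievable threshold (midpoints of sorted unique values plus sentinels)
  and returns the one maximising specificity subject to sensitivity ≥
  target, ties toward higher sensitivity. By construction the achieved
  sensitivity on the fitting data never falls below the target.
* **Pooled thresholds.** `average_thresholds` arithmetic-means the
  per-structure thresholds of a metric and re-scores each structure at the
  pooled value; mixed flag directions across structures are an error. The
  package ships pooled defaults usable without training: DSC 0.75,
  SDSC_1 0.30, SDSC_2 0.54, SDSC_3 0.69, all flag-if-below.
* **ROC/AUC.** The curve is computed over all thresholds with the score
  oriented so higher means more suspect; AUC is the trapezoidal area (equal
  to the Mann–Whitney concordant-pair fraction, tested exhaustively at
  small n). The 95% CI is the 2.5–97.5 percentile of AUCs over 2000 seeded
  bootstrap resamples of the (value, label) pairs; resamples that lose a
  class are redrawn. The percentile method is used because it is
  distribution-free and simple to reproduce.

## The synthetic study

Clinical contours are not redistributable, so the generator builds the same
*population structure* a real QA training set has, at organ scale, fully
seeded:

* **Phantoms.** Four archetypes with millimetre dimensions typical of pelvic
  anatomy (ellipsoid ~40–65 mm across; curved tube of radius ~10–14 mm;
  two-component bean pair; branched Y-slab), each jittered per seed, on a
  default grid of 48×64×64 voxels at (2.5, 1.5, 1.5) mm. Sizes matter only
  through their ratio to the 1–10 mm tolerances, which is preserved.
* **Source sets.** 49 "internal" reference-vs-verification pairs
  (verification noise 0.5 mm — emulating verification contours predicted on
  their own training scans, which suppresses false positives), 38 "external"
  pairs (verification noise 1.5 mm), 49 acceptable and 49 unacceptable
  "manual" pairs: 185 pairs per structure. Internal/external reference
  contours are unacceptable at rates 8% / 13%; the manual sets are labelled
  by construction.
* **Acceptable contours** differ from the underlying anatomy by a smooth
  random boundary displacement bounded by 1.5 mm (a seeded Gaussian-filtered
  field applied through the signed distance transform, so amplitude 0 is the
  identity and the Hausdorff shift never exceeds the amplitude plus one
  voxel diagonal), plus, with probability 0.6, one to three local bumps or
  dents of up to 4.5 mm over ~8 mm patches (the regional deviations of a
  contour "needing minor edits"), plus, with probability 0.35, a thin
  "finger" artefact up to 9 mm long with ~1% surface area. The artefacts are
  what makes HD_100/HD_95 genuinely poor discriminators here, for the same
  reason they are poor on clinical data: a single worst point dominates them
  while barely moving surface Dice or MSD.
* **Unacceptable contours** carry one injected error: cranio-caudal
  truncation of 25–35 mm, rigid shift of 5–15 mm, sector over-expansion of
  5–12 mm, dropped component (bean pair only), or gross misplacement (≥ 3×
  an 8–12 mm magnitude). Every error type has a checkable geometric
  signature, asserted in the tests. The smallest error magnitude (5 mm)
  deliberately exceeds the acceptable noise amplitude by more than 3×, so
  the two populations are genuinely separated — mirroring the role of
  deliberately constructed unacceptable contours in anchoring thresholds.

With these defaults the acceptable and unacceptable SDSC_2 distributions do
not overlap, the learned SDSC_2 threshold sits near 0.77, and perturbing it
by ±20% changes whole-dataset accuracy by ~2 percentage points.

**What passing tests show, and what they don't.** The synthetic study
establishes the *mechanics* of the method — metric correctness, the
qualitative metric ranking (1–3 mm surface Dice best, maximum-distance
Hausdorff metrics worst), threshold robustness, and the end-to-end pipeline.
It does not establish clinical performance: phantoms lack inter-observer
ambiguity, image-driven failure correlations between the two systems,
per-structure anatomical variation, and borderline cases near the
acceptable/unacceptable boundary, so accuracies here (≈ 1.0 for surface
Dice) are upper bounds, not forecasts, relative to the ≈ 0.9 achievable on
clinical contours.

## Problem sizes and numerical choices

* Default study: 185 pairs on 48×64×64 grids; generation plus metrics runs
  in well under a minute on one CPU. Tests use a coarser 36×48×48 grid at
  (3, 2, 2) mm for classifier and CLI fixtures.
* Metric cross-checks run on random grids up to 20³ with random anisotropic
  spacing in [0.5, 3] mm, against an all-pairs brute force.
* Tolerances: distances 1e-9 mm, fractions 1e-12 (EDT vs brute force is
  exact up to float rounding); SVM-threshold vs direct-minimisation
  agreement 5e-3 (optimizer precision); everything seeded is asserted
  bit-identical.
* NIfTI I/O assumes axis-aligned affines (diagonal scaling + translation);
  data are transposed between the on-disk `(x, y, z)` order and the
  package's `(z, y, x)` convention, and float volumes binarise at > 0.5.

## Known limitations

* Point-set surfaces slightly overweight voxels on coarse grids compared to
  area-weighted surfels; metric values on very anisotropic, very coarse
  grids differ from mesh-based implementations (by design — see the
  convention note above).
* No resampling: pairs must share a grid exactly.
* The generator does not simulate CT images, deformable anatomy, or
  correlated failures between the two contouring systems.
* Probability calibration, per-slice error localisation and non-SVM
  classifiers are out of scope.
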