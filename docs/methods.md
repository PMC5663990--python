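# Methods

This note records the models, parameter choices, and numerical decisions
behind `sirtdose`, and what the synthetic-phantom tests do and do not show
about real data.

## Dose model

All dosimetry is compartmental ("partition") MIRD dosimetry under three
assumptions: (i) complete local energy deposition of the Y-90 beta spectrum
inside each partition, (ii) complete decay of the implanted activity in
place, and (iii) uniform activity concentration within a partition. The
dose factor is computed in SI from ⟨E⟩ = 0.9267 MeV and T½ = 64.04 h:

    k = ⟨E⟩ [J] · 10⁹ [decays/s per GBq] · T½ [s] / ln 2
      = 49.3831 Gy·kg/GBq

and is kept at full precision internally; 49.38 is a display rounding.
Doses are linear in the administered activity A₀, which is what makes
threshold-constrained planning a closed-form inversion.

The territorial model assigns partition activities proportionally to
SPECT-like counts: A_i = A₀·(1−L)·f_i with f_i = c_i/Σc. A partition with
zero counts receives f = 0 (the well-defined limit), zero dose. No
partial-volume correction is applied to counts. For the two-partition set
{normal liver, tumor} the territorial dose formula reduces algebraically
to the classical formulas; the test suite verifies this identity to
1e-10 relative over 1000 random parameter draws, and verifies the energy
balance Σ_i D_i·m_i = k·A₀·(1−L) exactly.

## Masses

Partition mass = voxel count × voxel volume × density. Default densities:
1.05 kg/L for liver-side tissue (liver, tumor, margin) and 0.30 kg/L for
lung parenchyma. The lung value matters: an inflated lung at soft-tissue
density would weigh ~2.7 kg for a realistic volume and make the 25 Gy lung
limit unrealistically slack; 0.3 kg/L yields ~0.8 kg for the phantom slab,
in the physiological range. Both densities are configurable.

## Arterial territories

1. **Skeletonization** — `skimage.morphology.skeletonize` (Lee 3-D
   thinning) reduces the binary vessel mask to a one-voxel centerline. If
   the mask has several 26-connected components only the largest is used
   (with a warning).
2. **Graph abstraction** — skeleton voxels become a 26-adjacency graph with
   mm-weighted edges. Cycles (thinning artifacts) are broken by repeatedly
   removing the shortest edge of a found cycle. Voxels of degree ≥ 3 are
   bifurcation nodes, degree-1 voxels endpoints; maximal junction-free
   chains become branch polylines. Leaf spurs shorter than a configurable
   arc length (pipeline default: two voxel diagonals) are pruned and
   pass-through chains re-merged. Polylines get two passes of an
   endpoint-preserving (¼, ½, ¼) smoothing kernel to damp voxel zigzag.
   The root is the node nearest a supplied hint (the catheter/entry
   position), else the first endpoint.
3. **Canonical branch ids** — branches are numbered 1..B by polyline
   centroid (lexicographic in mm). Ids are the documented tie-break in
   voxel assignment, so they must not depend on construction order; the
   geometric numbering makes a ground-truth tree and its skeleton-based
   reconstruction agree on which branch "wins" exactly-tied voxels (the
   Voronoi wedge behind a junction is tied between all branches meeting
   there).
4. **Grouping** — with generation g, the territories are the branch
   subtrees rooted at depth g (branch depth counted from the root node).
   Branches shallower than g — the feeding stem — define no territory and
   do not compete for voxels; the liver volume around the stem divides
   among the nearest subtrees by distance. Anatomical (Couinaud-style)
   grouping can be expressed through the explicit branch→territory map
   instead. If g exceeds the tree depth, each leaf branch becomes one
   territory (with a warning).
5. **Voxel assignment** — every liver voxel is labeled with the territory
   of the nearest assignable branch. Distance is Euclidean in world mm
   (anisotropy-aware) from the voxel center to the branch polyline
   densified to ≤ 1 mm steps, which bounds the polyline-sampling error
   well below voxel size. Exact distance ties go to the lowest branch id.
   The suite checks this assignment against a brute-force scan over all
   (voxel, polyline-point) pairs — exact label equality on 20 random
   phantoms — plus exhaustiveness/exclusivity and invariance under joint
   isotropic rescaling of spacing and geometry.

## Tumor margin

The margin is the set of liver voxels within 11 mm (world mm, anisotropic
Euclidean distance transform) of any tumor voxel, excluding the tumors
themselves; 11 mm is the maximum Y-90 emission range in tissue, i.e. the
shell in which counts can plausibly originate from the tumor. By default
the margin is booked as its own `excluded_margin` partition: its counts
stay in the liver-side total (so activity conservation and the lung-shunt
denominator are unchanged) but contribute to no reported normal-liver or
tumor dose and to no planning constraint. Alternatives: merge each margin
voxel into its nearest tumor, or drop margin counts entirely. The default
was chosen because merging would change tumor doses, which contradicts the
intended "exclude from normal liver" behavior.

## Planning

A₀ = min over the active constraints of the single-constraint inversions:
mean normal-liver dose (mass-weighted over the normal-liver territories;
equivalent to the pooled normal-liver dose, with an unweighted option) at
its limit, and lung dose at its limit. The tumor-dose threshold
(> 100 Gy) is a report-only flag per tumor, never a constraint — a plan is
returned even when the target is missed. An optional cap on the mean tumor
dose can be enabled as a third constraint (off by default). The returned
plan has the binding constraint at equality to 1e-9 relative and the other
constraint satisfied. The BSA prescription depends only on height, weight,
and volumes, never on counts.

## Synthetic phantom

The phantom emulates the *geometry and counting statistics* of an MAA
SPECT/CT planning study: a 64³ grid at 4.795 mm isotropic spacing (SPECT
matrix scale), an ellipsoidal liver (semi-axes 90×65×50 mm, ≈ 1.2 L), a
lung slab above it, spherical tumors (default one, radius 20 mm), a
procedurally grown strict-bifurcation arterial tree (3 generations,
branch angles 25–40°, segment lengths 30–50 mm tapered by 0.75), uniform
unit activity density in normal liver, true_TN× that density in tumors
(default 6), a lung compartment holding exactly the true shunt fraction
(default 0.10) of total activity, a 6-mm-FWHM Gaussian PSF standing in for
the reconstruction filter, and Poisson counting at 10⁶ total counts.

Design points:

* **Counts are placed before blurring**, so tumor spill-out across the
  tumor boundary — the effect the 11-mm margin targets — emerges from the
  PSF rather than being painted in.
* **Blur boundary handling** is constant-zero padding with all organs kept
  ≥ 3σ from the grid edge, so convolution conserves counts in the field of
  view (verified to 1e-6 relative).
* **Tube rasterization** stamps each centerline sample as a ball centered
  on its nearest voxel. This guarantees 26-connectivity when the radius is
  below the voxel size and keeps tube cross-sections odd and symmetric —
  Lee thinning has no stable medial axis for even (e.g. 2×2-voxel)
  cross-sections and can erase such segments entirely.
* Activity is a continuous density; microsphere discreteness is ignored
  (irrelevant at partition level).

What the phantom does **not** emulate: attenuation, scatter, collimator
response beyond a stationary Gaussian, reconstruction artifacts
(no projector or OSEM), respiratory motion, segmentation and coregistration
error, heterogeneous intra-tumor uptake, and anatomical vessel geometry
(the tree is synthetic; no portal vein). Passing tests therefore
demonstrate internal consistency of the method under an idealized imaging
model, not clinical accuracy.

## Parameter recovery and what the tests show

On noiseless, unblurred counts the lung shunt and T/N estimators recover
the generator values to 1e-6 (exact by construction). Under the 6-mm PSF,
mask-restricted count sums lose a thin boundary shell of each organ, which
biases the shunt estimate by ≈ 4e-4 for this geometry — inside the
single-acquisition binomial error bar (3·SE ≈ 9e-4 at 10⁶ counts); the
suite asserts that the estimate averaged over 100 Poisson replicates stays
within that bar. The blurred T/N estimate is biased toward 1 by spill-out
(≈ 5.5 for a true 6 with a 20-mm tumor), which is the phenomenon
motivating the margin rule; the suite asserts the bias direction.

Territory recovery through the full chain (rasterized vessels → skeleton →
graph → labels vs the analytic ground truth) is evaluated on phantoms at
CT-like 2.4 mm voxels — vessel segmentations come from CT in practice —
where mean voxel agreement across 10 phantom draws is ≥ 95% (each ≥ 90%).
At SPECT voxel size (4.795 mm) single-voxel junction displacement can cost
a few percent more; the limiting factor is voxel quantization of junction
positions, not the assignment rule (which is exactly brute-force-correct
for any given graph).

## Numerical conventions

* Voxel centers sit at `index × spacing`; all distances in world mm; the
  NIfTI affine carries spacing on disk (int64/float64 volumes are written
  as int32/float32, within NIfTI-1's type set).
* All grids of one analysis must share shape and spacing; no resampling is
  performed (inputs are assumed coregistered upstream).
* Doses and tables carry full double precision; any rounding happens only
  at display.
* Every stochastic step takes an explicit seed or `numpy.random.Generator`;
  pipeline runs are byte-identical for a fixed seed and config, and output
  JSONs carry a config hash.

## Problem sizes

Default analyses run on 64³ grids (≈ 11 000 liver voxels, 10⁶ counts);
the labeling-oracle comparisons use 32³ phantoms and the recovery study
2.4-mm grids of 120×120×96. These sizes keep the full suite and the
acceptance script in the tens of seconds on one CPU while leaving every
estimator in its asymptotic regime (counting error ≪ thresholds of
interest).

## Known limitations

* The margin rule assumes margin counts are tumor spill-out; in a liver
  with genuinely hot peri-tumoral parenchyma it discards real normal-liver
  signal.
* Counts-as-activity ignores scatter/attenuation and any SPECT calibration;
  only relative weights matter, absolute activities enter through A₀.
* The mean normal-liver dose is mass-weighted by default; an unweighted
  mean across territories is available and gives different plans when
  territory uptake densities differ.
* Territory quality is bounded by the vessel segmentation and image
  resolution; the graph stage can merge generations whose junctions fall
  within a voxel of each other.
* Lung dose uses the single-compartment shunt model; no lung volume
  heterogeneity.
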