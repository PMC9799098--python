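# Methods

`calyxmorph` measures morphometric quantities of the medial nucleus of the
trapezoid body (MNTB) — the auditory brainstem nucleus whose principal
neurons (PNs) receive the giant calyx of Held (CH) terminal — from labeled
(segmented) volume-EM stacks. This note records the models, parameter
choices, numerical conventions and known limitations. Everything stated here
is computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from external measurements.

## Data model and conventions

A scene is an `AnnotatedVolume`: a 3D integer label grid with a physical
voxel pitch per axis, ordered (X, Y, Z) = (dorso-ventral, medio-lateral,
rostro-caudal). The medio-lateral Y axis is the tonotopic axis: lateral =
low frequency (LF), medial = high frequency (HF). Voxel `(i, j, k)` spans
the half-open box `[i·px, (i+1)·px) × …` and its center sits at
`(i+0.5)·pitch`; centroids and all footprint tests use voxel centers, so
the physical extent is exactly `shape × pitch`.

Two distinct surface-area conventions exist and are never mixed within one
statistic:

* **exposed-face area** (segment table): the count of voxel faces between a
  segment and its complement, weighted by the anisotropic face areas. It is
  deterministic and exactly reproducible, but overestimates a smooth surface
  (≈1.5× for a sphere).
* **mesh area/volume** (`segment_mesh`): marching cubes on the binary mask
  with physical spacing. Mesh volume agrees with voxel volume to well under
  5% for blobs ≥ 5 µm across (the unit test measures ≈0.1% for a 10 µm
  ball at 250 nm pitch).

PN identification uses an equivalent-sphere-diameter screen of 20–30 µm
(`d = (6V/π)^{1/3}`). The defining study does not state how "diameter" was
measured on real cells; the equivalent-sphere convention is adopted because
it is rotation-invariant and computable from labels alone.

## Synthetic scenes and ground truth

The raw EM volumes behind the original study are not deposited, so every
stage is validated against generated label volumes with exact ground truth
(`GroundTruthManifest`). The generator works at a coarsened desk-scale
pitch — full-resolution SBEM grids (15×15×50 nm) of a whole nucleus are
~10¹² voxels — and all measurement code accepts any pitch.

* **Somas** are superellipsoids (exponent 2.2, mild ±5% axis eccentricity —
  mildly blocky and non-spherical to avoid symmetric-special-case bugs),
  with semi-axes normalized by `(π/6 / (Γ(1+1/e)³/Γ(1+3/e)))^{1/3}` so the
  rendered equivalent-sphere diameter equals the nominal one. Diameters
  are uniform in 20–26 µm (20–23 µm in the 12-cell scene, where tighter
  packing along the tonotopic line is needed).
* **Placement.** Whole-nucleus scenes use stratified random sequential
  placement: exact per-third counts at the target LF:HF density ratio
  (largest-remainder allocation), uniform positions within each third,
  and minimum-image (toroidal) overlap exclusion. The toroidal metric
  matters: naive rejection sampling at ~20% packing produces a wall excess
  of cells at the block faces and a density-dependent thinning that
  compresses the gradient; both artifacts were measured at the 5–10% level
  before this choice. Per-cell reconstruction scenes place 12 cells on a
  staggered line along the tonotopic axis. Cells may be clipped at the
  block faces ("clip" mode — as a real imaged block clips cells) or kept
  fully interior ("inset").
* **Calyces** are shell sectors 1–1.5 µm thick wrapping a geodesic cap of
  the soma. The cap half-angle is calibrated on the soma's surface voxels
  (quantile of angles around the cap axis) so the covered surface fraction
  hits the target; the manifest stores the *achieved* fraction, recounted
  from the painted voxels by an independent surface-adjacency oracle
  (26-neighborhood). Coverage targets must stay below 0.95; the polar gap
  hosts a thin axon cone (radius 1 µm) that marks the calyx as a terminal
  with an afferent, mirroring the axonal-cone identification criterion.
* **Swellings** are spherical lobes (radius 3 µm ≥ 2× shell thickness)
  attached outside the shell on a spherical-Fibonacci layout, with a
  packing-feasibility check (error, or clamping when counts were drawn
  from a range). A lobe that would be blocked by a neighboring structure
  is dropped and unpainted rather than rendered partially, so the manifest
  count always equals what a counter can see.
* **Boutons** (non-calyceal inputs) are ~0.75 µm-radius spheres apposed to
  the soma outside the calyx caps, Poisson counts with a linear
  medio-lateral gradient (defaults 74 lateral → 90 medial per cell,
  matching the reported LF/HF means for young animals).
* **Pigments** are log-normal-diameter spots (geometric mean 1.8 µm,
  σ_log 0.35, clipped to 0.7–5.2 µm) carved from the soma interior; the
  manifest stores the achieved equivalent diameter of each rendered spot.
* **Degeneration** fragments a calyx (removes the cap pole, detaching the
  axon cone, plus ≥3 azimuthal wedge cuts placed in the gaps between
  lobes, verified to leave ≥3 connected components) and roughens a PN
  membrane by carving correlated radial dips (Gaussian-filtered noise,
  σ = 3 voxels, depth up to 18% of the radius).

What the generator does **not** emulate: EM grayscale texture, segmentation
split/merge errors, dendrites and axons of the PNs themselves, glia,
myelin, and realistic (50% packing) cell density — real MNTB tissue is
denser than non-overlapping quasi-spheres can be packed by this scheme.
Passing recovery tests therefore demonstrate correctness of the measurement
algorithms on clean labels, not robustness to segmentation noise.

## Soma coverage (dilation shells)

Coverage of a PN soma by calyceal terminals is measured with voxel-set
operations, radii in voxel units (digital Euclidean balls, i.e. all offsets
with ‖o‖ ≤ r — the pixel-radius convention of the original protocol, kept
even on anisotropic grids; an optional physical mode takes radii in µm with
anisotropic elements):

* `S = dilate(soma, r_soma=3) \ soma` — the thin outer shell. (The
  protocol's phrasing "dilated volume subtracted from the original" is
  set-theoretically empty; the outer crust is the only reading that yields
  a shell.)
* `A = dilate(calyx, r_axon=6)` — bridges the membrane/cleft gap.
* `M = dilate(manual soma outline, r_guard=30)` — tolerates annotation
  errors < 20 voxels and cuts dendrite trunks from supervoxel somas.
* `f = |S∩M∩A| / |S∩M|`, per calyx; per-cell total = Σ per-calyx f, with
  an overlap flag when the union-based fraction is > 1 pp short of the sum.

Dilations by large radii are computed as thresholds on the exact Euclidean
distance transform (identical to the ball dilation, verified by offset
enumeration in the tests).

**Discretization bias.** `A` spills ~r_axon voxels laterally past the cap
rim, inflating `f` by ≈ 3·sinθ/R (R = soma radius in voxels, θ = cap
half-angle): ~+4 pp at R=75, ~+2 pp at R=120. The coverage-recovery scenes
therefore use ~24 µm somas at 100 nm pitch (R ≈ 120), where measured
fractions recover ground truth within 3 pp at the default radii (observed
max error ≈ 2.3 pp over targets 0.10–0.75). At the native 15 nm pixel size
of real SBEM data the same ratio is r_axon/R ≈ 6/830, i.e. the bias is
negligible there.

## Stereology (cube sampling)

Whole-volume density is count/volume. Regional density follows the cube
protocol: 70 µm cubes (0.000343 mm³) placed uniformly at random inside each
tonotopic region (four per region, averaged; placements may overlap — the
protocol does not forbid it). The tonotopic axis is cut into equal thirds
(lateral/central/medial) by default; the cut positions are configurable.

A cell is counted when ≥ 60% of its projected footprint (the voxel-column
shadow on each axis-aligned plane) lies inside the cube's square in at
least two of the three planes — the only reading of the counting rule that
is defined for a 3D object.

**The rule is not an unbiased counting frame.** A convex cell of radius r
crossing one face is excluded once its center is nearer than δ = 0.158·r
to the face (the 60% chord depth of a disk), so the effective sampling box
is ≈ (L−0.32·r)³: an intrinsic undercount of ~13–15% for 20–26 µm somas in
70 µm cubes, confirmed here both by continuum Monte Carlo and on rendered
scenes (measured −9…−20% per region). Absolute cube densities therefore
undershoot a known true density by more than 10%, and the acceptance test
asserting a 10% bound fails by design of the rule itself. The regional
*percentages* (LF vs HF shares) divide out the multiplicative bias and
recover the realized gradient within ~1–2 points (tested); these shares are
the quantity meaningfully compared along the tonotopic axis, and the
whole-volume density — not cube counts — is the right absolute estimator.

Whole-nucleus extrapolation multiplies the imaged count by the
rostro-caudal depth ratio (default full depth 800 µm) and reports two
significant figures (221 cells at 1/10 depth → 2,200 per nucleus).

## Innervation graph and calyx typing

Contacts are face-adjacency counts (6-connectivity across the boundary);
an edge qualifies at ≥ 5 adjacent face pairs (default; suppresses
single-voxel incidental touches — a label-only stand-in for the
ultrastructural cues, vesicles/active zones/axonal cone, that identified
genuine contacts on real data). Contact area = face count × anisotropic face
area. A calyx touching several PNs is attributed to the PN with the
largest contact area (ties: lower id). Poly-innervation = ≥ 2 hosted
calyces. The published regional comparison is the share of poly cells
falling in the LF vs HF region (the printed fractions force this reading,
e.g. 4/6 vs 2/6); central cells are outside the comparison.

Swellings are counted as connected components of the calyx's morphological
opening with a 2.1 µm-radius ball: the shell (≤ 1.5 µm thick) is everywhere
too thin to admit the ball and vanishes, while every lobe (radius 3 µm)
retains a core, so the opening decomposes into exactly one component per
lobe. Components below half the structuring-ball volume are discarded as
slivers; a component far larger than any plausible lobe means the shell
survived and raises an error suggesting a larger radius. This replaces an
inherently manual count with a reproducible one; on real calyces, whose
swellings are less stereotyped, agreement with human counts is not implied.
Complexity types follow the swelling-count rule 0–7 → Type 1, 8–14 →
Type 2, ≥ 15 → Type 3 (the printed rule leaves exactly 15 unassigned;
it is mapped to Type 3 here).

## Pigments and degeneration

Pigment spots are connected components of pigment-class labels; size =
equivalent-sphere diameter from 3D volume (the defining study reports µm
without fixing the measure; the 3D convention is rotation-invariant).
Bins are half-open: [1.2, 2.2) µm, [2.2, 3.4) µm, [3.4, 5.2] µm; spots
below 1.2 µm (frequent staining artifacts) are excluded from reported
counts and spots above 5.2 µm are reported separately (SUPRA) rather than
forced into the top bin. Hosts are the majority label in the one-voxel
26-neighborhood shell; orphan spots warn and carry host −1.

Degeneration is operationalized per structure:

* **fragmentation**: the label splits into ≥ 3 six-connected components —
  degenerate regardless of any score (the hallmark of a disintegrating
  terminal);
* **membrane roughness** (PN somas only): the coefficient of variation of
  boundary-voxel distances to the centroid, in physical units, after
  filling enclosed cavities (pigment granules) so only the outer membrane
  counts. A digital ball scores < 0.02; intact eccentric somas score
  ≤ 0.03; roughened somas score ≥ 0.075. The default threshold 0.06 sits
  inside this gap, consistent with the equal-error calibration
  (`calibrate_threshold`, which lands at ≈ 0.05 on the preset populations);
  classification agrees exactly with generator flags. The score presumes a
  quasi-spherical body and is deliberately not applied to shell-shaped
  calyces.

## Statistics

Two-group comparisons: Wilcoxon rank-sum (the Methods-section name for the
independent-samples Mann-Whitney form), midrank ties, two-sided. Exact
permutation null by subset-sum dynamic programming whenever min(n) ≤ 8
(verified against brute-force enumeration for every size pair up to 8×8,
including ties); otherwise the normal approximation with continuity
correction and tie-corrected variance. Two-sided p doubles the smaller
tail, capped at 1. Note the exact test's granularity: at n = 4 vs 4 the
smallest achievable two-sided p is 2/70 ≈ 0.029, which can never clear a
Bonferroni-adjusted α of 0.0167.

Multi-group comparisons gate through Kruskal-Wallis (tie-corrected H,
χ² reference, via scipy) and follow up pairwise at α = 0.05/m (m = number
of pairwise contrasts; 0.0167 for three age contrasts). Count tables use
the plain Pearson χ² without Yates correction; zero marginals and
non-positive expected counts are errors. Tonotopic trends are ordinary
least squares (R², slope). Summary statistics report mean ± SEM (sd/√n)
and CV (sd/mean, flagged undefined at mean 0).

## Pipeline determinism and problem sizes

`run_pipeline` executes innervation → coverage → stereology →
pigments/degeneration → statistics on one scene, writes CSV tables, a JSON
summary (floats rounded to 6 decimals, keys sorted — reruns are
byte-identical under the same seed) and a log of every radius, threshold
and seed. Validation problem sizes are chosen so the full suite runs on a
single CPU in minutes: 12-cell scenes at 300 nm pitch for graph recovery,
single-cell scenes at 100 nm pitch for coverage, a 320-cell block at
600 nm pitch for stereology; every stochastic check runs over ≥ 50 seeded
replicates.

## Known limitations

* Clean-label validation only; no robustness claims under segmentation
  errors (the study's own automated segmentation degraded on the oldest,
  most degenerated tissue — precisely the regime where label-based
  morphometry is least reliable).
* The cube-counting rule's intrinsic undercount (above) makes absolute
  cube densities low by ~13–15% for PN-sized cells; use whole-volume
  density for absolute numbers.
* The swelling counter is calibrated to the generator's lobe geometry
  (lobe radius ≥ 2× shell thickness); real fenestrated calyces violate
  this regime in places.
* Voxel-unit ball elements reproduce the original pixel-radius protocol
  but make coverage pitch-dependent; compare coverages across datasets
  only at matched pitch, or use the physical-units mode.
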