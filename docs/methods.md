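# Methods

## Physical model

At tDCS frequencies (DC to a few kHz) capacitive and inductive effects in
tissue are negligible, so the electric potential obeys the steady
volume-conduction equation ∇·(σ∇φ) = 0 with piecewise-constant, isotropic
conductivity σ. Electrodes are ideal conducting patches: the potential is
fixed on the scalp surface they cover (all anodes share one terminal value,
all cathodes the other, so current splits freely within a terminal group, as
in a 4×1 ring), and the rest of the head boundary carries zero normal
current. There is no sponge, gel or electrode-impedance model; a
current-controlled stimulator is represented by solving the unit-potential
drive and rescaling to the prescribed total current, which is exact by
linearity. The electric field is E = −∇φ; all dose measures use its
magnitude |E| (V/m).

Default conductivities (S/m): skin 0.465, skull (bone) 0.01, CSF 1.654,
grey matter 0.275, white matter 0.126. The two orders of magnitude between
skull and CSF drive the physics this package exists to model: the skull
blocks and spreads the injected current while the CSF shunts it
tangentially, and the balance of the two sets how electrode geometry maps to
cortical dose.

## Head phantoms

A phantom is five nested tissue shells. The geometry is analytic and
star-shaped: every boundary is r_k(d) = R_k · a(d) · g(d), where R_k are
the nominal shell radii (defaults 92/86/80/78/70 mm: 6 mm skin, 6 mm skull,
2 mm CSF, 8 mm grey matter, white-matter core), a(d) is an ellipsoidal
direction factor (axis ratios right–left, anterior–posterior,
superior–inferior) and g(d) a smooth perturbation built from l = 2,3 real
harmonics, scaled so its peak radial displacement equals the requested
amplitude. Because every shell shares a·g, nesting is structural: no choice
of admissible parameters can make shells cross (amplitudes above 20% of the
outer radius are rejected). The label grid samples this geometry at voxel
centres (RAS mm, 0-based indices, voxel centres at origin + (index+0.5)·h);
eyes, meninges sub-layers and sulci are deliberately absent.

Population variability (uniform draws, per subject): outer radius
87–97 mm, skin 5–7 mm, skull 4–9 mm, CSF 1–3 mm, grey matter 7–9 mm, axis
ratios 0.94–1.02 (RL) / 1.00–1.12 (AP, heads are longer than wide) /
0.96–1.06 (SI), perturbation amplitude 0–2.5 mm. These ranges bracket adult
head-size and tissue-depth variation around the default head; they are the
fixed study conditions for all population results. Sampling and phantom
construction are deterministic under their seeds.

## 10–10 EEG coordinates

Positions are constructed proportionally on each phantom's own scalp, the
way the 10–20/10–10 system is defined: Cz is fixed iteratively as the joint
midpoint of the nasion–inion and preauricular arcs; midline and central
coronal rows subdivide those arcs in 10% steps (C3 at 30% of the LPA→RPA
arc); the 10% circumferential ring passes through Fpz, T7/T8 and Oz with
named positions placed by arc length along the ring (Fp2 at 10% of the
half-ring); FC/CP rows interpolate between the ring and the midline (FC3 at
50% of the FT7–FCz arc). Arcs are central plane sections radially projected
onto the scalp — exact great-circle geodesics on spheres (where the
construction reduces to closed-form angles used as test oracles) and
near-geodesic on the mildly ellipsoidal, perturbed phantoms. Positioning
error emulation (real automated pipelines mislocate electrodes by ~5 mm) is
not applied by default.

## Electrode montages

An electrode is the image of a flat rectangle or disc under the scalp's
exponential map at its centre (geodesic projection), carrying a quadrature
sampling of its area and a boundary polyline. Pad orientation is a fixed
convention — long axis along the scalp left–right direction for bilateral
and M1–SO pads, perpendicular to the surround axis for APPS/LRPS-type pads
— because physical pad orientation is rarely reported. Edge-to-edge distance
is the minimal geodesic distance between footprint boundaries (mean over
anode–cathode pairs for the 4×1 ring); montages with touching or
overlapping footprints are rejected.

The matched-distance size family fixes the edge-to-edge distance of every
variant to that of the 1×1 cm pads at CP3–FC3 by solving for the centre
separation along the CP3–FC3 geodesic (secant refinement against scalp
curvature, converged to 0.1 mm). The distance ladder likewise solves for
baseline +2/+4/+6/+8 cm. A plain centre-offset operation
(`offset_along_ap`) is also provided; note that on a curved scalp moving
centres apart by δ grows the minimal boundary distance by slightly less
than δ (the closest boundary points drift toward pad corners), which is why
the study families are built by solving for the distance itself.

## Discretisation and solver

The conduction equation is discretised by a cell-centred finite-volume
scheme on the voxel grid: 7-point stencil, face conductance σ_face·h with
harmonic averaging of the two adjacent voxel conductivities, Dirichlet
electrode faces as half-cell couplings 2σh on the outward scalp faces whose
centres fall inside a footprint. The resulting operator is a symmetric
M-matrix.

Labelled voxels alone resolve the thin shells poorly: the staircased 6 mm
skull lets fluctuating local thickness leak current (parallel paths average
the conductance, not the resistance), and the 1-voxel CSF layer loses
tangential connectivity. Faces adjacent to an interior tissue boundary are
therefore homogenised from the analytic geometry: the ns³ (ns = 4) sample
block spanning the two cells is reduced slab-wise — arithmetic (parallel)
mean of σ over each face-parallel station, harmonic (series) combination
along the face normal. Against the analytic shell oracle this reduces the
whole-head relative L2 potential error at 2 mm from 17% to 7.2% (28% to 14%
in the brain), and to 3.5% (6.6%) at 1 mm. Faces on the outer scalp
boundary keep the label-based value: a sub-voxel column that exits the head
would series-block legitimate skin current. Homogenised conductances are
cached per phantom and shared by all montages of a subject.

The linear system is solved by conjugate gradients preconditioned with a
geometric multigrid V-cycle: piecewise-constant prolongation, summation
restriction, Galerkin-consistent coarse operators (coarse face conductance =
sum of fine faces on the interface; verified equal to P^T A P in the tests),
red–black Gauss–Seidel smoothing with the colour order reversed between pre-
and post-smooth so the cycle stays symmetric, and a direct factorisation on
the coarsest level. Convergence criterion: relative residual ≤ 1e-8
(configurable); typical cost ~25 iterations, about 2 s per 2 mm solve and
40 s at 1 mm on one CPU. E is recovered per voxel by central differences
restricted to conductive neighbours (one-sided at boundaries).

## Analytic oracle

For concentric spherical layers the potential separates into Legendre
harmonics; per degree l the coefficients of r^l and r^−(l+1) propagate
through the interfaces by continuity of φ and σ∂φ/∂r, the core keeps only
the regular solution, and the surface Neumann condition fixes the overall
scale. The injected current density is expanded either as a point source,
(2l+1)/4πR², or as a uniform spherical cap, whose expansion follows from
∫P_l over the cap. The l = 0 term vanishes for a balanced source–sink pair,
which also fixes the zero-mean gauge. The implementation (numba-accelerated
recurrences for P_l and P_l′) reproduces the homogeneous-sphere closed form
to 1e-15 and its own gradient to 1e-10 of finite differences; the default
truncation order is 300 with a surface tail estimate that warns below
convergence. Solver-versus-oracle comparisons subtract each field's mean
over the compared region (gauge alignment) and are reported as relative L2
errors over the whole conductive volume and over the brain.

## Outcome measures

* **ROI dose**: the ROI centre is the first grey-matter voxel on the ray
  from the C3 scalp point toward the head centre; the measure is the mean
  |E| over grey-matter voxels within 10 mm. The ROI is located once per
  subject and reused for every montage, so montage contrasts are pure
  electrode effects.
* **Whole-brain top-1% dose**: mean |E| over the top 1% by volume of brain
  (GM+WM by default; GM-only by configuration) voxels, with fractional
  weighting of the element at the 1% boundary.
* **Focality volume**: brain volume with |E| ≥ 0.5 × the 99.9th-percentile
  |E|. A literal "volume above the 50th-percentile field" would by
  definition always be half the brain, so the phrase is interpreted as the
  half-maximum volume with a robust (99.9th percentile rather than literal
  maximum) peak; both the level fraction and the peak percentile are
  configuration parameters. Focality and peak location depend only on the
  field's shape and are invariant under current rescaling; the dose
  measures scale linearly.
* **Peak-midpoint offset**: distance from the volume-weighted centroid of
  the supra-99.9th-percentile region to the montage midpoint projected onto
  grey matter (for ring montages, the central electrode's projection).

## Statistics

One-way repeated-measures ANOVA from explicit sums of squares with
Greenhouse–Geisser epsilon computed from the doubly-centred condition
covariance (Huynh–Feldt available); degrees of freedom are multiplied by
epsilon, so two-condition designs give epsilon = 1 exactly. Post-hoc
contrasts use Tukey's HSD with the studentized-range distribution on the
within-subject error mean square and its (k−1)(n−1) degrees of freedom.
Agreement between the ROI and top-1% doses is ICC(3,1) (two-way mixed,
single measure, consistency) — the consistency form is chosen because a
fixed offset between the two measures is expected and uninformative; the
absolute-agreement form ICC(2,1) is available by option. All of these are verified
against brute-force formula evaluation to 1e-10 and cross-checked against
an independent statistics package in the tests. The significance convention
is two-tailed p < 0.05.

## Problem sizes

Default study resolution is 2 mm voxels (~0.4–0.6 M conductive unknowns per
phantom); the solver convergence and oracle checks run at 1 mm (~3.4 M).
The packaged population runs use 20 subjects in the test suite and 8 in the
reproduction script, against 200 in a full-scale design; orderings and
sign-consistency statistics stabilise well below that, while F statistics
scale with the cohort size as usual.

## Known limitations

* Phantoms are smooth shells: no sulci, gyri, interhemispheric fissure,
  eyes or skull inhomogeneity. Absolute dose values differ from MRI-derived
  heads (phantom ROI doses run higher than literature values for the same
  montages), and effects driven by anatomy rather than electrode geometry
  are out of reach. A concrete instance: on real heads the left–right
  surround montage (C1–C5) stimulates a *larger* half-peak volume than the
  anterior–posterior one despite closer electrodes — an anatomy effect,
  plausibly midline-CSF spreading. On shell phantoms focality tracks
  electrode separation, so that particular inversion does not reproduce;
  the size and distance trends, the surround-beats-conventional ROI
  ordering and the ring montage's focality advantage all do.
* The ideal-patch electrode model omits contact impedance and sponge
  spreading; its influence is bounded by the oracle comparison (the
  oracle's uniform-current cap differs from the solver's equipotential
  patch most strongly near the electrode).
* Scalar conductivities: no white-matter anisotropy.
* Absolute doses carry a resolution-dependent bias: refining the grid from
  2 mm to 1 mm lowers the APPS ROI dose by about 12% (the coarse grid
  overestimates trans-skull current; the oracle comparison shows the same
  scale factor shrinking from 1.14 to 1.07). The bias is common to all
  montages solved on the same grid, so within-grid orderings, ratios and
  paired contrasts — the quantities the population studies report — are
  insensitive to it; absolute V/m values should be read with that caveat.
* Central-section "geodesics" are exact only on spheres; on perturbed
  ellipsoids arc errors are second order in the deviation and well below
  electrode-placement uncertainty.
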