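# tdcsim

Electric-field dosimetry for transcranial direct current stimulation (tDCS)
on synthetic head phantoms — no MRI data required.

tDCS pushes a weak direct current (typically 2 mA) through scalp electrodes;
how much of it reaches the cortex depends strongly on where the electrodes
sit, how big they are and how far apart they are. `tdcsim` is a library for
studying exactly those three dials. It provides:

* **Synthetic head phantoms** — five nested tissue shells (skin, skull, CSF,
  grey matter, white matter) with population variability in head size, skull
  thickness, CSF depth and overall shape, built from an analytic star-shaped
  geometry and voxelised onto a regular grid.
* **10–10 EEG coordinates** computed on each phantom's scalp by the
  proportional nested-arc construction (Cz as the joint midpoint of the
  nasion–inion and preauricular arcs, 10% subdivisions, circumferential
  ring, intermediate FC/CP rows).
* **The fifteen study montages** of a four-round electrode-optimisation
  design: conventional bilateral M1 (C3–C4) and M1–supraorbital (C3–Fp2)
  7×5 cm pads, 4×1 high-definition rings, left–right (C1–C5) and
  anterior–posterior (CP3–FC3) pad-surround montages, a matched-distance
  electrode-size family (1×1 → 7×5 cm), a +2…+8 cm inter-electrode distance
  ladder, and the optimised 1×1 cm surround montage moved 2 cm closer.
* **A quasi-static conduction solver**: the current density obeys
  ∇·(σ∇φ) = 0 with Dirichlet conditions on the electrode contact surfaces
  and zero normal current elsewhere; finite-volume discretisation on the
  voxel grid with sub-voxel conductivity homogenisation at tissue
  boundaries, solved by multigrid-preconditioned conjugate gradients to a
  1e-8 relative residual and scaled to the prescribed current.
* **An analytic oracle**: the Legendre-series solution for layered
  concentric spheres with point or spherical-cap current electrodes, used as
  independent ground truth for the solver.
* **Outcome measures** — mean |E| in a 10 mm grey-matter ROI under C3
  (on-target dose), mean |E| of the top 1% of brain voxels (whole-brain peak
  dose), focality volume (brain tissue at or above half the robust peak;
  smaller = more focal), and the offset between the field hot-spot and the
  montage midpoint.
* **Within-subject statistics** — repeated-measures ANOVA with
  Greenhouse–Geisser (or Huynh–Feldt) correction, Tukey-HSD post-hocs on
  the within-subject error term, and ICC(3,1) between the on-target and
  whole-brain dose measures.

## Worked example

```bash
python examples/03_solve_and_metrics.py
```

```
montage APPS: 2.00 mA, residual 9.1e-09
  ROI mean |E|        : 0.467 V/m   (on-target dose)
  99th-pct mean |E|   : 0.417 V/m   (whole-brain peak dose)
  focality volume     : 1.72e+05 mm^3 (brain at >= half the robust peak; smaller = more focal)
  peak-midpoint offset: 2.4 mm
  current through the mid-plane: 2.000 mA (conservation check)
```

This is 2 mA anterior–posterior pad-surround tDCS (anode CP3, cathode FC3,
7×5 cm pads) on the default spherical phantom. The ROI dose (0.467 V/m) is
*above* the whole-brain top-1% dose and the hot-spot sits 2.4 mm from the
montage midpoint — the montage focuses its maximum on the target, which is
precisely the property that distinguishes surround montages from
conventional ones (whose maxima land midway between two distant electrodes,
off target). The full 2 mA cross the separating mid-plane, confirming
current conservation.

Other entry points: `examples/01_build_phantom.py` (anatomy and EEG
coordinates), `02_montages.py` (the fifteen configurations and their
edge-to-edge distances), `04_oracle_check.py` (analytic validation),
`05_population_study.py` (a miniature population study with ANOVA, Tukey
and ICC). A thin CLI wraps the same calls:

```bash
tdcsim simulate --montage APPS --out results_sim
tdcsim study --n 20 --seed 1 --out results_study
tdcsim report --table results_study/study_table.csv
tdcsim validate --voxel-mm 2
```

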