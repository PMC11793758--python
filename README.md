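# archmorph

3D surface morphometry of arch-shaped dental appliances (e.g. occlusal
splints) scanned before and after storage: rigid best-fit alignment of the
two scans, a signed surface-deviation field, cutoff-thresholded deformation
area/volume outcomes, cross-sectional deviation profiles, a sphere-fit
scanner accuracy protocol that derives the cutoff, and an exact paired
Wilcoxon comparison of storage conditions.  A synthetic-specimen module
generates appliance-like meshes with known, parametric deformations so the
whole pipeline is testable end to end without physical scans.

## Components

| module          | what it does |
|-----------------|--------------|
| `mesh`          | `TriangleMesh`, STL (binary/ASCII) and XYZ I/O, vertex normals, surface area |
| `synthetic`     | horseshoe-band appliance generator, parametric deformation fields (posterior shrink, palatal lift, buccal retraction), normal-direction scan noise, calibration-sphere scans |
| `register`      | exact nearest-point-on-surface index, point-to-point ICP with SVD rigid solves (`best_fit_align`) |
| `deviation`     | signed deviation field, ±cutoff classification, the six outcomes (max±, area±, volume±), plane cross-sections, PLY/CSV color-map export |
| `spherefit`     | least-squares sphere fits, repeated-subsample accuracy protocol (trueness/precision), cutoff derivation |
| `paired_stats`  | exact Wilcoxon signed-rank test (full enumeration of the realized rank multiset for n ≤ 20), six-outcome condition comparison |
| `pipeline`      | YAML-configured experiment orchestration with a reproducibility manifest |

## Command line

```bash
# synthesize a deformed, noisy scan
archmorph generate --palatal-lift 0.08 --noise-sigma 0.0279 --seed 1 --out scan.stl

# align a later scan onto an earlier reference
archmorph align --ref w0.stl --test w4.stl --out transform.json --report report.json

# signed deviation analysis (aligns first unless --no-align)
archmorph deviate --ref w0.stl --test w4.stl --cutoff 0.040 \
    --out summary.json --colormap map.ply

# cross-sectional deviation profile (y = frontal plane at 15 mm)
archmorph section --ref w0.stl --test w4.stl --axis y --position 15 --out profile.csv

# scanner accuracy from a calibration-sphere scan (STL or XYZ)
archmorph accuracy --cloud sphere.xyz --true-radius 7.940 \
    --n-points 100 --iters 1000 --seed 1 --out accuracy.json

# paired wet-vs-dry comparison of an outcomes table
archmorph compare --outcomes outcomes.csv --out comparison.csv

# the whole study analog from one config
archmorph run --config configs/default.yaml --out results/
```

The full pipeline emits, per specimen, the three scans (STL), alignment
transforms and convergence reports (JSON) and the six-outcome summaries
(JSON); at the top level `outcomes.csv`, `comparison.csv`/`.json` and a
`manifest.json` with per-file SHA-256 checksums.  Runs are deterministic
per seed (byte-identical outputs).

## Conventions

* Units are millimetres everywhere; the default deviation cutoff is
  0.040 mm (40 µm), derived from scanner trueness + precision rounded up
  to the next 10 µm.
* Deviation sign: positive where the test surface lies on the side the
  reference normal points to.
* Alignment direction: the later scan is aligned onto the earlier
  reference.
* Synthetic arch frame: z is occlusal (up), the posterior arm ends sit at
  +y, palatal = toward the arch midline.
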