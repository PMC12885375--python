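# swmprof

Surface-based profiling of superficial white matter (SWM) microstructure:

1. **Laplace-guided depth surfaces** — solve the Laplace equation in the
   white-matter domain between the GM/WM interface (u=0) and the
   ventricular walls (u=1), then advect the GM/WM mesh along the unit
   potential gradient, emitting a surface each time the accumulated
   streamline length crosses a depth step (histology preset: 50 × 0.06 mm;
   in-vivo preset: 15 × 0.2 mm; 3 mm maximum depth).
2. **Depth profiling** — trilinear volume-to-surface sampling into
   depth × vertex intensity profile matrices, Tukey outlier repair,
   per-depth moments (mean, SD, skewness, excess kurtosis), iterative
   uniform-kernel smoothing (5 iterations, relaxation 0.5), and optional
   curvature regression.
3. **MPC gradients** — microstructural profile covariance (partial
   Spearman correlations controlling the average profile, Fisher-z
   transformed), row-wise top-10% sparsification, normalized-angle
   affinity, and diffusion map embedding (α = 0.5) with variance-explained
   and cross-subject sign alignment.
4. **Context statistics** — FC strength (Σ|Fisher z|), SC strength
   (ln(1+Σw)), short-range masking (geodesic < 35 mm), Spearman
   associations, spin permutation tests, and LOWESS trends.
5. **Phantoms** — slab and spherical-shell segmentations with analytic
   Laplace solutions, depth-dependent intensity volumes with planted
   regional gradients, planted-gradient profile sets, and synthetic
   connectomes, so every stage has a ground-truth oracle.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, one test per acceptance
criterion (solver accuracy vs analytic solutions, surface placement,
sampling exactness, moment/MPC/embedding oracles, planted-gradient
recovery, spin-test calibration, end-to-end determinism).

## CLI

```sh
swmprof phantom --kind slab --out ph/
swmprof sample-swm --seg ph/seg.nii --surf ph/gmwm.surf.gii --preset histology --out stack/
swmprof profile --stack stack/ --vol feature.nii --out profiles.tsv
swmprof moments --profiles profiles.tsv --out moments.tsv
swmprof gradients --profiles profiles.tsv --alpha 0.5 --sparsity 0.9 --out gset/
swmprof associate --gradient g1.gii --feature curv.gii --sphere sphere.gii --n-perm 1000 --seed 7 --out result.json
swmprof run-all --out run/ --seed 0        # full phantom pipeline + provenance
```

Exit codes: 0 ok, 1 user/config error, 2 internal error.

## Layout

```
src/swmprof/
  geometry_io.py    volumes, meshes, per-vertex maps, I/O, mesh geometry
  phantom.py        synthetic segmentations / volumes / profiles / connectomes
  laplace_swm.py    Laplace solver, gradient, surface shifting, equivolumetric
  profiling.py      sampling, outlier repair, moments, smoothing, regression
  gradients.py      MPC, normalized-angle affinity, diffusion embedding
  stats_context.py  strengths, masks, spin tests, correlations, LOWESS
  cli_config.py     YAML config, subcommands, run-all orchestration
```
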