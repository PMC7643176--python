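# corticalmap

3D morphometric mapping of long-bone cortical thickness, with the
multivariate statistics used to compare shaft morphology across groups
of specimens.

## The problem

The cortical bone of a limb-bone shaft (the diaphysis) remodels under
habitual loading, so its thickness topography carries a signal of how an
animal moved during growth — a signal zooarchaeologists and
anthropologists use to infer locomotor behaviour, captivity, or
selective breeding from skeletal remains.  Quantifying that signal
requires turning each bone (a pair of closed triangle meshes: the outer
**periosteum** and inner **endosteum**) into a standardized 2D
"morphometric map" of cortical thickness that can be compared across
specimens, then testing group structure and trait covariation on those
maps.

## The method

For each specimen the pipeline:

1. **Axis and crop** — fits the shaft's long axis as the first principal
   direction of the periosteal vertices, oriented proximal→distal by two
   anatomical landmarks (LM1 on the periosteum near the proximal
   metaphysis, LM2 in the medullary cavity distally).  The diaphysis is
   cropped in two steps: keep material between the planes through LM1 and
   LM2 orthogonal to the axis, then trim 10% of that axial span proximally
   and 5% distally.
2. **Volume** — caps the cut rings and integrates the closed periosteal
   surface (divergence theorem): shaft bone volume including the medulla.
3. **Thickness** — at every periosteal vertex, cortical thickness is the
   exact minimal point-to-triangle distance to the endosteal surface.
4. **Unrolling** — each vertex maps to cylinder coordinates
   `x ∈ [0,1]` (axial fraction) and `y ∈ [0,1)` (azimuth from the cut
   meridian through LM1, mirrored for left bones so sides are comparable).
5. **Standardization** — thickness is min-max scaled to [0,1] per
   specimen and regressed onto a fixed M×100 × K×200 grid by a penalized
   thin-plate-spline (GAM) smoother, `z ~ s(x, y)`, with the
   circumferential coordinate treated as circular and the smoothing
   parameter chosen by generalized cross-validation (GCV).  The result is
   a K×M grid and its 20,000-row `(x, y, z)` long form.  Pooling several
   specimens into one fit gives a group **consensus map** (scored by its
   GCV); subtracting two consensus maps gives a **deformation map**.

On the map matrix `Y` (one flattened grid per specimen row) the package
provides the standard geometric-morphometrics battery as scikit-learn
style estimators:

- `PermutationMANOVA` — factorial MANOVA/MANCOVA with sequential sums of
  squares, Goodall-style pseudo-F, and residual-randomization permutation
  p-values (the one-way case reproduces PERMANOVA on Euclidean distances);
- `MapPCA` — PCA keeping 95% of variance; `CanonicalVariates` — CVA on the
  retained scores, with theoretical minimum/maximum maps per axis;
- `TwoBlockPLS` — 2B-PLS between maps and a trait block (body mass, age,
  bone volume, or muscle ACSA), first-dimension correlation tested by
  permutation;
- `trait_models` — factorial ANOVA, Pearson tests, per-group allometric
  regressions, Bonferroni pairwise comparisons;
- `acsa` — anatomical muscle cross-sectional area,
  `ACSA = (mass / 1.06 g·cm⁻³) / fascicle length`, a muscle-force proxy.

A synthetic-bone generator (`corticalmap.synthetic`) builds hollow
diaphysis phantoms whose wall thickness is an exact analytic field
(base wall + periodic Gaussian "enthesis" bumps), plus CT-like volumes
and whole cohorts with planted group effects, sexual dimorphism and
trait–map covariation — so every stage is validated against analytic
truth without any data download.

## Worked example

```python
import numpy as np
from corticalmap import synthetic as syn
from corticalmap.pipeline import process_specimen
from corticalmap.stats import perm_manova

# one synthetic humerus-like shaft: 3 mm wall plus a 1 mm enthesis
spec = syn.TubeSpec(bumps=(syn.Bump(0.5, 0.25, 1.0),),
                    axial_resolution=80, angular_resolution=48)
pair, landmarks = syn.make_tube_specimen(spec, "demo")
res = process_specimen(pair, landmarks)
print(f"shaft volume: {res.volume_cm3:.2f} cm^3")
print(f"cortical thickness: {res.cloud_mm.z.min():.2f}-{res.cloud_mm.z.max():.2f} mm")
print(f"standardized map: {res.map.grid.shape}, long form {len(res.map.long_form)} rows")

# a two-group cohort with a planted difference, tested by permutation MANOVA
maps, meta = syn.analytic_maps(syn.group_difference_design(delta=0.3, seed=0))
table = perm_manova(maps.to_numpy(), meta, ["group", "sex"],
                    n_perm=999, seed=0).table
print(table.round(3).to_string(index=False))
```

prints

```
shaft volume: 28.76 cm^3
cortical thickness: 2.99-4.00 mm
standardized map: (200, 100), long form 20000 rows
     term  df      SS    R2       F  p_perm
    group   1 142.418 0.943 225.265   0.001
      sex   1   0.424 0.003   0.670   0.412
Residuals  13   8.219 0.054     NaN     NaN
```

The measured volume matches the analytic cylinder (π·10²·span), the
thickness range is exactly the constructed 3–4 mm wall, and the planted
group difference is detected (p = 0.001, the minimum attainable with 999
permutations) while the null sex term is not.

The same pipeline is scriptable from the shell:

```bash
corticalmap simulate --outdir run --seed 1 --n-per-group 6
corticalmap all --outdir run --n-perm 999 --seed 1
```

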