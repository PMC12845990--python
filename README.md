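# vpdp — voxel point-density-proxy radiative transfer for forest LiDAR

`vpdp` evaluates how faithfully UAV and handheld (ground/SLAM) LiDAR point
clouds represent forest canopy structure, for people working in vegetation
remote sensing who want a quantitative, satellite-anchored quality metric for
their point clouds rather than visual inspection. It implements a simplified
radiative transfer scheme in which the per-voxel LiDAR point count stands in
for leaf area density, so no leaf-area inversion is needed: if the simulated
top-of-canopy radiance correlates strongly with what a nadir-viewing satellite
actually measured, the point cloud captured the light-interacting structure
well.

## The model

Point clouds are binned into a regular voxel lattice (isotropic size *s*,
default 0.5 m) storing counts *P<sub>ijk</sub>* (k indexes height upward).
With incident irradiance *I* (set to 1) attenuated along the vertical path,
the transmitted irradiance reaching voxel [i,j,k] is

    I'_ijk = I · exp(−α · P_sum)

where *P*<sub>sum</sub> is the cumulative point count in the voxels of the
same column strictly above *k*, and α (point⁻¹) converts point density into an
attenuation factor. Each occupied voxel reflects upward as a Lambertian
surface with leaf NIR reflectance *R* (default 0.05), attenuated again on the
return path by a second coefficient β:

    I''_ijk = R · I'_ijk · exp(−β · Σ_{k'>k} P_ijk') / π
    I_sum(i,j) = Σ_k I''_ijk

The per-column map *I*<sub>sum</sub> is average-aggregated to the satellite
pixel size (10 m) and compared with observed NIR reflectance by the Pearson
correlation *r*. α and β are calibrated per dataset by a deterministic
coarse-to-fine log-grid search maximizing *r*, with the simulated map
horizontally shifted by up to ±3 m (satellite geolocation tolerance) and the
best shift adopted. Because *I*<sub>sum</sub> is linear in *I* and *R*, the
correlation is invariant to absolute radiometric scale: *r* measures spatial
pattern agreement, i.e. structural fidelity. (Under this purely nadir
geometry both paths traverse the same column counts, so *r* depends on α and
β only through α+β; the fit reports one point on that ridge.)

Structural completeness is measured independently of the satellite by the
coverage gap ratio (CGR): with *V*<sub>All</sub> the occupied-voxel set of the
merged all-platform reference and *V*<sub>c</sub> that of one dataset, per
height bin *z*

    CGR_z = |{v ∈ V_All at z : v ∉ V_c}| / |V_All at z|  ∈ [0, 1].

A synthetic-scene generator (plantation-like stand, virtual aerial scan with
limited returns per pulse, ground scan with trajectory range decay and
upward occlusion, and a model-generated 10 m satellite image with known
coefficients and noise) makes every stage testable end to end.

## Worked example

```python
import numpy as np
from vpdp import (make_standard_scene, fit_alpha_beta, occupancy_set,
                  merge_occupancy, coverage_gap_ratio)

scene = make_standard_scene(seed=1)   # stand + aerial/ground scans + image
for name, grid in [("aerial", scene.aerial_grid), ("ground", scene.ground_grid),
                   ("merged", scene.merged_grid)]:
    fit = fit_alpha_beta(grid, scene.observed)
    print(f"{name:7s} r={fit.r:.3f}  alpha+beta={fit.alpha + fit.beta:.4f}  "
          f"shift=({fit.shift[0]:+.1f}, {fit.shift[1]:+.1f}) m  n={fit.n_pixels}")

ref = merge_occupancy([occupancy_set(scene.aerial_grid),
                       occupancy_set(scene.ground_grid)])
for name, grid in [("aerial", scene.aerial_grid), ("ground", scene.ground_grid)]:
    prof = coverage_gap_ratio(ref, occupancy_set(grid), bin_height=0.5)
    upper = prof.cgr[int(0.75 * len(prof.cgr)):]
    print(f"{name:7s} mean upper-canopy CGR = {np.nanmean(upper):.2f}")
```

prints

```
aerial  r=0.818  alpha+beta=0.0002  shift=(+0.5, +0.5) m  n=128
ground  r=0.759  alpha+beta=2.0000  shift=(+0.0, +0.0) m  n=128
merged  r=0.815  alpha+beta=0.3163  shift=(+0.0, +0.0) m  n=128
aerial  mean upper-canopy CGR = 0.05
ground  mean upper-canopy CGR = 0.88
```

Read: the aerial scan correlates best with the nadir satellite image (it sees
the upper canopy, which dominates the nadir signal), the ground scan misses
88% of the reference's upper-canopy voxels and correlates worse, and merging
does not beat the aerial scan on a nadir metric even though it fills the
structural gaps — CGR and *r* answer different questions. The fitted α+β
differs per platform because the optimizer compensates for each sensor's
density and return behaviour; that is the intended radiometric normalization.

A `vpdp` command-line tool wraps the same operations
(`vpdp density | xsec | voxelize | cgr | simulate | calibrate | validate |
synth ...`); run `vpdp --help`.

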