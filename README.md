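# soilpore

Quantitative analysis of X-ray micro-computed tomography (µCT) scans of
intact soil cores: pore-architecture metrics and particulate organic matter
(POM) decomposition between paired scans.

## Who this is for

Soil scientists and biogeochemists who scan intact cores (typical setup:
~18 µm voxels, 8/16-bit TIFF stacks exported from reconstruction software)
and want a scripted, reproducible version of the classic ImageJ-based
workflow: shading removal, median denoising, contrast stretch, ROI
cropping, solid/pore segmentation with stone exclusion, Minkowski
functionals, continuous pore-size distribution, and fragment-level POM
change detection with pore-shell and root-distance context.

## What it computes

For a segmented, stone-free core volume with voxel edge $a$ (µm):

- **Total porosity** from bulk density: $\phi_t = 1 - \rho_b/\rho_p$ with
  particle density $\rho_p = 2.6\ \mathrm{g\,cm^{-3}}$ by default.
- **Visible porosity** $\phi_v$ = pore voxels / stone-free voxels — the
  fraction in pores larger than the image resolution.  **Sub-resolution
  porosity** is $\phi_t - \phi_v$.
- **Solid–pore interfacial area** from a marching-cubes isosurface of the
  binary pore phase with a fixed digitization calibration (0.92), accurate
  to <1% on digitized spheres of radius ≥ 10 voxels; also the **Euler
  number** of the pore phase.
- **Connectivity** = fraction of pore volume in 26-connected components
  that touch any external face of the volume.
- **Pore-size distribution** by the maximal-inscribed-sphere method: each
  pore voxel gets the radius of the largest ball fully contained in pore
  space that covers it (equivalent to morphological opening by balls of
  decreasing radius); voxel volumes are binned by radius, so the bins sum
  exactly to $\phi_v$.
- **POM decomposition** between co-registered before/after scans, per
  matched fragment:

  $$\mathrm{loss} = \left(1 - \frac{A_a}{A_b}\right) \times 100\,\%$$

  where $A_b$, $A_a$ are the fragment's voxel counts as percent of the
  shared stone-free reference volume.
- **Shell analysis**: pore fraction within 1, 5 and 8 mm Euclidean
  distance of each fragment (optionally by pore-size class), and minimum
  distance to segmented roots.

A phantom generator (`soilpore.phantom`) builds synthetic cores — pore
networks at realistic visible porosity, stone inclusions, POM blobs with
prescribed decomposition, roots, polynomial shading, Gaussian noise — with
exact voxel-level ground truth, so the whole pipeline is testable without
proprietary scan data.

## Worked example

```python
import soilpore as sp

# a standard validation core: 128³ voxels at 18.2 µm, ~16% visible
# porosity, multiplicative shading and sd-8 noise
spec = sp.standard_core_spec(n=128, noise_sd=8.0, seed=1)
vol, truth = sp.generate_phantom(spec)

proc = sp.preprocess_chain(vol)                     # shading → median → contrast
mask = sp.stone_free_basis(sp.segment_solid_pore(proc))
summary = sp.pore_summary(mask, bulk_density_g_cm3=1.29)
psd = sp.pore_size_distribution(mask)

print(f"true visible porosity : {truth.true_visible_porosity:.4f}")
print(f"total porosity        : {summary.total_porosity:.4f}")
print(f"visible porosity      : {summary.visible_porosity:.4f}")
print(f"sub-resolution        : {summary.sub_resolution_porosity:.4f}")
print(f"connectivity fraction : {summary.connectivity_fraction:.4f}")
print(f"interface area        : {summary.interface_area_mm2:.3f} mm^2")
print(f"mean pore radius      : {psd.mean_radius_um():.1f} um")
```

prints

```
true visible porosity : 0.1606
total porosity        : 0.5038
visible porosity      : 0.1641
sub-resolution        : 0.3398
connectivity fraction : 0.9725
interface area        : 19.510 mm^2
mean pore radius      : 171.5 um
```

The segmentation recovers the ground-truth porosity within 0.35 porosity
points through the full conditioning chain; total porosity for a bulk
density of 1.29 g cm⁻³ is 50.4%, of which 16.4% is image-resolved and the
rest sub-resolution.  Nearly all pore volume (97%) connects to the sample
surface, as expected for a channel-bearing macropore network.

POM change between a generated before/after pair:

```python
spec = sp.pom_study_spec(n_fragments=3, n=96, fragment_volume_mm3=0.35, seed=1)
before, truth = sp.generate_phantom(spec)
after, _ = sp.degrade_pom(before, truth, {1: 0.4, 2: 0.0, 3: 0.75}, seed=2)
seg_b = sp.segment_pom(before, 86, 134)
seg_a = sp.segment_pom(after, 86, 134)
for change in sp.compare_pom(seg_b, seg_a, before.voxels.size):
    print(f"fragment {change.fragment_id}: loss = {change.loss_pct:5.1f}%  ({change.status})")
```

```
fragment 2: loss =   0.0%  (matched)
fragment 3: loss =  41.8%  (matched)
fragment 1: loss =  77.9%  (matched)
```

against prescribed losses of 0%, 40% and 75% (fragments are reported in
volume order, so ids differ from the prescription order).

## Command line

```sh
soilpore phantom    --spec spec.yaml --out core/ --seed 1
soilpore preprocess --input core/gray.tif --out proc.tif --voxel-size 18.2
soilpore segment    --input proc.tif --out mask.tif --stone-t 200
soilpore metrics    --mask mask.tif --out reports/ --bulk-density 1.29
soilpore run        --config pipeline.yaml           # everything at once
```

`soilpore run` (and `pom-compare` for paired scans) writes `metrics.csv`,
`psd.csv`, `pom.csv`/`pom_compare.csv` and a `provenance.json` recording
the config, package version and seed; outputs are byte-identical for a
fixed config and seed.

## Layout

- `soilpore.volume` — `GrayscaleVolume` / `PhaseMask` containers
- `soilpore.phantom` — synthetic cores with ground truth
- `soilpore.preprocess` — background removal, median, contrast, crop
- `soilpore.segment` — two-threshold + voted-band segmentation, stones
- `soilpore.pore_metrics` — porosities, Minkowski, connectivity, PSD
- `soilpore.pom` — POM segmentation, loss, shells, root distances
- `soilpore.io` / `soilpore.pipeline` / `soilpore.cli` — formats, config,
  end-to-end runs

See `docs/methods.md` for the modelling choices, parameter defaults, and
known limitations.
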