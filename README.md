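# chromdom

Quantitative analysis of H3K27ac chromatin domains in 3D-SIM nuclear image
stacks.

Super-resolution structured-illumination microscopy resolves acetylated
(H3K27ac-marked) chromatin inside breast-cancer nuclei into discrete 3D
domains whose size, shape and position change with estrogen-receptor
activity: estradiol-stimulated cells show large, elongated, centrally
placed "open" domains with strong ER colocalization, while
estrogen-deprived or antagonist-treated cells show compact, spherical,
peripheral "closed" domains. `chromdom` implements the full image-to-
statistics pipeline needed to quantify that contrast, plus a seeded
synthetic-stack generator with known ground truth for validating every
stage.

## Pipeline

Given a multi-channel Z-stack (DAPI, H3K27ac, and optionally ER or p300)
with 0.06 µm X/Y and 0.15 µm Z spacing:

1. **Z enhancement** — two interpolated slides are inserted between each
   adjacent pair of real slides, each a distance-weighted average
   Î = (2/3)·I_near + (1/3)·I_far, turning the 0.15 µm Z-pitch into a
   near-isotropic 0.05 µm grid.
2. **Nucleus segmentation** — per-slide 2D DAPI thresholding (counts
   > 500), 8-connected components (top 15 by size), morphological
   refinement (fill, 10 dilations, fill), acceptance gates (area
   ≥ 100 000 px, circularity 4πA/P² > 0.4), Sobel boundary extraction,
   and stacking into 3D nuclei.
3. **Channel alignment** — the systematic X/Y offset between the H3K27ac
   and ER channels is found as the Pearson cross-correlation peak over an
   integer shift window and corrected.
4. **Domain detection** — the threshold is the top-0.1-percentile value of
   the H3K27ac background (all voxels outside every nucleus); in-nucleus
   voxels above it are joined into 26-connected 3D components, refined
   per component (fill, 2 dilations, fill) and size-filtered
   (10–100 000 voxels).
5. **Features** — per domain: Pearson correlation of H3K27ac vs ER
   intensities, volume (voxels and µm³), sphericity
   φ = π^(1/3)·(6V)^(2/3)/S with S the marching-cubes isosurface area,
   distance from the domain centroid to the nearest nuclear boundary,
   and a quartile-based volume class (1–4). Per cell: feature means and
   the Gini inequality index G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄).
6. **Statistics** — one-sided Welch t-tests with per-batch t summaries for
   stack-derived features; Shapiro–Wilk/Kolmogorov–Smirnov normality
   gating into Kruskal–Wallis followed by Bonferroni-corrected
   Mann–Whitney U tests for feature tables; configurable significance
   stars (default \* p<0.05, \*\* p<0.01, \*\*\* p<0.001).

## Worked example

```python
import chromdom as cd

# one synthetic estrogen-deprived-like nucleus on the acquisition grid
stack, truth = cd.generate_stack(cd.ed_like_spec(),
                                 grid_shape=(10, 256, 256), seed=1)

# analysis parameters scaled to the 256x256 field of view
cfg = cd.RunConfig(min_nucleus_px=5000, max_shift=6, alignment_max_slides=3)
result = cd.analyze_stack(stack, cfg)

print(len(truth.domains), len(result.domains))
print(result.features[["volume_vox", "sphericity",
                       "boundary_distance_um", "corr_h3k27ac_er"]].mean())
```

prints

```
26 26
volume_vox              1040.923077
sphericity                 0.968934
boundary_distance_um       0.662583
corr_h3k27ac_er            0.964618
dtype: float64
```

All 26 generated domains are recovered. Mean sphericity is high (compact,
near-spherical domains), the mean boundary distance is small (peripheral
placement), and the H3K27ac–ER voxel correlation is recovered after the
generator's deliberate (+3, −2)-pixel ER offset has been estimated and
corrected — run the same example with `cd.e2_like_spec()` to see the
opposite phenotype (larger volumes, lower sphericity, larger distances).

The same pipeline runs from the shell:

```sh
chromdom simulate cell.ome.tif --condition e2-like --seed 1
chromdom enhance cell.ome.tif enhanced.ome.tif
chromdom run-all config.yaml
```

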