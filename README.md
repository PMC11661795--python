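# flycount3d

3-D cell counting and assay quantification for *Drosophila* brain studies.

Counting dopaminergic neurons in confocal stacks is hard because anti-TH
(tyrosine hydroxylase) immunostaining is diffuse and irregular, and the
somata of clusters such as PAM (~100 or more cells per hemisphere) touch
one another: a plain intensity threshold merges neighbours and
undercounts. `flycount3d` implements a seeded 3-D watershed pipeline for
this regime, a simpler threshold counter for the easy regime of bright
nuclear reporters (Histone-YFP, nls-tdTomato), a plausibility filter for
watershed fragments, seeded synthetic-stack generators with exact ground
truth, and the standard behavioural/molecular assay formulas used
alongside such counts (negative-geotaxis performance index, open-arena
locomotion metrics, appetitive-memory index, ratiometric FRET series,
2^−ΔΔCt relative expression).

## The segmentation algorithm

Given an intensity volume *f* on an anisotropic voxel grid, the
dopaminergic-soma pipeline runs:

1. **median filter** (box, radius 1) — suppresses Poisson shot noise;
2. **grayscale closing** (ball, radius 1) — fills small dark pits inside
   somata;
3. **dark suppression** — voxels with *f* < *t* (default *t* = 75 on the
   8-bit scale) are zeroed; the surviving voxels form the foreground mask;
4. **inverse-dome seeding** — the image is inverted so each bright soma
   becomes a basin, and the extended h-minima transform
   *HMIN_h(f) = R^ε_f(f + h)* (morphological reconstruction by erosion of
   *f + h* over *f*) flattens every basin of dynamic ≤ *h* (default
   *h* = 10); the regional minima of the result give exactly one connected
   seed per soma instead of one per noise wiggle;
5. **marker-controlled watershed** — flooding the inverted relief from the
   seeds partitions the mask into one connected region per cell,
   recovering cell shapes and splitting touching somata along their
   intensity necks.

Per-cell measurements (centroid in µm, voxel count, volume, mean
intensity) come out as a tidy table; an RGB overlay of the raw signal and
region boundaries supports manual proof-reading.

## Worked example

```python
from flycount3d import make_cell_stack, pam_cluster_recipe, segment_dopa3d

recipe = pam_cluster_recipe(rng_seed=1)   # ~110 somata, 15 % touching
grid, truth_labels, truth_table = make_cell_stack(recipe)
labels, table = segment_dopa3d(grid)
print(f"segmented {labels.n_labels} cells")
print(table.head(3).to_string(index=False))
```

prints

```
segmented 110 cells
 label  centroid_z  centroid_y  centroid_x  voxels  volume_um3  mean_intensity
     1    4.058020   16.639590   23.860239     586     84.6184      148.226962
     2    3.387097   42.347527   65.613333      93     13.4292      161.634409
     3    3.443299   59.883299   46.529759     291     42.0204      151.326460
```

The recovered count equals the generator's ground truth (110), meaning
every soma — including the fused pairs — received exactly one watershed
region. Each row is one cell: centroid in micrometres (z, y, x), size in
voxels and µm³, and mean staining intensity.

More narrative scripts live in `examples/` (nuclear-reporter counting,
behavioural assays, FRET and qPCR).

## Command line

Every capability is also a subcommand of the `flycount3d` tool:

```sh
flycount3d synth stack --seed 7 --out demo/
flycount3d segment-dopa3d demo/stack.tif --out labels.tif --table cells.csv \
    --overlay overlay.tif --h 10 --dark 75 --spacing 1,0.4,0.4
flycount3d count-nuclei input.tif --threshold 75 --out nl.tif --table nc.csv
flycount3d assay climbing counts.csv
```

Each run writes a JSON manifest of its effective parameters and seed, so
any output is reproducible from its manifest alone. A YAML config file
(`--config`) can hold defaults; explicit flags override it.

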