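# Methods

## Scope and model

`flycount3d` quantifies two kinds of fluorescence signal met when
counting neurons in adult *Drosophila* brains, plus the behavioural and
molecular assays that normally accompany such counts.

**Diffuse soma signal (anti-TH immunostaining).** Somata are bright but
irregular, and cluster neighbours touch. The pipeline treats each soma as
a dome of the intensity relief: after denoising (median filter), pit
filling (grayscale closing) and background suppression (zeroing voxels
below a dark threshold), the image is inverted so domes become basins,
and the extended h-minima transform

    HMIN_h(f) = R^ε_f(f + h)

(reconstruction by erosion of `f + h` over `f`) removes every basin whose
dynamic — the climb needed to escape it — is at most `h`. The regional
minima of the result give one connected seed per soma; a
marker-controlled watershed on the inverted relief, restricted to the
foreground mask, then assigns every foreground voxel to exactly one seed.
Two somata fused by an intensity neck are split when the neck's dynamic
exceeds `h`.

**Compact nuclear signal (Histone-YFP, nls-tdTomato, Dcp-1).** High
contrast and near-spherical shape make a global threshold sufficient:
binarize at intensity ≥ threshold, label connected components, drop
components outside a size window, and optionally re-split fused nuclei
with a watershed seeded from Euclidean distance-transform peaks (the
distance computed in µm so anisotropy is respected). This counter is a
re-interpretation of the classic plugin-style approach from first
principles, not a port; only the default threshold value (75) follows
established practice.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `median_radius` | 1 | voxels | box half-width of the median filter |
| `closing_radius` | 1 | voxels | ball radius of the grayscale closing |
| `dark_threshold` | 75 | intensity (8-bit scale) | background cut; also the watershed mask |
| `h` | 10 | intensity | minimum basin dynamic for a seed |
| `connectivity` | 26 | — | neighbourhood for minima/components |
| `watershed_connectivity` | 6 | — | neighbourhood of the flood (6 leaks least) |
| `min_seed_voxels` | 1 | voxels | optional speck filter on seeds |
| nucleus `threshold` | 75 | intensity | closed lower bound (≥ kept) |
| nucleus `min/max_voxels` | 8 / 100 000 | voxels | size window |
| filter volume bounds | 20–2000 | µm³ | plausible soma volumes |
| `walk_threshold` | 4 | mm/s | ≈ two body lengths/s; strict `>` |
| `immobility_threshold` | 1 | mm/s | ≈ half a body length/s; strict `<` |
| FRET `cfp_floor` | 1 | intensity | excludes pixels with no usable denominator |

Thresholds are expressed in native grid units, so both 8- and 16-bit
stacks work; defaults assume the 8-bit scale. `min_seed_voxels` defaults
to off (1): the h-minima transform already removes noise-induced seeds,
and genuine small somata produce minima plateaus of only 2–3 voxels, so a
larger default silently drops real cells.

Structuring elements are balls **in voxel units**: anisotropy is
deliberately not compensated inside the morphology, matching how
plugin-style tools operate on confocal exports, and the synthetic
generator produces matching anisotropic voxels so the tests exercise the
same regime. Borders use edge replication, which avoids spurious minima
at stack faces.

## Design choices where the design was open

- **Inversion.** Somata are bright, yet seeds are defined via *minima*;
  the pipeline reconciles the two by inverting the preprocessed image
  (bright domes ↔ "inverse domes"). The `invert` flag lets users run the
  opposite convention for stacks where cells appear dark.
- **Watershed relief.** The flood runs on the inverted intensity relief
  (it recovers cell shape from the image itself), not on a distance
  transform — except inside the nuclear counter's optional re-split,
  where shape, not intensity, separates fused nuclei.
- **Tie-breaking.** Ridge voxels equidistant between seeds are assigned
  by the flood's deterministic priority ordering, so repeated runs are
  bit-identical; no randomness exists anywhere in the segmentation path.
- **Sphericity** uses ψ = π^⅓(6V)^⅔/A with surface area A from exposed
  voxel faces scaled by the per-axis face areas. Face counting is exact
  on digital shapes (hence oracle-checkable) but overestimates smooth
  surface area, so a digital ball scores ~0.6–0.7 rather than 1; the
  filter's role is separating compact blobs from sheets and filaments,
  for which this margin is ample. Sphericity and intensity criteria are
  off by default because TH signal is legitimately irregular.
- **Memory PI discard rule** returns `None` (not 0) when either
  reciprocal half scored fewer than 15 flies among the odorants, so
  discarded groups cannot silently enter averages.
- **ΔΔCt baseline** is the mean ΔCt of the control group (Livak form);
  technical replicates are averaged per sample first. The geometric mean
  of control fold changes is exactly 1 by construction.
- **Walking speed** averages only frames strictly above 4 mm/s and is NaN
  when no frame qualifies; walking distance sums *all* displacements. The
  immobility cutoff has no single standard; 1 mm/s is the declared
  default and is recorded in the output metadata.

## Synthetic data: what it emulates and what it does not

The stack generator renders somata as spheres with a flat bright core
(radius r/2) and a Gaussian shoulder, on a uniform background, with
radii drawn from N(2, 0.4²) µm clipped to the realistic soma range
(diameter 3–8 µm), anisotropic voxels (defaults 1 × 0.4 × 0.4 µm; the
PAM-like preset uses 1 × 0.38 × 0.38 µm, 110 cells, 15 % touching), and
per-voxel Poisson noise — the dominant noise source in confocal
acquisition. Touching pairs are equal-radius spheres placed so the
max-of-profiles saddle equals `peak − neck_depth` (default 200 − 60 =
140, safely above the dark threshold and with dynamic well above `h`);
pair axes lie in-plane, because at ~1 µm z-steps two somata fused along
z are not optically resolvable and clusters spread laterally.

Not modelled: the microscope point-spread function, photobleaching,
depth-dependent attenuation, autofluorescence texture, and genuinely
irregular (non-spherical) soma shapes. Passing counts on these stacks
therefore demonstrate the algorithm's correctness on its intended signal
model — bright compact somata with neck-bridged contacts — not
performance on degraded real-world staining, where manual proof-reading
via the overlay export remains part of the workflow.

Trajectory tracks use piecewise-constant speeds with random headings
inside a circular arena (steps keep exact length, so the locomotion
metrics have closed forms); FRET series use constant CFP frames with
YFP = ratio × CFP + Gaussian noise. All generators are pure functions of
(parameters, seed).

## Numerical notes

- Morphology and reconstruction run in float64; inputs are integer grids,
  so all comparisons are exact and the reconstruction fixed point is
  reached without tolerance issues.
- `regional_minima` of a perfectly constant volume is defined as the
  whole volume (one plateau); seed extraction warns on this degenerate
  input.
- The benchmark problem sizes (24 × 160 × 160 voxel stacks, 50 cells, 20
  seeded replicates; 200 random ≤ 6³ volumes for the reconstruction
  oracle; 50 random volumes for watershed invariants) were chosen as the
  package's standard desk-scale benchmark: large enough to place tens of
  non-overlapping somata at realistic density, small enough to iterate
  on freely.
- Intensity-offset equivariance holds exactly: adding a constant c to
  the stack and to `dark_threshold` leaves the labelling unchanged,
  because every stage commutes with the shift inside the foreground mask.

## Known limitations

- Seeds and counts degrade when the neck dynamic between touching cells
  falls below `h`, or when staining drops cells below `dark_threshold`
  (the regime the original assisted-manual workflow handles by manual
  correction on the overlay).
- The watershed assigns *every* masked voxel to some seed, so spurious
  foreground attached to a cell inflates its volume rather than creating
  a new region; the cell filter can only remove whole regions.
- The nuclear re-split is heuristic (distance peaks ≥ 2 voxels apart) and
  is validated for modest fusion (overlap < 30 % of radius), not for
  densely packed clumps.
- No group-level statistics: outputs are tidy per-cell / per-fly /
  per-sample tables intended for standard statistical tooling.
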