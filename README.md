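# cellaxis

Post-segmentation analysis of bacterial single-cell microscopy.

Segmentation and spot-detection programs for bacterial microscopy (Oufti,
MicrobeJ, SuperSegger, Morphometrics, ObjectJ/ChainTracer, iSBatch, ...)
each emit their own output format and ship their own limited plotting.
`cellaxis` is a funnel for those outputs: it converts cell outlines,
fluorescent foci, fluorescent objects, raw TIFF images and genealogy tables
from any of these programs (or any program that can export a delimited
table) into one standard data model, so datasets from different programs,
channels and experiments can be combined, compared and analyzed in a single
pipeline. It is a library plus a thin `cellaxis` command-line tool, aimed at
bacterial cell-biology labs quantifying protein localization and cell-cycle
dynamics.

## The model

Everything is built on one coordinate transform. For each cell outline
(polygon) the **minimum-area enclosing rectangle** is computed by rotating
calipers over the convex hull, giving cell **length** L, **width** W, the
orientation **angle** θ ∈ [−90°, 90°) of the length axis, and the box
center **c**. A point **x** in image coordinates maps into the cell's
internal frame by

    (l, d) = R(−θ) (x − c),    l_rel = l / L,    d_rel = d / W,

so `l` runs along the cell's length axis (0 at mid-cell) and `d` across it.
Spots, object outlines and image pixels are all relativized this way, which
makes differently sized, arbitrarily oriented cells directly comparable.

On top of the transform sit the analytics:

* **length groups / cell towers** — cells split into equal-count groups by
  length; pooled 2-D densities of `(l_rel, d_rel)` per group;
* **demographs** — per-cell length-axis intensity profiles, rows ordered by
  cell length;
* **kymographs** — one cell's length-axis profile stacked over time, with
  pole orientation held consistent by flip-distance minimization;
* **division detection & percentage-of-division** — a division is called
  when cell length drops by more than a fraction δ (default 0.25) between
  consecutive frames; within a complete cycle each frame gets a percentage
  p = 100·(t − t_birth)/(t_div − t_birth), aligning cells with different
  cycle lengths;
* **profile clustering** — per-cell mean fluorescence vs. percentage of
  division, interpolated to a common grid, z-normalized, converted to a
  dissimilarity matrix (Euclidean or 1 − Pearson r) and clustered by
  agglomerative hierarchical clustering.

A synthetic-data module generates every input the toolbox consumes (rod /
coccus / ovococcus outlines, Gaussian-spot images with Poisson noise,
exponentially growing and dividing tracks, planted fluorescence-dynamics
archetypes) with known ground truth, including writers for the supported
import dialects.

## Worked example

```python
import numpy as np
from cellaxis import synthetic, build_dataset, length_groups, density_projection

meshes, truth = synthetic.make_population(50, shape="rod", seed=1)
spots, _ = synthetic.place_spots(truth, pattern="quarter", seed=2)
ds = build_dataset(meshes, spots=spots)

cells = ds.meshframe.cells_table()
print(cells.head(3).round(2).to_string(index=False))

grouping = length_groups(cells, n_groups=5)
print(grouping.summary.round(2).to_string(index=False))

grids = density_projection(ds.spots_relative, grouping)
print("spots per group:", [g.n_spots for g in grids])
print("mean |l_rel| of assigned spots:", round(ds.spots_relative["l_rel"].abs().mean(), 3))
```

prints

```
cell_id  frame_id    source  length  width  angle  center_x  center_y
   c000         0 synthetic   25.24   8.83  81.08     19.79     21.40
   c001         0 synthetic   21.24   7.43 -13.80     62.16     20.32
   c002         0 synthetic   25.99   9.10 -85.04    103.01     20.58
 group  n  mean_length  mean_width
     1 10        17.16        6.00
     2 10        21.13        7.39
     3 10        24.62        8.62
     4 10        28.59       10.01
     5 10        32.69       11.44
spots per group: [20, 20, 20, 20, 20]
mean |l_rel| of assigned spots: 0.247
```

The recovered box fits match the generating parameters (compare
`truth.cells`), the five groups hold exactly 10 cells each, every planted
spot lands in its cell, and the mean `|l_rel|` of ~0.25 reflects the
planted quarter-position localization pattern.

The same pipeline from the shell:

```sh
cellaxis simulate --kind snapshot --seed 1 --n-cells 50 --out sim
cellaxis import --dialect generic --meshes sim/meshes.csv --spots sim/spots.csv --out ds
cellaxis transform --dataset ds --out rel
cellaxis group --dataset rel --n-groups 5 --out groups
```

Every subcommand writes a `run_manifest.txt` (configuration, version, input
checksums) so runs are reproducible from their manifests alone.

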