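# cycifpipe

Automated analysis of **cyclic multiplex immunofluorescence** (CyCIF-style)
tissue imaging: the same FFPE section is stained, imaged, antibody-stripped
and re-stained over several rounds, building a high-plex image one nuclear
counterstain (DAPI) plus a few markers at a time. `cycifpipe` implements the
computational half of that workflow for liver immune phenotyping — e.g.
separating resident Kupffer cells (IBA1⁺CLEC4F⁺) from monocyte-derived
macrophages (IBA1⁺CLEC4F⁻) and mapping them around ductular (CK19⁺) and
proliferating (PCNA⁺) cells — as a reproducible, scriptable pipeline
instead of a chain of interactive GUI tools.

It is aimed at imaging groups who acquire cyclic IF on conventional
microscopes and want deterministic, inspectable processing: every
intermediate is a plain TIFF or CSV, every run writes a manifest with its
parameters and seed, and every stage is validated against a synthetic-tissue
renderer with known ground truth.

## What the pipeline does

1. **Preprocess** — per-channel background subtraction (white top-hat with a
   disk, default radius 50 px) and autofluorescence (AF) removal: given an AF
   reference channel, the leakage coefficient `s` into a marker channel is
   the least-absolute-deviation slope through the origin of marker vs AF on
   high-AF pixels, and `clip(marker − s·AF, 0)` is subtracted. Collagen is
   extracted from a Masson's-trichrome RGB by HSV color thresholding.
2. **Register** — each cycle is mapped onto cycle 0 by a planar affine
   `x_ref = A·x_mov + t` estimated on the DAPI channel: phase-correlation
   translation, then coarse-to-fine Powell refinement of all six parameters
   maximizing normalized cross-correlation. All channels of a cycle are
   warped with the cycle's transform and the experiment is cropped to the
   largest rectangle valid in every cycle.
3. **Segment** — marker masks from a trainable pixel classifier (random
   forest over Gaussian/gradient/Laplacian features at several scales,
   trained from brush labels or an unattended quantile auto-labeler); nuclei
   from the DAPI channel with Otsu thresholding, hole filling,
   distance-transform + watershed splitting of touching nuclei and an area
   filter.
4. **Phenotype** — nuclei expand a few pixels into cells (nearest-nucleus
   tie-break); a cell is positive for a marker when the marker mask covers
   ≥ 30 % of its footprint (nucleus footprint for nuclear markers such as
   PCNA); ordered conjunctive gates assign phenotypes (first match wins).
5. **Spatial analysis** — mass-conserving Gaussian density maps of cell
   centroids; neighbor counts by dilating reference objects (e.g. CK19⁺
   structures) by a disk and counting target cells whose centroid falls
   inside; tumor regions as collagen-encapsulated areas (holes of the
   morphologically closed collagen mask) containing enough PCNA⁺ nuclei,
   with per-region phenotype composition.

A synthetic-tissue module (`cycifpipe.synthetic`) renders multi-cycle
acquisitions from a known cell map — configurable phenotype frequencies,
marker co-expression, per-cycle affine misalignment, background,
a shared AF component, shot-like noise, and an optional tumor scenario with
collagen rings — so every stage above can be scored against ground truth.

## Worked example

Simulate a five-cycle acquisition of 200 cells on a 512 px section and run
the full pipeline on the rendered TIFFs:

```python
from cycifpipe.synthetic import SimulationConfig
from cycifpipe.pipeline import RunConfig, run_pipeline, simulate

cfg = SimulationConfig(image_shape=(512, 512), n_cells=200, rng_seed=1)
paths = simulate(cfg, "demo/bundle")          # cycle TIFFs + panel + truth
result = run_pipeline(RunConfig(
    cycle_paths=paths["cycles"], panel_path=paths["panel"],
    out_dir="demo/run", seed=1,
))
print(result.summary.round(3).to_string(index=False))
```

which prints:

```
phenotype  n_cells  fraction_of_all  pcna_positive_fraction  mean_CK19  mean_CLEC4F  mean_IBA1  mean_PCNA
       KC       63            0.315                   0.365     16.547      121.401    133.077     34.751
     MoMF       59            0.295                   0.203     16.969       17.920    134.193     26.903
 ductular       21            0.105                   0.095    123.382       17.837     19.476     21.550
    other       57            0.285                   0.070     16.939       17.559     18.779     19.657
```

All 200 simulated cells are recovered; the mean-intensity columns show the
expected co-expression structure (KC high in both IBA1 and CLEC4F, MoMF high
in IBA1 only, ductular cells high in CK19), and the PCNA⁺ fractions reflect
the simulated proliferation probabilities (0.3 for macrophages, 0.05
elsewhere). `demo/run/` additionally contains the aligned channels, marker
masks, nuclei labels, per-cell table, per-cycle transforms with similarity
scores, density maps and `manifest.json`.

The same is available from the shell:

```bash
cycifpipe simulate --out demo/bundle --seed 1 --n-cells 200 --shape 512
cycifpipe run --panel demo/bundle/panel.yaml \
    --images demo/bundle/cycle_0.tif --images demo/bundle/cycle_1.tif \
    --images demo/bundle/cycle_2.tif --images demo/bundle/cycle_3.tif \
    --images demo/bundle/cycle_4.tif --out demo/run --seed 1
```

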