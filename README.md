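# mitoradial

Quantification of the subcellular distribution of the mitochondrial
network from multi-channel fluorescence micrographs, at single-cell
resolution.

Biological context: in tumor cells, prolonged hypoxia and perturbations
of mitochondrial import/redox machinery shift the mitochondrial network
from the cell periphery toward the nucleus. Measuring that shift needs a
per-cell, size-independent summary of where the mitochondrial
fluorescence sits between the nucleus and the cell edge. This package
implements such a measurement pipeline, the matching electron-microscopy
size classification, the group statistics, and a synthetic-field
generator that provides ground truth for testing it.

## The measurement

For each field of view with channels DAPI (nuclei, blue), α-tubulin
(cell, red) and a mitochondrial marker such as COXIV or ATP5B (green):

1. **Segmentation.** Nuclei are thresholded with Ridler–Calvard
   (ISODATA) — the iterative threshold `T = (μ_below(T) + μ_above(T))/2`
   — declumped by a distance-transform watershed, and gated to
   equivalent circular diameters in [50, 450] px. Cell boundaries come
   from the tubulin channel (Ridler–Calvard again); a seeded watershed
   grows one cell per nucleus through the foreground. Nuclei or cells
   touching the image border are excluded. The cytoplasmic compartment
   is the cell mask minus the nucleus mask.
2. **Radial profile.** Each cytoplasm is divided into *n* = 5 equally
   spaced concentric rings starting at the nucleus boundary: with
   `d` the Euclidean distance of a pixel to its own nucleus and `D` the
   cell's maximum, a pixel with `u = d/D` lands in ring `⌈u·n⌉`. The
   normalization by `D` makes the rings adapt to cell size. Ring
   fractions are `f_i = (Σ mito intensity in ring i) / (Σ over all
   rings)`; the **perinuclear fraction** is `f₁+f₂` and the
   **peripheral fraction** `f₄+f₅`.
3. **EM morphology.** Mitochondrial section diameters (µm) are grouped
   strictly above vs at-or-below a 1 µm cutoff; each cell is summarized
   by its percentage of large mitochondria.
4. **Inference.** Per-cell values are compared between conditions with a
   two-tailed unpaired Student's t-test (pooled variance), significance
   at p < 0.05; summaries are mean ± SD.

The synthetic generator places non-overlapping cells with elliptical
nuclei and renders mitochondrial puncta from the density
`p ∝ exp(−β·u)` over the cytoplasm, so `β = 0` is uniform placement and
larger β increasingly perinuclear, with the exact expected ring
fractions recorded per cell as ground truth.

## Worked example

Stage a two-condition synthetic experiment (13 fields per condition,
~50 analyzable cells each; `control` has β = 0, `perinuclear` β = 2) and
measure it:

```sh
python analysis/01_simulate_fields.py
python analysis/02_profile_cells.py
```

which prints:

```
measured 104 cells in 26 fields
               mean     std  count
condition
control      0.4448  0.0586     52
perinuclear  0.5991  0.0615     52
perinuclear fraction, control vs perinuclear: t = -13.09, p = 1.42e-23
```

Reading: in the unbiased condition ~44% of mitochondrial fluorescence
sits in the two innermost rings (close to their area share), while the
biased condition concentrates ~60% there; the per-cell contrast is
overwhelmingly significant. `analysis/03_bias_calibration.py` sweeps
β ∈ {0, 0.5, 1, 2, 4} (mean perinuclear fraction 0.448 → 0.732,
strictly increasing) and `analysis/04_em_morphology.py` runs the EM
classification arm (25 cells per condition). Tables land in `results/`.

The same pipeline is scriptable on real data:

```sh
mitoradial run --input input/ --config config.yaml --output out/ --overlays
mitoradial em --diameters em.csv --cutoff 1.0 --output out/
mitoradial simulate --preset two-condition-demo --output demo/ --seed 1
```

where `input/<condition>/*.tif` holds 3-channel TIFF fields (blue =
nuclei, red = cell, green = mitochondria by default; remappable in the
config).

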