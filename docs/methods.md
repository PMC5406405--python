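# Methods

## Measurement model

The pipeline quantifies, per cell, where mitochondrial fluorescence sits
along the nucleus-to-edge axis. The underlying assumptions:

- One nucleus per cell, and each cytoplasmic pixel belongs to the cell
  whose nucleus seeded it. The nuclear subtraction step ties every
  cytoplasm to its own nucleus, so radial distance is always measured to
  the cell's own nucleus mask, never a neighbor's.
- Fluorescence intensity in the mitochondrial channel is proportional to
  local mitochondrial mass. Fractions are therefore intensity-weighted
  ("fluorescence mass"), not object counts, and the mitochondria channel
  is never thresholded.
- Cells partially outside the field cannot be profiled meaningfully, so
  any cell or nucleus with a border pixel is dropped (the strictest
  reading of whole-object inclusion: both the nucleus and the cell must
  be interior).

## Ring geometry

"Equally spaced concentric rings starting from the boundary of the
nucleus" is implemented as equal-width bands of normalized
nucleus-boundary distance: `u = d/D` with `d` the Euclidean distance to
the nearest nucleus pixel and `D` the cell's own maximum, ring
`i = ⌈u·n⌉` (half-open bins on the left; `u = 0` → ring 1, `u = 1` →
ring n). Normalizing per cell by `D` is what makes profiles of small
and large cells comparable — the scale-equivariance test asserts exactly
this. A fixed-pixel-width alternative was considered and rejected
because it confounds cell size with the profile. Distances come from the
exact Euclidean distance transform; brute-force per-pixel oracles in the
tests confirm bit-identical ring labels on small fixtures.

Degenerate inputs: a cell whose cytoplasm is empty after nuclear
subtraction is dropped with a warning; a cell with zero total
mitochondrial fluorescence has an undefined (0/0) profile and is flagged
and excluded from statistics, counted in the run manifest.

## Thresholding

Ridler–Calvard (ISODATA) iterates `T ← (mean(v ≤ T) + mean(v > T))/2`
from the global mean on the exact value multiset — no histogram
rebinning, so no hidden quantization — with ties (`v = T`) in the lower
class, convergence when successive T differ by less than 1e-6 of the
intensity range, and a 500-iteration cap that flags rather than fails.
The method is equivariant under affine intensity maps, which is why raw
intensities are used without normalization. The same operator is used
for the nuclei channel (the choice there was open; one consistent
operator is simpler to reason about and configurable).

## Segmentation details

- Declumping of touching nuclei: watershed on the negated distance
  transform, peaks detected on a lightly smoothed (σ = 1 px) transform
  with minimum separation of half the minimum nucleus diameter; a
  component without a peak keeps one marker so it cannot vanish.
- The nucleus size gate uses the equivalent circular diameter
  `2·√(area/π)`, 50–450 px by default.
- Cells: seeded watershed on inverted tubulin intensity restricted to
  the thresholded foreground (union the nuclei so seeds are always
  inside the mask). On flat plateaus the flooding reduces to
  geodesic nearest-seed growth with deterministic tie-breaking; the
  symmetric two-cell fixture verifies the partition boundary lies on the
  midline to ±2 px. Foreground with no nucleus is not a cell; a nucleus
  wholly outside the foreground loses its cell (logged).
- 8-connectivity everywhere; object labels are consecutive from 1 in
  deterministic order.

## Statistics

Two-tailed unpaired Student's t (pooled variance), df = n_a + n_b − 2;
each cell is one data point, pooled across fields (field identity is
retained in the per-cell table so users can re-aggregate). Welch's
variant is available behind a config switch for sensitivity analysis
but is not the default, and no multiple-testing correction is applied;
raw p-values are reported with the α in use (0.05). Degenerate cases
are explicit: identical constant groups → t = 0, p = 1; zero pooled
variance with unequal means → p at the smallest positive float,
flagged. Type-I calibration under the null (n = 20 per group, 2,000
replicates) is asserted to land in [0.04, 0.06] at α = 0.05.

EM: "above 1 µm" is strict (`d > cutoff`); a diameter exactly at the
cutoff counts as below. Section diameter defaults to the equivalent
circular diameter from section area (robust to boundary noise), with a
max-Feret option since the original manual measurement convention is
ambiguous. The unit of replication for EM inference is the cell
(n = 25 cells per condition in the emulated design).

## Synthetic data

The generator emulates fields of adherent cells: non-overlapping
circular cells (radius 55–70 px), elliptical nuclei (semi-axes
26–34 px, so equivalent diameters land inside the 50–450 px gate),
tubulin filling the cell footprint, and 200 mitochondrial puncta per
cell rendered as Gaussian spots (σ = 1.5 px, peak 1200) placed from the
density `p ∝ exp(−β·u)`. This one-parameter family was chosen because
it is monotone in β, reduces exactly to uniform at β = 0, and
integrates trivially over the realized pixel grid — the recorded
"true" ring fractions are that integral, so measured-vs-true
comparisons carry no discretization bias. Noise is Poisson shot noise
plus Gaussian read noise (SD 20 on a 16-bit scale) over a smooth
background gradient. Three named random streams (geometry, placement,
noise) keep geometry fixed when noise is toggled; every output is a
pure function of (spec, seed).

What the generator does **not** emulate: optics (PSF, chromatic shift),
mitochondrial network topology (filaments, fission/fusion), irregular
cell shapes, intensity inhomogeneity within a cell, or touching cells
with ambiguous boundaries. Passing tests therefore demonstrate the
correctness of the measurement given its segmentation, and the
sensitivity of the perinuclear fraction to a genuine placement bias —
not robustness to every pathology of real micrographs.

EM tables come from a two-component log-normal mixture of section
diameters (small mode median 0.55 µm, σ_log 0.30; large mode median
1.30 µm, σ_log 0.25; the large-mode weight is the condition knob), with
optional truncation and a closed-form truncation-adjusted expectation of
the >1 µm percentage for calibration tests.

## Problem sizes

Simulation-backed tests and the acceptance script use 13 fields of
512×512 px with 4 cells each (~50 interior cells) per condition or β
level, and 2,000 replicates for the type-I calibration — sizes at which
every distributional check has comfortable power while the whole suite
runs in a couple of minutes on one CPU.

## Known limitations

- Watershed cell boundaries between genuinely touching cells of unequal
  brightness can deviate from the true contact line; the generator does
  not produce such configurations, so this is untested against truth.
- The ring count (5) and the 2+2 perinuclear/peripheral split are the
  published convention; other splits are configurable but the defaults
  are not revisited.
- The per-cell maximum distance `D` makes the outermost ring sensitive
  to thin cytoplasmic protrusions in irregular cells.
- Field-level clustering is ignored by design (each cell is one
  independent data point); a mixed-effects treatment is out of scope.
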