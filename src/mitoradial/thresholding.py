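"""Ridler–Calvard (ISODATA) automatic thresholding.

The threshold used to delineate cell edges (and, for consistency, the
nuclei channel) is the classic iterative intersection-of-means scheme:
starting from the global mean, the candidate T is repeatedly replaced by
the mean of the two class means it induces,

    T <- ( mean{ v : v <= T } + mean{ v : v > T } ) / 2,

until successive values differ by less than a tolerance.  At the fixed
point the threshold sits midway between the background and foreground
mean intensities.  The iteration runs on the exact value multiset — no
histogram rebinning — so no hidden quantization enters; ties (v == T)
fall to the lower class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MAX_ITER = 500
REL_TOL = 1e-6  # fraction of the intensity range


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    iterations: int
    converged: bool


def ridler_calvard(raster: np.ndarray, max_iter: int = MAX_ITER, rel_tol: float = REL_TOL) -> ThresholdResult:
    """Iterate the mean-of-class-means map to its fixed point.

    Raises ``ValueError`` on a constant raster, where no foreground /
    background separation is possible.  On pathological histograms the
    iteration is capped at ``max_iter`` and flagged unconverged rather
    than failing.
    """
    values = np.asarray(raster, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("empty raster: no foreground/background separation possible")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        raise ValueError("constant raster: no foreground/background separation possible")
    tol = rel_tol * (vmax - vmin)

    t = float(values.mean())
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        lower = values <= t
        t_new = (values[lower].mean() + values[~lower].mean()) / 2.0
        if abs(t_new - t) < tol:
            t = float(t_new)
            converged = True
            break
        t = float(t_new)
    return ThresholdResult(threshold=t, iterations=iterations, converged=converged)


def binarize(raster: np.ndarray, result: ThresholdResult | float) -> np.ndarray:
    """Boolean mask: true exactly where intensity exceeds the threshold."""
    t = result.threshold if isinstance(result, ThresholdResult) else float(result)
    return np.asarray(raster, dtype=np.float64) > t
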