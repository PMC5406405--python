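"""Electron-microscopy mitochondrial size classification.

Per-mitochondrion section diameters (µm) are grouped above and below a
1 µm cutoff and each cell is summarized by the percentage of its
mitochondria strictly larger than the cutoff; condition groups of these
per-cell percentages are then compared with the unpaired t-test.

Diameters may be supplied directly as a CSV (cell_id, diameter_um),
matching manual measurement against a scale bar, or derived from a
labelled section mask with a µm/px scale, using the equivalent circular
diameter 2*sqrt(area/pi) (a max-Feret alternative is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .stats import GroupComparison, ttest_unpaired


@dataclass
class EMRecord:
    cell_id: str
    diameters: list[float]
    pct_large: float


def diameters_from_masks(
    label_raster: np.ndarray, scale: float, mode: str = "equivalent"
) -> list[float]:
    """Per-object section diameter in µm from a labelled mask.

    ``scale`` is µm per pixel.  ``mode='equivalent'`` uses the diameter
    of the circle with the object's area; ``mode='feret'`` the maximum
    Feret (caliper) diameter.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive µm/px (got {scale})")
    if mode not in ("equivalent", "feret"):
        raise ValueError(f"mode must be 'equivalent' or 'feret' (got {mode!r})")
    out = []
    for rp in regionprops(np.asarray(label_raster)):
        if mode == "equivalent":
            d_px = rp.equivalent_diameter_area
        else:
            d_px = rp.feret_diameter_max
        out.append(float(d_px * scale))
    return out


def pct_large(diameters: Sequence[float], cutoff: float = 1.0) -> float:
    """Percentage of diameters strictly greater than the cutoff."""
    d = np.asarray(diameters, dtype=np.float64)
    if d.size == 0:
        raise ValueError("no mitochondria measured for cell")
    return float(100.0 * np.count_nonzero(d > cutoff) / d.size)


def em_records(table: pd.DataFrame, cutoff: float = 1.0) -> list[EMRecord]:
    """Per-cell EM summaries from a (cell_id, diameter_um) table."""
    records = []
    for cell_id, grp in table.groupby("cell_id", sort=True):
        d = grp["diameter_um"].tolist()
        records.append(EMRecord(cell_id=str(cell_id), diameters=d, pct_large=pct_large(d, cutoff)))
    return records


def em_summary_table(records: Sequence[EMRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cell_id": r.cell_id, "n_mito": len(r.diameters), "pct_large": r.pct_large}
            for r in records
        ],
        columns=["cell_id", "n_mito", "pct_large"],
    )


def compare_em_groups(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """t-test on per-cell percentages of large mitochondria between two conditions."""
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 condition groups (got {len(groups)})")
    (la, va), (lb, vb) = sorted(groups.items())
    return ttest_unpaired(va, vb, alpha=alpha, labels=(la, lb))
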