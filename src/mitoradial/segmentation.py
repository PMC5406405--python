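"""Nucleus and cell segmentation with size gating and border exclusion.

Whole DAPI-stained nuclei are identified by Ridler–Calvard thresholding
of the nuclei channel, hole filling, distance-transform watershed
declumping, and an equivalent-circular-diameter gate (50–450 px by
default).  Cell boundaries come from the α-tubulin channel: within its
thresholded foreground every pixel is assigned to a cell by a seeded
watershed growing from the retained nuclei, so each cell carries the
label of its seed nucleus and contains it.  Objects touching the image
border are excluded, and the cytoplasmic compartment of each retained
cell is the cell mask minus its nucleus mask.

Conventions: 8-connectivity throughout; row-major 0-based indices; a
pixel is on the border iff its row or column index is 0 or the last
index; "diameter" means the equivalent circular diameter 2*sqrt(area/pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .io_formats import FluorescenceField, RunConfig
from .thresholding import binarize, ridler_calvard

logger = logging.getLogger(__name__)


@dataclass
class ObjectInfo:
    label: int
    area: int
    equivalent_diameter: float
    centroid: tuple[float, float]
    touches_border: bool


@dataclass
class LabeledObjects:
    """Labelled 8-connected objects: 0 = background, k > 0 = object k."""

    label_raster: np.ndarray
    objects: list[ObjectInfo] = field(default_factory=list)
    pre_gate_count: int = 0  # objects found before any size gate

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def mask(self, lbl: int) -> np.ndarray:
        return self.label_raster == lbl


@dataclass
class CellRecord:
    """One retained cell: nucleus, whole-cell and cytoplasm masks."""

    field_id: str
    cell_id: int
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    condition: str = ""


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def _collect(label_raster: np.ndarray) -> LabeledObjects:
    objs = []
    for rp in regionprops(label_raster):
        minr, minc, maxr, maxc = rp.bbox
        touches = (
            minr == 0
            or minc == 0
            or maxr == label_raster.shape[0]
            or maxc == label_raster.shape[1]
        ) and _touches_border(label_raster == rp.label)
        objs.append(
            ObjectInfo(
                label=int(rp.label),
                area=int(rp.area),
                equivalent_diameter=float(rp.equivalent_diameter_area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                touches_border=touches,
            )
        )
    objs.sort(key=lambda o: o.label)
    return LabeledObjects(label_raster=label_raster, objects=objs)


def relabel_consecutive(label_raster: np.ndarray, keep: list[int]) -> np.ndarray:
    """Keep the given labels, renumbered 1..k in ascending original order."""
    out = np.zeros_like(label_raster)
    for new, old in enumerate(sorted(keep), start=1):
        out[label_raster == old] = new
    return out


def identify_nuclei(field: FluorescenceField, config: RunConfig | None = None) -> LabeledObjects:
    """Segment whole nuclei from the DAPI channel and apply the diameter gate."""
    config = config or RunConfig()
    raster = field.channels["nuclei"]
    try:
        th = ridler_calvard(raster)
    except ValueError:
        # constant channel: nothing to segment
        return LabeledObjects(label_raster=np.zeros(raster.shape, dtype=np.int32))
    mask = ndi.binary_fill_holes(binarize(raster, th))
    if not mask.any():
        return LabeledObjects(label_raster=np.zeros(raster.shape, dtype=np.int32))

    comps = sk_label(mask, connectivity=2)
    dist = ndi.distance_transform_edt(mask)
    # slight smoothing removes plateau jitter so elongated nuclei yield one peak
    smooth = ndi.gaussian_filter(dist, 1.0)
    min_sep = max(1, int(config.nucleus_diameter_min / 2))
    coords = peak_local_max(smooth, min_distance=min_sep, labels=comps, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    # a component too small to host a peak keeps itself as one marker
    seeded = set(np.unique(comps[markers > 0]))
    next_marker = len(coords) + 1
    for comp_lbl in np.unique(comps):
        if comp_lbl == 0 or comp_lbl in seeded:
            continue
        rr, cc = np.nonzero(comps == comp_lbl)
        best = np.argmax(dist[rr, cc])
        markers[rr[best], cc[best]] = next_marker
        next_marker += 1
    labels = watershed(-dist, markers, mask=mask, connectivity=2)

    props = regionprops(labels)
    keep = [
        rp.label
        for rp in props
        if config.nucleus_diameter_min <= rp.equivalent_diameter_area <= config.nucleus_diameter_max
    ]
    out = _collect(relabel_consecutive(labels, keep))
    out.pre_gate_count = len(props)
    return out


def identify_cells(field: FluorescenceField, nuclei: LabeledObjects) -> LabeledObjects:
    """Grow one cell per retained nucleus through the tubulin foreground.

    Seeded watershed on the inverted tubulin intensity restricted to the
    thresholded foreground (each cell keeps its seed nucleus' label);
    foreground components containing no nucleus are discarded, and a
    nucleus falling entirely outside the foreground loses its cell.
    """
    if nuclei.n_objects == 0:
        raise ValueError("no retained nuclei to seed cells from")
    raster = field.channels["cell"]
    th = ridler_calvard(raster)
    foreground = binarize(raster, th)

    markers = np.zeros(raster.shape, dtype=np.int32)
    dropped = []
    for obj in nuclei.objects:
        nuc = nuclei.mask(obj.label)
        if not (nuc & foreground).any():
            dropped.append(obj.label)
            logger.warning(
                "field %s: nucleus %d lies entirely outside the cell-channel "
                "foreground; cell discarded",
                field.field_id,
                obj.label,
            )
            continue
        markers[nuc] = obj.label
    grow_mask = foreground | (markers > 0)
    labels = watershed(-raster, markers, mask=grow_mask, connectivity=2)
    labels = labels.astype(np.int32)
    return _collect(labels)


def exclude_border(objects: LabeledObjects) -> LabeledObjects:
    """Remove every object with a pixel on the image border; relabel 1..k."""
    keep = [o.label for o in objects.objects if not o.touches_border]
    return _collect(relabel_consecutive(objects.label_raster, keep))


def build_cell_records(
    field: FluorescenceField,
    nuclei: LabeledObjects,
    cells: LabeledObjects,
    config: RunConfig | None = None,
    condition: str = "",
) -> list[CellRecord]:
    """Pair nuclei with their cells, enforce whole-object rules, subtract nuclei.

    A cell is retained only if both it and its nucleus lie wholly in the
    interior of the image; its cytoplasmic compartment is the cell mask
    minus the nucleus mask, and must be non-empty.
    """
    nuc_labels = {o.label for o in nuclei.objects}
    cell_labels = {o.label for o in cells.objects}
    if not cell_labels <= nuc_labels:
        raise ValueError(
            f"field {field.field_id!r}: cell labels {sorted(cell_labels - nuc_labels)} "
            "have no matching nucleus (cells must be seeded from nuclei)"
        )
    records: list[CellRecord] = []
    cell_id = 0
    for lbl in sorted(cell_labels):
        nuc = nuclei.mask(lbl)
        cell = cells.mask(lbl)
        if not (nuc & ~cell).sum() == 0:
            # watershed guarantees nucleus ⊆ cell; anything else is a bug upstream
            raise ValueError(f"field {field.field_id!r}: nucleus {lbl} not contained in its cell")
        if _touches_border(cell) or _touches_border(nuc):
            continue
        cytoplasm = cell & ~nuc
        if not cytoplasm.any():
            logger.warning(
                "field %s: cell %d has empty cytoplasm after nuclear subtraction; dropped",
                field.field_id,
                lbl,
            )
            continue
        cell_id += 1
        records.append(
            CellRecord(
                field_id=field.field_id,
                cell_id=cell_id,
                nucleus_mask=nuc,
                cell_mask=cell,
                cytoplasm_mask=cytoplasm,
                condition=condition,
            )
        )
    return records
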