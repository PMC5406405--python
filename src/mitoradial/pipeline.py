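"""Orchestration: field discovery → segmentation → radial profiling → statistics.

`run` drives the full analysis over a directory of TIFF fields (or
`run_fields` over in-memory fields), producing a per-cell measurement
CSV, a pairwise condition-comparison CSV, a JSON run manifest whose
counts reconcile exactly with the CSV rows, and optional QC overlays.
Condition labels come from a sidecar CSV (field_id, condition) or from
the `input/<condition>/*.tif` directory layout; the sidecar wins on
conflict.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .io_formats import FluorescenceField, RunConfig, read_field, write_json, write_results
from .radial import profile_cell
from .segmentation import CellRecord, build_cell_records, identify_cells, identify_nuclei
from .stats import compare_all_pairs, summarize_condition

logger = logging.getLogger(__name__)

METRICS = ("perinuclear_frac", "peripheral_frac")


@dataclass
class FieldCounts:
    field_id: str
    condition: str
    nuclei_found: int = 0
    nuclei_size_gated: int = 0
    cells_seeded: int = 0
    cells_border_excluded: int = 0
    cells_retained: int = 0
    zero_fluorescence_cells: int = 0
    error: str = ""


@dataclass
class RunManifest:
    config: dict
    fields: list[FieldCounts] = field(default_factory=list)
    n_cells_total: int = 0
    software_version: str = __version__
    seed: int | None = None
    started: str = ""
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "fields": [vars(f) for f in self.fields],
            "n_cells_total": self.n_cells_total,
            "software_version": self.software_version,
            "seed": self.seed,
            "started": self.started,
            "finished": self.finished,
        }


def profile_field(
    fieldobj: FluorescenceField, config: RunConfig, condition: str = ""
) -> tuple[list[dict], FieldCounts, list[CellRecord]]:
    """Measure every retained cell of one field; returns rows, counts, records."""
    counts = FieldCounts(field_id=fieldobj.field_id, condition=condition)
    nuclei_all = identify_nuclei(fieldobj, config)
    counts.nuclei_found = nuclei_all.pre_gate_count
    counts.nuclei_size_gated = nuclei_all.n_objects
    if nuclei_all.n_objects == 0:
        return [], counts, []
    cells = identify_cells(fieldobj, nuclei_all)
    counts.cells_seeded = cells.n_objects
    records = build_cell_records(fieldobj, nuclei_all, cells, config, condition=condition)
    counts.cells_border_excluded = counts.cells_seeded - len(records)
    rows = []
    kept = []
    for rec in records:
        part, prof = profile_cell(rec, fieldobj.channels["mitochondria"], config)
        if not prof.valid:
            counts.zero_fluorescence_cells += 1
            logger.warning(
                "field %s: cell %d has zero mitochondrial fluorescence; excluded",
                fieldobj.field_id,
                rec.cell_id,
            )
            continue
        row = {
            "field_id": rec.field_id,
            "cell_id": rec.cell_id,
            "condition": condition,
            **{f"ring_frac_{i+1}": float(prof.fractions[i]) for i in range(config.n_rings)},
            "perinuclear_frac": prof.perinuclear_fraction,
            "peripheral_frac": prof.peripheral_fraction,
            "total_fluo": prof.total_fluorescence,
            "cytoplasm_area": int(rec.cytoplasm_mask.sum()),
        }
        rows.append(row)
        kept.append(rec)
    counts.cells_retained = len(rows)
    return rows, counts, kept


def run_fields(
    fields: Iterable[tuple[FluorescenceField, str]],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Full analysis over in-memory (field, condition) pairs.

    Returns the per-cell table, the pairwise comparison table (empty
    with fewer than two conditions), and the manifest.
    """
    config = config or RunConfig()
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    manifest.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    all_rows: list[dict] = []
    for fieldobj, condition in fields:
        try:
            rows, counts, _ = profile_field(fieldobj, config, condition)
        except Exception as exc:  # per-field failures are logged and skipped
            logger.error("field %s failed: %s", fieldobj.field_id, exc)
            counts = FieldCounts(field_id=fieldobj.field_id, condition=condition, error=str(exc))
            rows = []
        manifest.fields.append(counts)
        all_rows.extend(rows)
    manifest.n_cells_total = len(all_rows)
    per_cell = pd.DataFrame(all_rows)

    per_condition = {}
    if not per_cell.empty:
        for cond, grp in per_cell.groupby("condition"):
            per_condition[cond] = grp
    n_fields_by_cond: dict[str, int] = {}
    for fc in manifest.fields:
        n_fields_by_cond[fc.condition] = n_fields_by_cond.get(fc.condition, 0) + 1
    for cond, n in n_fields_by_cond.items():
        if n < 10:
            logger.warning(
                "condition %r has only %d field(s) of view; the reference protocol "
                "analyzed at least 10 per condition",
                cond,
                n,
            )

    comp_frames = []
    if len(per_condition) >= 2:
        for metric in METRICS:
            groups = {c: g[metric].to_numpy() for c, g in per_condition.items() if len(g) >= 2}
            if len(groups) >= 2:
                comp_frames.append(
                    compare_all_pairs(groups, metric, alpha=config.alpha, welch=config.welch)
                )
    comparisons = pd.concat(comp_frames, ignore_index=True) if comp_frames else pd.DataFrame()
    manifest.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return per_cell, comparisons, manifest


def discover_fields(
    input_dir: str | Path, conditions_csv: str | Path | None = None
) -> list[tuple[Path, str]]:
    """Find field TIFFs and their condition labels.

    Layout `input/<condition>/*.tif` labels by directory; a sidecar CSV
    (field_id, condition) overrides directory labels.
    """
    input_dir = Path(input_dir)
    sidecar: dict[str, str] = {}
    if conditions_csv is not None:
        df = pd.read_csv(conditions_csv)
        if not {"field_id", "condition"} <= set(df.columns):
            raise ValueError("conditions CSV needs columns field_id, condition")
        sidecar = dict(zip(df["field_id"].astype(str), df["condition"].astype(str)))
    found: list[tuple[Path, str]] = []
    for p in sorted(input_dir.rglob("*")):
        if p.suffix.lower() not in (".tif", ".tiff") or not p.is_file():
            continue
        cond = p.parent.name if p.parent != input_dir else ""
        cond = sidecar.get(p.stem, cond)
        found.append((p, cond))
    if not found:
        raise FileNotFoundError(f"no TIFF fields found under {input_dir}")
    return found


def write_overlay(
    fieldobj: FluorescenceField,
    records: Sequence[CellRecord],
    config: RunConfig,
    path: str | Path,
) -> Path:
    """QC PNG: nucleus/cell outlines and ring boundaries over the mito channel."""
    import imageio.v3 as iio
    from skimage.segmentation import find_boundaries

    from .radial import ring_partition

    mito = fieldobj.channels["mitochondria"]
    lo, hi = mito.min(), mito.max()
    base = (mito - lo) / (hi - lo) if hi > lo else np.zeros_like(mito)
    rgb = np.stack([base] * 3, axis=-1)
    for rec in records:
        rgb[find_boundaries(rec.cell_mask, mode="outer")] = (1.0, 0.2, 0.2)
        rgb[find_boundaries(rec.nucleus_mask, mode="outer")] = (0.2, 0.4, 1.0)
        part = ring_partition(rec, config.n_rings)
        rgb[find_boundaries(part.ring_raster, mode="subpixel")[::2, ::2] & rec.cytoplasm_mask] = (
            1.0,
            1.0,
            0.2,
        )
    path = Path(path)
    iio.imwrite(path, (rgb * 255).astype(np.uint8))
    return path


def run(
    input_dir: str | Path,
    output_dir: str | Path,
    config: RunConfig | None = None,
    conditions_csv: str | Path | None = None,
    channel_map: Mapping[str, int] | None = None,
    overlays: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, RunManifest]:
    """Disk-to-disk pipeline run; see `run_fields` for the in-memory core."""
    config = config or RunConfig()
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    cmap = channel_map or config.channel_map
    pairs = discover_fields(input_dir, conditions_csv)
    fields = ((read_field(p, cmap), cond) for p, cond in pairs)
    per_cell, comparisons, manifest = run_fields(fields, config)

    if not per_cell.empty:
        write_results(per_cell, output_dir / "per_cell.csv")
        summary = summarize_condition(
            {c: g["perinuclear_frac"].to_numpy() for c, g in per_cell.groupby("condition")}
        )
        summary.to_csv(output_dir / "condition_summary.csv", index=False, lineterminator="\n")
    if not comparisons.empty:
        comparisons.to_csv(output_dir / "comparisons.csv", index=False, lineterminator="\n")
    write_json(manifest.to_dict(), output_dir / "manifest.json")

    if overlays:
        overlay_dir = output_dir / "overlays"
        overlay_dir.mkdir(exist_ok=True)
        for p, cond in pairs:
            fieldobj = read_field(p, cmap)
            _, _, records = profile_field(fieldobj, config, cond)
            write_overlay(fieldobj, records, config, overlay_dir / f"{fieldobj.field_id}.png")
    return per_cell, comparisons, manifest
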