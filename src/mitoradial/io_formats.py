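"""Reading and writing of external artifacts.

Fluorescence fields arrive as multi-channel TIFFs (a page stack, an
interleaved RGB image, or a directory of single-channel files) and are
mapped onto three fixed roles: ``nuclei`` (DAPI, blue), ``cell``
(α-tubulin, red) and ``mitochondria`` (COXIV/ATP5B, green).  Channel
assignment is always explicit — it defaults to the blue/red/green
convention above and is never inferred from pixel content.

Intensities are kept on the raw scale of the source dtype (converted to
float, not rescaled): the Ridler–Calvard threshold used downstream is
equivariant under affine intensity maps, so no normalization is needed
or wanted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

ROLES = ("nuclei", "cell", "mitochondria")

#: blue -> nuclei, red -> cell, green -> mitochondria, on RGB plane order
DEFAULT_CHANNEL_MAP: dict[str, int] = {"nuclei": 2, "cell": 0, "mitochondria": 1}

#: plane order used by :func:`write_field` (matches DEFAULT_CHANNEL_MAP)
_WRITE_ORDER = ("cell", "mitochondria", "nuclei")


@dataclass
class FluorescenceField:
    """One acquired field of view: three same-shaped intensity rasters."""

    field_id: str
    channels: dict[str, np.ndarray]
    height: int
    width: int
    bit_depth: int
    source_path: str = ""

    def __post_init__(self) -> None:
        if set(self.channels) != set(ROLES):
            missing = sorted(set(ROLES) - set(self.channels))
            raise ValueError(f"field {self.field_id!r}: missing channel role(s) {missing}")
        shapes = {role: np.shape(r) for role, r in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"field {self.field_id!r}: channel shapes differ: {shapes}")
        for role, raster in self.channels.items():
            arr = np.asarray(raster, dtype=np.float64)
            if not np.all(np.isfinite(arr)) or arr.min() < 0:
                raise ValueError(
                    f"field {self.field_id!r}, role {role!r}: intensities must be "
                    "non-negative and finite"
                )
            self.channels[role] = arr
        self.height, self.width = next(iter(shapes.values()))


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the analysis.

    Defaults mirror the published pipeline: nuclei accepted between 50
    and 450 px equivalent diameter, five concentric rings with the inner
    two taken as perinuclear and the outer two as peripheral, a 1 µm EM
    diameter cutoff, and two-sided significance at 0.05.
    """

    nucleus_diameter_min: float = 50.0
    nucleus_diameter_max: float = 450.0
    n_rings: int = 5
    perinuclear_rings: int = 2
    peripheral_rings: int = 2
    em_diameter_cutoff: float = 1.0
    alpha: float = 0.05
    seed: int | None = None
    channel_map: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    em_diameter_mode: str = "equivalent"  # or "feret"
    welch: bool = False

    def __post_init__(self) -> None:
        if not self.nucleus_diameter_min < self.nucleus_diameter_max:
            raise ValueError(
                "nucleus_diameter_min must be < nucleus_diameter_max "
                f"(got {self.nucleus_diameter_min} >= {self.nucleus_diameter_max})"
            )
        if self.n_rings < 1:
            raise ValueError(f"n_rings must be >= 1 (got {self.n_rings})")
        if self.n_rings < self.perinuclear_rings + self.peripheral_rings:
            raise ValueError(
                "n_rings must be >= perinuclear_rings + peripheral_rings "
                f"(got {self.n_rings} < {self.perinuclear_rings} + {self.peripheral_rings})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1) (got {self.alpha})")
        if self.em_diameter_mode not in ("equivalent", "feret"):
            raise ValueError(f"em_diameter_mode must be 'equivalent' or 'feret' (got {self.em_diameter_mode!r})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_map"] = dict(d["channel_map"])
        return d


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML/JSON run configuration, applying defaults for absent keys."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path}: expected a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return RunConfig(**data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def _split_planes(arr: np.ndarray, path: Path) -> list[np.ndarray]:
    """Interpret a TIFF array as a list of 2D channel planes."""
    if arr.ndim == 2:
        return [arr]
    if arr.ndim == 3:
        # channel-first page stack vs interleaved RGB(A): channels are few
        if arr.shape[0] <= 4 < arr.shape[-1]:
            return [arr[i] for i in range(arr.shape[0])]
        if arr.shape[-1] <= 4:
            return [arr[..., i] for i in range(arr.shape[-1])]
        return [arr[i] for i in range(arr.shape[0])]
    raise ValueError(f"{path}: cannot interpret array of shape {arr.shape} as 2D channels")


def _bit_depth(dtype: np.dtype) -> int:
    return np.dtype(dtype).itemsize * 8


def read_field(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    field_id: str | None = None,
) -> FluorescenceField:
    """Read one field of view from a TIFF file or a per-channel directory.

    ``channel_map`` maps each of the roles ``nuclei``/``cell``/``mitochondria``
    to a plane index (file order for a directory).  Defaults to the
    blue=nuclei, red=cell, green=mitochondria convention on RGB planes.
    """
    path = Path(path)
    cmap = dict(DEFAULT_CHANNEL_MAP if channel_map is None else channel_map)
    missing = sorted(set(ROLES) - set(cmap))
    if missing:
        raise ValueError(f"{path}: channel map lacks role(s) {missing}")
    if field_id is None:
        field_id = path.stem if path.is_file() else path.name

    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"{path}: no TIFF files in directory")
        planes, dtypes = [], []
        for f in files:
            arr = tifffile.imread(f)
            if arr.ndim != 2:
                raise ValueError(f"{f}: per-channel files must be single-plane 2D")
            planes.append(arr)
            dtypes.append(arr.dtype)
        dtype = dtypes[0]
    else:
        if not path.is_file():
            raise FileNotFoundError(f"{path}: not a readable file")
        arr = tifffile.imread(path)
        planes = _split_planes(np.asarray(arr), path)
        dtype = np.asarray(arr).dtype

    channels: dict[str, np.ndarray] = {}
    for role in ROLES:
        idx = cmap[role]
        if not 0 <= idx < len(planes):
            raise ValueError(
                f"{path}: role {role!r} mapped to plane {idx}, but only "
                f"{len(planes)} plane(s) present"
            )
        channels[role] = planes[idx]
    return FluorescenceField(
        field_id=field_id,
        channels=channels,
        height=planes[0].shape[0],
        width=planes[0].shape[1],
        bit_depth=_bit_depth(dtype),
        source_path=str(path),
    )


def write_field(field_obj: FluorescenceField, path: str | Path) -> Path:
    """Write a field as a 3-page TIFF (R=cell, G=mitochondria, B=nuclei order).

    Rasters are cast back to the source bit depth, so
    ``read_field(write_field(f))`` is the identity on channel rasters.
    """
    path = Path(path)
    dtype = {8: np.uint8, 16: np.uint16, 32: np.float32, 64: np.float64}.get(field_obj.bit_depth)
    if dtype is None:
        raise ValueError(f"unsupported bit depth {field_obj.bit_depth}")
    stack = np.stack([field_obj.channels[r].astype(dtype) for r in _WRITE_ORDER])
    tifffile.imwrite(path, stack, photometric="minisblack")
    return path


RESULT_COLUMNS_FIXED = ["field_id", "cell_id", "condition"]
RESULT_COLUMNS_TAIL = ["perinuclear_frac", "peripheral_frac", "total_fluo", "cytoplasm_area"]


def results_columns(n_rings: int = 5) -> list[str]:
    return (
        RESULT_COLUMNS_FIXED
        + [f"ring_frac_{i}" for i in range(1, n_rings + 1)]
        + RESULT_COLUMNS_TAIL
    )


def write_results(records, path: str | Path) -> Path:
    """Write per-cell measurements to CSV (one row per cell, stable column order)."""
    df = pd.DataFrame(list(records) if not isinstance(records, pd.DataFrame) else records)
    if df.empty:
        raise ValueError("no cell records to write; refusing to create an empty results file")
    n_rings = sum(c.startswith("ring_frac_") for c in df.columns)
    cols = [c for c in results_columns(n_rings) if c in df.columns]
    extras = [c for c in df.columns if c not in cols]
    df = df[cols + extras]
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_em_csv(path: str | Path) -> pd.DataFrame:
    """Read an EM diameter table with columns ``cell_id`` and ``diameter_um``."""
    df = pd.read_csv(path)
    required = {"cell_id", "diameter_um"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: EM CSV must have columns {sorted(required)}")
    if (df["diameter_um"] <= 0).any():
        raise ValueError(f"{path}: diameters must be positive")
    return df


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
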