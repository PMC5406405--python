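"""Seed-deterministic synthetic fluorescence fields with known ground truth.

Fields emulate adherent cultured cells imaged in three channels: DAPI
nuclei (elliptical, bright), an α-tubulin cytoplasm that fills the cell
footprint, and punctate mitochondrial signal rendered as small Gaussian
spots.  Mitochondrial placement over each cell's cytoplasm follows the
density

    p(pixel) ∝ exp(-beta * u),   u = normalized nucleus-boundary distance,

so ``beta = 0`` gives uniform placement and increasing beta an
increasingly perinuclear distribution — a single monotone knob standing
in for the perinuclear accumulation phenotype, integrable per ring over
the realized pixel grid.  Optional Poisson shot noise, Gaussian read
noise and a smooth uneven background complete the image model.

Randomness is split into one named stream per purpose (geometry,
placement, noise) so that toggling noise does not shift geometry draws;
all outputs are pure functions of (spec, seed).

Per-cell ground truth records the realized masks and the exact expected
ring fractions of the placement density integrated over the pixel grid,
so measurements can be compared without discretization bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .io_formats import FluorescenceField, write_field
from .radial import nucleus_distance, ring_labels_from_distance


@dataclass(frozen=True)
class SimSpec:
    """Generator parameters; defaults give in-gate nuclei under the 50–450 px rule."""

    height: int = 512
    width: int = 512
    n_cells: int = 4
    cell_radius: tuple[float, float] = (55.0, 70.0)
    nucleus_radius: tuple[float, float] = (26.0, 34.0)  # ellipse semi-axes range
    n_puncta: int = 200
    puncta_sigma: float = 1.5
    puncta_peak: float = 1200.0
    beta: float = 0.0
    n_rings: int = 5
    nucleus_level: float = 800.0
    tubulin_level: float = 400.0
    background: float = 100.0
    read_noise_sd: float = 20.0
    poisson_noise: bool = True
    bit_depth: int = 16
    border_cells: int = 0  # cells deliberately crossing the image border
    margin: float = 4.0  # interior clearance beyond the cell radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0 (got {self.beta})")
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValueError(
                "largest nucleus radius must be smaller than smallest cell radius "
                f"(got {self.nucleus_radius} vs {self.cell_radius})"
            )
        peak = self.background + max(self.nucleus_level, self.tubulin_level) + self.puncta_peak
        if peak > 2**self.bit_depth - 1:
            raise ValueError(f"intensities up to {peak} exceed bit depth {self.bit_depth}")
        if self.border_cells > self.n_cells:
            raise ValueError("border_cells cannot exceed n_cells")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellTruth:
    cell_index: int
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    centroid: tuple[float, float]
    touches_border: bool
    true_fractions: np.ndarray  # expected ring fractions of the placement density

    @property
    def true_perinuclear(self) -> float:
        return float(self.true_fractions[:2].sum())

    @property
    def true_peripheral(self) -> float:
        return float(self.true_fractions[-2:].sum())


@dataclass
class GroundTruth:
    cells: list[CellTruth] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def interior_cells(self) -> list[CellTruth]:
        return [c for c in self.cells if not c.touches_border]


@dataclass(frozen=True)
class CellGeometry:
    """Explicit geometry for one cell, for hand-built fixtures."""

    center: tuple[float, float]
    cell_radius: float
    nucleus_center: tuple[float, float]
    nucleus_axes: tuple[float, float]
    nucleus_angle: float = 0.0


MAX_PLACEMENT_TRIES = 2000


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    geometry = np.random.default_rng([seed, 0])
    placement = np.random.default_rng([seed, 1])
    noise = np.random.default_rng([seed, 2])
    return geometry, placement, noise


def sample_geometry(spec: SimSpec, rng: np.random.Generator) -> list[CellGeometry]:
    """Place non-overlapping circular cells, optionally some crossing the border."""
    geoms: list[CellGeometry] = []
    h, w = spec.height, spec.width
    for i in range(spec.n_cells):
        on_border = i < spec.border_cells
        for _ in range(MAX_PLACEMENT_TRIES):
            r = rng.uniform(*spec.cell_radius)
            if on_border:
                side = rng.integers(0, 4)
                along = rng.uniform(r, (w if side < 2 else h) - r)
                off = rng.uniform(0.2 * r, 0.6 * r)  # center close enough to cross
                cy, cx = {
                    0: (off, along),
                    1: (h - 1 - off, along),
                    2: (along, off),
                    3: (along, w - 1 - off),
                }[int(side)]
            else:
                cy = rng.uniform(r + spec.margin, h - 1 - r - spec.margin)
                cx = rng.uniform(r + spec.margin, w - 1 - r - spec.margin)
            if all(
                np.hypot(cy - g.center[0], cx - g.center[1]) > r + g.cell_radius + 3
                for g in geoms
            ):
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells after "
                f"{MAX_PLACEMENT_TRIES} tries; reduce cell_radius or n_cells"
            )
        a = rng.uniform(*spec.nucleus_radius)
        b = rng.uniform(*spec.nucleus_radius)
        angle = rng.uniform(0, np.pi)
        max_off = max(r - max(a, b) - 3.0, 0.0)
        rho = rng.uniform(0, max_off)
        phi = rng.uniform(0, 2 * np.pi)
        nc = (cy + rho * np.sin(phi), cx + rho * np.cos(phi))
        geoms.append(
            CellGeometry(
                center=(cy, cx),
                cell_radius=r,
                nucleus_center=nc,
                nucleus_axes=(a, b),
                nucleus_angle=angle,
            )
        )
    return geoms


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy, dx = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dy * ca + dx * sa
    v = -dy * sa + dx * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def _render_puncta(
    canvas: np.ndarray, centers: np.ndarray, sigma: float, peak: float
) -> None:
    """Add a Gaussian spot of the given peak at each (row, col) center."""
    h, w = canvas.shape
    half = int(np.ceil(4 * sigma))
    for cy, cx in centers:
        r0, r1 = max(int(cy) - half, 0), min(int(cy) + half + 1, h)
        c0, c1 = max(int(cx) - half, 0), min(int(cx) + half + 1, w)
        rr = np.arange(r0, r1)[:, None] - cy
        cc = np.arange(c0, c1)[None, :] - cx
        canvas[r0:r1, c0:c1] += peak * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def render_field(
    geoms: Sequence[CellGeometry],
    spec: SimSpec,
    placement_rng: np.random.Generator,
    noise_rng: np.random.Generator,
    field_id: str = "sim",
) -> tuple[FluorescenceField, GroundTruth]:
    """Render channels and ground truth for an explicit cell layout."""
    shape = (spec.height, spec.width)
    nuclei_ch = np.zeros(shape)
    cell_ch = np.zeros(shape)
    mito_ch = np.zeros(shape)
    truth = GroundTruth()

    for i, g in enumerate(geoms, start=1):
        cell_mask = _disc_mask(shape, g.center, g.cell_radius)
        nuc_mask = _ellipse_mask(shape, g.nucleus_center, g.nucleus_axes, g.nucleus_angle)
        nuc_mask &= cell_mask
        cyto = cell_mask & ~nuc_mask
        nuclei_ch[nuc_mask] += spec.nucleus_level
        cell_ch[cell_mask] += spec.tubulin_level

        # placement density exp(-beta * u) over the realized cytoplasm grid
        d = nucleus_distance(nuc_mask)
        rows, cols = np.nonzero(cyto)
        dc = d[rows, cols]
        u = dc / dc.max() if dc.max() > 0 else np.zeros_like(dc)
        wts = np.exp(-spec.beta * u)
        probs = wts / wts.sum()
        idx = placement_rng.choice(len(rows), size=spec.n_puncta, replace=True, p=probs)
        jitter = placement_rng.uniform(-0.5, 0.5, size=(spec.n_puncta, 2))
        centers = np.column_stack([rows[idx], cols[idx]]).astype(float) + jitter
        _render_puncta(mito_ch, centers, spec.puncta_sigma, spec.puncta_peak)

        ring_raster = ring_labels_from_distance(d, cyto, spec.n_rings)
        ring_of_pixel = ring_raster[rows, cols]
        true_frac = np.array(
            [wts[ring_of_pixel == r].sum() for r in range(1, spec.n_rings + 1)]
        )
        true_frac = true_frac / true_frac.sum()
        truth.cells.append(
            CellTruth(
                cell_index=i,
                nucleus_mask=nuc_mask,
                cell_mask=cell_mask,
                centroid=(float(g.nucleus_center[0]), float(g.nucleus_center[1])),
                touches_border=_touches_border(cell_mask) or _touches_border(nuc_mask),
                true_fractions=true_frac,
            )
        )

    channels = {"nuclei": nuclei_ch, "cell": cell_ch, "mitochondria": mito_ch}
    if spec.background > 0:
        yy, xx = np.mgrid[: spec.height, : spec.width]
        bg = spec.background * (0.7 + 0.2 * xx / spec.width + 0.1 * yy / spec.height)
        for ch in channels.values():
            ch += bg
    for role in ("nuclei", "cell", "mitochondria"):
        ch = channels[role]
        if spec.poisson_noise:
            ch = noise_rng.poisson(ch).astype(np.float64)
        if spec.read_noise_sd > 0:
            ch = ch + noise_rng.normal(0, spec.read_noise_sd, size=ch.shape)
        channels[role] = np.clip(ch, 0, 2**spec.bit_depth - 1)

    fieldobj = FluorescenceField(
        field_id=field_id,
        channels=channels,
        height=spec.height,
        width=spec.width,
        bit_depth=spec.bit_depth,
        source_path="<synthetic>",
    )
    return fieldobj, truth


def generate_field(spec: SimSpec, field_id: str = "sim") -> tuple[FluorescenceField, GroundTruth]:
    """Generate one synthetic field; identical spec (incl. seed) → identical output."""
    geometry_rng, placement_rng, noise_rng = _streams(spec.seed)
    geoms = sample_geometry(spec, geometry_rng)
    return render_field(geoms, spec, placement_rng, noise_rng, field_id=field_id)


def generate_fields(
    spec: SimSpec, n_fields: int, prefix: str = "field"
) -> list[tuple[FluorescenceField, GroundTruth]]:
    """A set of fields with per-field seeds derived from the spec seed."""
    out = []
    for k in range(n_fields):
        fspec = replace(spec, seed=int(np.random.default_rng([spec.seed, 100 + k]).integers(2**31)))
        out.append(generate_field(fspec, field_id=f"{prefix}_{k:03d}"))
    return out


# ---------------------------------------------------------------------------
# EM diameter tables


@dataclass(frozen=True)
class EMMixture:
    """Two truncated log-normal section-diameter components (µm).

    Small mode ~ fragmented mitochondria, large mode ~ fused/enlarged;
    the large-mode weight is the knob a condition shifts.
    """

    weight_large: float = 0.3
    small_median: float = 0.55
    small_sigma: float = 0.30
    large_median: float = 1.30
    large_sigma: float = 0.25
    trunc_small: tuple[float, float] | None = None
    trunc_large: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.weight_large <= 1:
            raise ValueError(f"weight_large must be in [0, 1] (got {self.weight_large})")

    def _component(self, median: float, sigma: float):
        return sps.lognorm(s=sigma, scale=median)

    def _trunc_sf(self, median, sigma, trunc, x) -> float:
        """P(D > x) for one component under optional truncation."""
        dist = self._component(median, sigma)
        if trunc is None:
            return float(dist.sf(x))
        lo, hi = trunc
        z = dist.cdf(hi) - dist.cdf(lo)
        xx = min(max(x, lo), hi)
        return float((dist.cdf(hi) - dist.cdf(xx)) / z)

    def expected_pct_large(self, cutoff: float = 1.0) -> float:
        """Closed-form truncation-adjusted expectation of the >cutoff percentage."""
        p = self.weight_large * self._trunc_sf(
            self.large_median, self.large_sigma, self.trunc_large, cutoff
        ) + (1 - self.weight_large) * self._trunc_sf(
            self.small_median, self.small_sigma, self.trunc_small, cutoff
        )
        return 100.0 * p

    def _sample_component(self, median, sigma, trunc, n, rng) -> np.ndarray:
        dist = self._component(median, sigma)
        if trunc is None:
            return dist.rvs(size=n, random_state=rng)
        lo, hi = trunc
        u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=n)
        return dist.ppf(u)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        is_large = rng.random(n) < self.weight_large
        out = np.empty(n)
        n_large = int(is_large.sum())
        if n_large:
            out[is_large] = self._sample_component(
                self.large_median, self.large_sigma, self.trunc_large, n_large, rng
            )
        if n - n_large:
            out[~is_large] = self._sample_component(
                self.small_median, self.small_sigma, self.trunc_small, n - n_large, rng
            )
        return out


def generate_em_table(
    n_cells: int = 25,
    mixture: EMMixture | None = None,
    mito_per_cell: tuple[int, int] = (8, 20),
    cutoff: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-cell EM diameter table with ground truth.

    Returns (long table with cell_id/diameter_um, per-cell truth table
    with the realized >cutoff percentage, and the mixture's closed-form
    expected percentage).
    """
    mixture = mixture or EMMixture()
    rng = np.random.default_rng([seed, 7])
    rows, truth_rows = [], []
    for c in range(1, n_cells + 1):
        n = int(rng.integers(mito_per_cell[0], mito_per_cell[1] + 1))
        d = mixture.sample(n, rng)
        for x in d:
            rows.append({"cell_id": f"cell_{c:03d}", "diameter_um": float(x)})
        truth_rows.append(
            {
                "cell_id": f"cell_{c:03d}",
                "n_mito": n,
                "pct_large": float(100.0 * np.count_nonzero(d > cutoff) / n),
            }
        )
    return (
        pd.DataFrame(rows),
        pd.DataFrame(truth_rows),
        mixture.expected_pct_large(cutoff),
    )


# ---------------------------------------------------------------------------
# Named fixtures


def two_level_raster(shape: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Half-zeros, half-100s raster whose ISODATA threshold is exactly 50."""
    arr = np.zeros(shape)
    arr[:, shape[1] // 2 :] = 100.0
    return arr


def annulus_cell(
    nucleus_radius: float = 10.0, cell_radius: float = 60.0, pad: int = 6
) -> CellGeometry:
    """Concentric disc nucleus inside a disc cell — the analytic-ring fixture."""
    c = cell_radius + pad
    return CellGeometry(
        center=(c, c),
        cell_radius=cell_radius,
        nucleus_center=(c, c),
        nucleus_axes=(nucleus_radius, nucleus_radius),
    )


def symmetric_two_cell_spec(seed: int = 0) -> tuple[list[CellGeometry], SimSpec]:
    """Two identical cells sharing one tubulin blob, mirror-symmetric layout."""
    spec = SimSpec(height=256, width=384, n_cells=2, seed=seed, background=0.0,
                   poisson_noise=False, read_noise_sd=0.0)
    r = 60.0
    geoms = [
        CellGeometry(center=(128.0, 132.0), cell_radius=r,
                     nucleus_center=(128.0, 132.0), nucleus_axes=(28.0, 28.0)),
        CellGeometry(center=(128.0, 252.0), cell_radius=r,
                     nucleus_center=(128.0, 252.0), nucleus_axes=(28.0, 28.0)),
    ]
    return geoms, spec


def six_cell_border_field(seed: int = 11) -> tuple[FluorescenceField, GroundTruth]:
    """Six cells, two of which cross the image border (exclusion fixture)."""
    spec = SimSpec(height=640, width=768, n_cells=6, border_cells=2, seed=seed,
                   poisson_noise=False, read_noise_sd=0.0, background=0.0)
    return generate_field(spec, field_id="six_cell_border")


def make_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the canonical named fixtures with ground-truth CSVs.

    Idempotent for a fixed seed; every fixture round-trips through the
    I/O layer.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    import tifffile

    p = outdir / "two_level.tif"
    tifffile.imwrite(p, two_level_raster().astype(np.uint8))
    written["two_level"] = p

    def _write(name: str, fieldobj: FluorescenceField, truth: GroundTruth, spec: SimSpec):
        fp = outdir / f"{name}.tif"
        write_field(fieldobj, fp)
        truth_df = pd.DataFrame(
            [
                {
                    "cell_index": c.cell_index,
                    "touches_border": c.touches_border,
                    "true_perinuclear": c.true_perinuclear,
                    "true_peripheral": c.true_peripheral,
                    **{f"true_frac_{i+1}": c.true_fractions[i] for i in range(spec.n_rings)},
                }
                for c in truth.cells
            ]
        )
        truth_df.to_csv(outdir / f"{name}_truth.csv", index=False, lineterminator="\n")
        (outdir / f"{name}_spec.yaml").write_text(yaml.safe_dump(spec.to_dict(), sort_keys=True))
        written[name] = fp

    ann_spec = SimSpec(height=144, width=144, n_cells=1, cell_radius=(60, 60),
                       nucleus_radius=(10, 10), poisson_noise=False,
                       read_noise_sd=0.0, background=0.0, seed=seed)
    g, p_rng, n_rng = _streams(seed)
    f, t = render_field([annulus_cell()], ann_spec, p_rng, n_rng, field_id="annulus")
    _write("annulus", f, t, ann_spec)

    geoms, spec2 = symmetric_two_cell_spec(seed)
    g, p_rng, n_rng = _streams(seed + 1)
    f, t = render_field(geoms, spec2, p_rng, n_rng, field_id="two_cell")
    _write("two_cell", f, t, spec2)

    f, t = six_cell_border_field()
    _write("six_cell_border", f, t, SimSpec(height=640, width=768, n_cells=6,
                                            border_cells=2, seed=11, poisson_noise=False,
                                            read_noise_sd=0.0, background=0.0))

    for beta in (0.0, 0.5, 1.0, 2.0, 4.0):
        bspec = SimSpec(beta=beta, seed=seed + int(beta * 10), poisson_noise=False,
                        read_noise_sd=0.0, background=0.0)
        f, t = generate_field(bspec, field_id=f"beta_{beta:g}")
        _write(f"beta_{beta:g}", f, t, bspec)

    return written
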