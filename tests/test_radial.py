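"""Ring partition and radial fluorescence fractions against brute-force oracles."""

import math

import numpy as np
import pytest

import mitoradial as mr
from mitoradial.segmentation import CellRecord


def make_record(nucleus_mask, cell_mask, field_id="t", cell_id=1):
    return CellRecord(
        field_id=field_id,
        cell_id=cell_id,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        cytoplasm_mask=cell_mask & ~nucleus_mask,
    )


def disc_record(r_nuc=10, r_cell=60, pad=6):
    size = int(2 * (r_cell + pad))
    yy, xx = np.mgrid[:size, :size]
    c = r_cell + pad
    d2 = (yy - c) ** 2 + (xx - c) ** 2
    return make_record(d2 <= r_nuc**2, d2 <= r_cell**2)


def brute_force_rings(nucleus_mask, cytoplasm_mask, n_rings):
    """Per-pixel nearest-nucleus distance by exhaustive pairwise search."""
    ny, nx = np.nonzero(nucleus_mask)
    rows, cols = np.nonzero(cytoplasm_mask)
    d2 = (rows[:, None] - ny[None, :]) ** 2 + (cols[:, None] - nx[None, :]) ** 2
    d = np.sqrt(d2.min(axis=1))
    rings = np.clip(np.ceil(d / d.max() * n_rings).astype(int), 1, n_rings)
    out = np.zeros(nucleus_mask.shape, dtype=int)
    out[rows, cols] = rings
    return out


def star_record(size=64):
    """Irregular star-shaped cell around an off-center blob nucleus."""
    yy, xx = np.mgrid[:size, :size]
    cy = cx = size / 2
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    cell = rho <= 18 + 8 * np.cos(5 * theta)
    nuc = (yy - (cy - 3)) ** 2 + ((xx - (cx + 2)) / 1.4) ** 2 <= 5**2
    nuc &= cell
    return make_record(nuc, cell)


class TestRingPartition:
    def test_annulus_matches_analytic_areas(self):
        rec = disc_record()
        part = mr.ring_partition(rec, 5)
        analytic = [
            math.pi * ((10 + 10 * i) ** 2 - (10 + 10 * (i - 1)) ** 2) for i in range(1, 6)
        ]
        for got, want in zip(part.ring_areas, analytic):
            assert got == pytest.approx(want, rel=0.03)

    def test_partition_is_exact_and_exhaustive(self):
        rec = star_record()
        part = mr.ring_partition(rec, 5)
        assert np.array_equal(part.ring_raster > 0, rec.cytoplasm_mask)
        assert part.ring_areas.sum() == rec.cytoplasm_mask.sum()
        assert part.ring_areas.min() >= 0

    def test_star_cell_matches_exhaustive_distance_oracle(self):
        rec = star_record()
        part = mr.ring_partition(rec, 5)
        oracle = brute_force_rings(rec.nucleus_mask, rec.cytoplasm_mask, 5)
        assert np.array_equal(part.ring_raster, oracle)

    def test_empty_cytoplasm_is_an_error(self):
        mask = np.zeros((8, 8), dtype=bool)
        nuc = mask.copy()
        nuc[3:5, 3:5] = True
        rec = make_record(nuc, nuc)  # cell == nucleus -> empty cytoplasm
        with pytest.raises(ValueError, match="empty cytoplasm"):
            mr.ring_partition(rec, 5)


class TestRadialFractions:
    def test_point_mass_in_ring_one(self, config):
        rec = disc_record()
        part = mr.ring_partition(rec, 5)
        mito = np.zeros(rec.cell_mask.shape)
        mito[part.ring_raster == 1] = 7.0
        prof = mr.radial_fractions(mito, part)
        assert prof.fractions == pytest.approx([1, 0, 0, 0, 0], abs=1e-12)
        peri, periph = mr.perinuclear_peripheral(prof, config)
        assert peri == pytest.approx(1.0)
        assert periph == pytest.approx(0.0)

    def test_uniform_intensity_gives_area_fractions(self):
        rec = star_record()
        part = mr.ring_partition(rec, 5)
        mito = np.full(rec.cell_mask.shape, 3.25)
        prof = mr.radial_fractions(mito, part)
        expected = part.ring_areas / part.ring_areas.sum()
        assert np.max(np.abs(prof.fractions - expected)) < 1e-9

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(31)
        rec = star_record()
        part = mr.ring_partition(rec, 5)
        mito = rng.random(rec.cell_mask.shape) * 100
        prof = mr.radial_fractions(mito, part)
        sums = np.zeros(5)
        for (r, c), ring in np.ndenumerate(part.ring_raster):
            if ring > 0:
                sums[ring - 1] += mito[r, c]
        assert np.max(np.abs(prof.fractions - sums / sums.sum())) < 1e-9
        assert prof.total_fluorescence == pytest.approx(sums.sum(), rel=1e-12)

    def test_zero_fluorescence_flags_cell(self):
        rec = disc_record()
        part = mr.ring_partition(rec, 5)
        prof = mr.radial_fractions(np.zeros(rec.cell_mask.shape), part)
        assert not prof.valid
        with pytest.raises(ValueError, match="zero total fluorescence"):
            mr.perinuclear_peripheral(prof)

    def test_shape_mismatch_fails(self):
        rec = disc_record()
        part = mr.ring_partition(rec, 5)
        with pytest.raises(ValueError, match="does not match"):
            mr.radial_fractions(np.zeros((4, 4)), part)


class TestPerinuclearPeripheral:
    def test_arithmetic_example(self, config):
        prof = mr.RadialProfile(fractions=np.array([0.3, 0.3, 0.2, 0.1, 0.1]), total_fluorescence=1)
        peri, periph = mr.perinuclear_peripheral(prof, config)
        assert (peri, periph) == (pytest.approx(0.6), pytest.approx(0.2))

    def test_flat_profile(self, config):
        prof = mr.RadialProfile(fractions=np.full(5, 0.2), total_fluorescence=1)
        peri, periph = mr.perinuclear_peripheral(prof, config)
        assert (peri, periph) == (pytest.approx(0.4), pytest.approx(0.4))

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_with_middle_ring(self, seed, config):
        rng = np.random.default_rng(seed)
        f = rng.random(5)
        f /= f.sum()
        prof = mr.RadialProfile(fractions=f, total_fluorescence=1)
        peri, periph = mr.perinuclear_peripheral(prof, config)
        assert peri + f[2] + periph == pytest.approx(1.0, abs=1e-12)


def test_scale_equivariance_of_fractions():
    """Doubling the whole cell geometry changes the fractions by < 2%.

    Per-cell normalization of the ring widths is exactly what makes the
    profile comparable across cell sizes.
    """
    small = disc_record(r_nuc=15, r_cell=45, pad=5)
    large = disc_record(r_nuc=30, r_cell=90, pad=10)
    f_small = mr.radial_fractions(
        np.ones(small.cell_mask.shape), mr.ring_partition(small, 5)
    ).fractions
    f_large = mr.radial_fractions(
        np.ones(large.cell_mask.shape), mr.ring_partition(large, 5)
    ).fractions
    assert np.max(np.abs(f_small - f_large)) < 0.02


def test_scaled_puncta_field_preserves_measured_fractions(config):
    """2x-scaled cell with 2x-scaled puncta placement: peri fraction within 2%."""
    rng = np.random.default_rng(77)
    small = disc_record(r_nuc=14, r_cell=44, pad=6)
    rows, cols = np.nonzero(small.cytoplasm_mask)
    idx = rng.choice(len(rows), size=300)
    mito_small = np.zeros(small.cell_mask.shape)
    mito_small[rows[idx], cols[idx]] += 1.0
    large = disc_record(r_nuc=28, r_cell=88, pad=12)
    mito_large = np.zeros(large.cell_mask.shape)
    np.add.at(mito_large, (rows[idx] * 2, cols[idx] * 2), 1.0)
    p_small = mr.profile_cell(small, mito_small, config)[1].perinuclear_fraction
    p_large = mr.profile_cell(large, mito_large, config)[1].perinuclear_fraction
    assert abs(p_small - p_large) < 0.02


def test_mean_perinuclear_fraction_is_strictly_monotone_in_bias(beta_sweep):
    means = [np.mean([c["perinuclear"] for c in cells]) for _, cells in sorted(beta_sweep.items())]
    assert all(a < b for a, b in zip(means, means[1:]))
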