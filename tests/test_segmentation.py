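"""Nucleus/cell segmentation: size gate, watershed partition, border rules."""

import numpy as np
import pytest

import mitoradial as mr
from mitoradial.segmentation import LabeledObjects, _collect
from mitoradial.simulate import SimSpec, generate_field, six_cell_border_field


def disc_field(diameter, shape=(512, 512), level=800.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    r = diameter / 2.0
    nuc = (yy - shape[0] / 2) ** 2 + (xx - shape[1] / 2) ** 2 <= r * r
    ch = {
        "nuclei": nuc * level,
        "cell": nuc * 0.0 + 10.0 * nuc,  # only used when cells are sought
        "mitochondria": np.zeros(shape),
    }
    return mr.FluorescenceField("disc", ch, *shape, 16), nuc


class TestIdentifyNuclei:
    def test_small_disc_rejected_by_gate(self, config):
        field, _ = disc_field(40)
        assert mr.identify_nuclei(field, config).n_objects == 0

    def test_in_gate_disc_retained_with_diameter(self, config):
        field, _ = disc_field(100)
        nuclei = mr.identify_nuclei(field, config)
        assert nuclei.n_objects == 1
        assert nuclei.objects[0].equivalent_diameter == pytest.approx(100, rel=0.02)

    def test_constant_channel_yields_empty_set(self, config):
        ch = {r: np.zeros((64, 64)) for r in ("nuclei", "cell", "mitochondria")}
        field = mr.FluorescenceField("blank", ch, 64, 64, 8)
        assert mr.identify_nuclei(field, config).n_objects == 0

    def test_generated_field_recovers_count_and_centroids(self, config):
        spec = SimSpec(seed=5, poisson_noise=False, read_noise_sd=0.0, background=0.0)
        field, truth = generate_field(spec)
        nuclei = mr.identify_nuclei(field, config)
        assert nuclei.n_objects == truth.n_cells
        found = sorted(o.centroid for o in nuclei.objects)
        expected = sorted(c.centroid for c in truth.cells)
        for (fr, fc), (tr, tc) in zip(found, expected):
            assert np.hypot(fr - tr, fc - tc) < 2.0

    def test_labels_consecutive_from_one(self, config):
        spec = SimSpec(seed=8, poisson_noise=False, read_noise_sd=0.0, background=0.0)
        field, _ = generate_field(spec)
        nuclei = mr.identify_nuclei(field, config)
        labels = sorted(o.label for o in nuclei.objects)
        assert labels == list(range(1, nuclei.n_objects + 1))
        assert set(np.unique(nuclei.label_raster)) == {0, *labels}


def two_cell_blob_field(h=128, w=232, r_cell=60, r_nuc=26):
    """Two nuclei inside one connected tubulin blob (mirror-symmetric)."""
    yy, xx = np.mgrid[:h, :w]
    c1, c2 = (64, 64), (64, 168)
    d1 = (yy - c1[0]) ** 2 + (xx - c1[1]) ** 2
    d2 = (yy - c2[0]) ** 2 + (xx - c2[1]) ** 2
    blob = (d1 <= r_cell**2) | (d2 <= r_cell**2)
    nucmask = (d1 <= r_nuc**2) | (d2 <= r_nuc**2)
    field = mr.FluorescenceField(
        "blob",
        {
            "nuclei": nucmask * 800.0,
            "cell": blob * 400.0,
            "mitochondria": blob * 10.0,
        },
        h,
        w,
        16,
    )
    return field, blob, (c1, c2)


class TestIdentifyCells:
    def test_single_nucleus_in_tubulin_disc(self, config):
        h = w = 256
        yy, xx = np.mgrid[:h, :w]
        cell = (yy - 128) ** 2 + (xx - 128) ** 2 <= 80**2
        nuc = (yy - 128) ** 2 + (xx - 128) ** 2 <= 30**2
        field = mr.FluorescenceField(
            "one",
            {"nuclei": nuc * 800.0, "cell": cell * 400.0, "mitochondria": cell * 1.0},
            h,
            w,
            16,
        )
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        assert cells.n_objects == 1
        assert not (nuclei.mask(1) & ~cells.mask(1)).any()  # cell ⊇ nucleus

    def test_two_nuclei_partition_blob_along_midline(self, config):
        field, blob, (c1, c2) = two_cell_blob_field()
        nuclei = mr.identify_nuclei(field, config)
        assert nuclei.n_objects == 2
        cells = mr.identify_cells(field, nuclei)
        lab = cells.label_raster
        # the two cells partition the blob
        assert np.array_equal(lab > 0, blob)
        # partition boundary within ±2 px of the symmetric midline
        midline = (c1[1] + c2[1]) / 2.0
        for row in range(lab.shape[0]):
            left = np.nonzero(lab[row] == lab[c1])[0]
            right = np.nonzero(lab[row] == lab[c2])[0]
            if len(left) and len(right):
                boundary = (left.max() + right.min()) / 2.0
                assert abs(boundary - midline) <= 2.0

    def test_partition_matches_nearest_seed_oracle(self, config):
        field, blob, _ = two_cell_blob_field()
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        # brute-force nearest-nucleus assignment over the blob
        rows, cols = np.nonzero(blob)
        dists = []
        for lbl in (1, 2):
            ny, nx = np.nonzero(nuclei.mask(lbl))
            d2 = (rows[:, None] - ny[None, :]) ** 2 + (cols[:, None] - nx[None, :]) ** 2
            dists.append(d2.min(axis=1))
        oracle = np.where(dists[0] <= dists[1], 1, 2)
        got = cells.label_raster[rows, cols]
        ties = np.abs(np.sqrt(dists[0]) - np.sqrt(dists[1])) <= 2.0
        assert np.array_equal(got[~ties], oracle[~ties])

    def test_foreground_blob_without_nucleus_is_not_a_cell(self, config):
        field, blob, _ = two_cell_blob_field()
        # add a detached tubulin blob with no nucleus
        extra = np.zeros_like(blob)
        extra[0:14, 210:231] = True  # clear of both discs (min gap ~6 px)
        assert not (extra & blob).any()
        field.channels["cell"] = field.channels["cell"] + extra * 400.0
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        assert cells.n_objects == 2
        assert not (cells.label_raster[extra] > 0).any()

    def test_no_nuclei_is_an_error(self, config):
        ch = {r: np.zeros((32, 32)) for r in ("nuclei", "cell", "mitochondria")}
        field = mr.FluorescenceField("none", ch, 32, 32, 8)
        with pytest.raises(ValueError, match="no retained nuclei"):
            mr.identify_cells(field, LabeledObjects(np.zeros((32, 32), dtype=np.int32)))


class TestExcludeBorder:
    def _objects(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        lab[0:5, 10:15] = 1  # touches top border
        lab[10:14, 10:14] = 2
        lab[20:24, 20:24] = 3
        lab[30:34, 5:9] = 4
        lab[36:40, 30:34] = 5  # touches bottom border
        return _collect(lab)

    def test_border_touching_objects_removed(self):
        kept = mr.exclude_border(self._objects())
        assert kept.n_objects == 3
        assert sorted(o.label for o in kept.objects) == [1, 2, 3]

    def test_single_corner_pixel_is_enough(self):
        lab = np.zeros((10, 10), dtype=np.int32)
        lab[0, 0] = 1
        lab[4:6, 4:6] = 2
        kept = mr.exclude_border(_collect(lab))
        assert kept.n_objects == 1
        assert kept.objects[0].area == 4

    def test_no_border_objects_is_identity_up_to_relabel(self):
        lab = np.zeros((12, 12), dtype=np.int32)
        lab[2:4, 2:4] = 3
        lab[7:9, 7:9] = 8
        kept = mr.exclude_border(_collect(lab))
        assert kept.n_objects == 2
        assert np.array_equal(kept.label_raster > 0, lab > 0)


class TestBuildCellRecords:
    def test_cytoplasm_is_exact_set_difference(self, config):
        h = w = 160
        yy, xx = np.mgrid[:h, :w]
        cell = (yy - 80) ** 2 + (xx - 80) ** 2 <= 60**2
        nuc = (yy - 80) ** 2 + (xx - 80) ** 2 <= 28**2
        field = mr.FluorescenceField(
            "c",
            {"nuclei": nuc * 800.0, "cell": cell * 400.0, "mitochondria": cell * 1.0},
            h,
            w,
            16,
        )
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        (rec,) = mr.build_cell_records(field, nuclei, cells, config)
        assert rec.cytoplasm_mask.sum() == rec.cell_mask.sum() - rec.nucleus_mask.sum()
        assert not (rec.cytoplasm_mask & rec.nucleus_mask).any()
        assert np.array_equal(rec.cytoplasm_mask | rec.nucleus_mask, rec.cell_mask)

    def test_six_cell_field_drops_the_two_border_cells(self, config):
        field, truth = six_cell_border_field()
        assert sum(c.touches_border for c in truth.cells) == 2
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        records = mr.build_cell_records(field, nuclei, cells, config)
        assert len(records) == 4

    def test_cell_masks_pairwise_disjoint(self, config):
        field, _ = generate_field(
            SimSpec(seed=17, poisson_noise=False, read_noise_sd=0.0, background=0.0)
        )
        nuclei = mr.identify_nuclei(field, config)
        cells = mr.identify_cells(field, nuclei)
        records = mr.build_cell_records(field, nuclei, cells, config)
        total = np.zeros(field.channels["cell"].shape, dtype=int)
        for rec in records:
            total += rec.cell_mask
        assert total.max() <= 1


def test_noise_free_segmentation_matches_truth_with_high_jaccard(config):
    field, truth = generate_field(
        SimSpec(seed=23, poisson_noise=False, read_noise_sd=0.0, background=0.0)
    )
    nuclei = mr.identify_nuclei(field, config)
    cells = mr.identify_cells(field, nuclei)
    records = mr.build_cell_records(field, nuclei, cells, config)
    assert len(records) == truth.n_cells
    # match each truth cell to the record with the same nucleus position
    for ct in truth.cells:
        best = max(
            records,
            key=lambda r: (r.cell_mask & ct.cell_mask).sum(),
        )
        inter = (best.cell_mask & ct.cell_mask).sum()
        union = (best.cell_mask | ct.cell_mask).sum()
        assert inter / union >= 0.9
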