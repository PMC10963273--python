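"""Ratio-based voxel detection and the 1-8 voxel cell-cluster rule."""

import numpy as np
import pytest

import fosmap as fm
from fosmap.detection import _round_half_down

from conftest import brute_force_components, brute_force_detect


class TestDetectFosVoxels:
    def test_constant_volume_yields_nothing(self):
        mask = fm.detect_fos_voxels(fm.Volume3D(np.full((6, 6, 6), 50.0)))
        assert mask.n_flagged == 0

    def test_zero_background_is_not_vacuously_flagged(self):
        mask = fm.detect_fos_voxels(fm.Volume3D(np.zeros((6, 6, 6))))
        assert mask.n_flagged == 0

    def test_center_peak_at_exact_threshold_detected(self, flat_volume):
        # 125 = 1.25 x 100 clears the 20% requirement; brute-force agrees
        mask = fm.detect_fos_voxels(flat_volume)
        expected = brute_force_detect(flat_volume.data, np.ones((5, 5, 5), bool))
        np.testing.assert_array_equal(mask.data, expected)
        assert mask.n_flagged == 1 and mask.data[2, 2, 2]

    def test_exact_20_percent_excess_counts_sub_threshold_does_not(self):
        data = np.full((5, 5, 5), 100.0)
        data[2, 2, 2] = 120.0
        assert fm.detect_fos_voxels(fm.Volume3D(data)).data[2, 2, 2]
        data[2, 2, 2] = np.nextafter(120.0, 0.0)
        assert not fm.detect_fos_voxels(fm.Volume3D(data)).data[2, 2, 2]

    def test_masked_neighbor_vetoes_detection(self):
        data = np.full((5, 5, 5), 100.0)
        data[2, 2, 2] = 1e6
        tissue = np.ones((5, 5, 5), bool)
        tissue[1, 1, 1] = False  # one of the 26 neighbors is outside tissue
        mask = fm.detect_fos_voxels(fm.Volume3D(data), fm.TissueMask(tissue))
        assert not mask.data[2, 2, 2]
        assert mask.n_flagged == 0

    def test_edge_voxels_never_flagged(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(1, 100, size=(6, 6, 6))
        flagged = np.argwhere(fm.detect_fos_voxels(fm.Volume3D(data)).data)
        if flagged.size:
            assert flagged.min() >= 1 and (flagged.max(axis=0) <= 4).all()

    def test_scale_invariance_and_offset_counterexample(self, flat_volume):
        base = fm.detect_fos_voxels(flat_volume).data
        scaled = fm.detect_fos_voxels(fm.Volume3D(flat_volume.data * 37.5))
        np.testing.assert_array_equal(scaled.data, base)
        # additive offset dilutes the ratio: 125+500 vs 100+500 is < 20%
        shifted = fm.detect_fos_voxels(fm.Volume3D(flat_volume.data + 500.0))
        assert base.sum() == 1 and shifted.data.sum() == 0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        data = np.full((10, 10, 10), 100.0)
        for z, y, x in [(3, 3, 3), (6, 5, 4)]:
            data[z, y, x] = 130.0
        base = fm.detect_fos_voxels(fm.Volume3D(data)).data
        shifted_vol = np.roll(data, shift=(1, 2, 1), axis=(0, 1, 2))
        shifted = fm.detect_fos_voxels(fm.Volume3D(shifted_vol)).data
        np.testing.assert_array_equal(np.roll(base, shift=(1, 2, 1), axis=(0, 1, 2)), shifted)

    def test_shape_mismatch_rejected(self, flat_volume):
        with pytest.raises(fm.DomainError):
            fm.detect_fos_voxels(flat_volume, fm.TissueMask(np.ones((6, 6, 6), bool)))

    @pytest.mark.parametrize("mode", ["each-neighbor", "mean-of-neighbors"])
    def test_oracle_equivalence_on_random_volumes(self, mode):
        """Optimized detector equals the literal triple-loop implementation."""
        rng = np.random.default_rng(42)
        for _ in range(12):
            shape = tuple(rng.integers(3, 13, size=3))
            data = rng.uniform(1, 100, size=shape)
            tissue = rng.random(shape) > 0.1
            params = fm.DetectionParams(comparison_mode=mode)
            got = fm.detect_fos_voxels(
                fm.Volume3D(data), fm.TissueMask(tissue), params
            ).data
            expected = brute_force_detect(data, tissue, mode=mode)
            np.testing.assert_array_equal(got, expected)


class TestFindCells:
    @staticmethod
    def _mask_from_voxels(shape, voxels):
        m = np.zeros(shape, bool)
        for v in voxels:
            m[v] = True
        return fm.DetectionMask(m)

    def test_single_voxel_is_one_cell(self):
        cells = fm.find_cells(self._mask_from_voxels((5, 5, 5), [(2, 2, 2)]))
        assert len(cells) == 1 and cells.cells[0].size == 1
        assert cells.cells[0].centroid == (2.0, 2.0, 2.0)

    def test_nine_voxel_component_is_an_artefact(self):
        voxels = [(2, 2, x) for x in range(9)]
        cells = fm.find_cells(self._mask_from_voxels((5, 5, 12), voxels))
        assert len(cells) == 0
        assert len(cells.artefacts) == 1 and cells.artefacts[0].size == 9

    def test_eight_voxel_component_still_counts(self):
        voxels = [(2, 2, x) for x in range(8)]
        cells = fm.find_cells(self._mask_from_voxels((5, 5, 12), voxels))
        assert len(cells) == 1 and cells.cells[0].size == 8

    def test_twelve_isolated_voxels_are_twelve_cells(self):
        m = np.zeros((12, 12, 12), bool)
        lattice = [(1 + 3 * a, 1 + 3 * b, 1 + 3 * c)
                   for a in range(3) for b in range(3) for c in range(3)][:12]
        for v in lattice:
            m[v] = True
        cells = fm.find_cells(fm.DetectionMask(m))
        assert len(cells) == 12 and all(c.size == 1 for c in cells.cells)

    def test_connectivity_changes_component_structure(self):
        # two diagonal voxels: one component under 26, two under 6
        m = self._mask_from_voxels((5, 5, 5), [(2, 2, 2), (3, 3, 3)])
        assert len(fm.find_cells(m, fm.DetectionParams(connectivity=26))) == 1
        assert len(fm.find_cells(m, fm.DetectionParams(connectivity=6))) == 2

    def test_partition_invariant_cells_plus_artefacts(self):
        rng = np.random.default_rng(5)
        m = fm.DetectionMask(rng.random((10, 10, 10)) > 0.7)
        cells = fm.find_cells(m)
        expected = brute_force_components(m.data, connectivity=26)
        assert len(cells.cells) + len(cells.artefacts) == len(expected)
        got = {frozenset(c.voxels) for c in cells.cells + cells.artefacts}
        assert got == set(expected)
        assert all(1 <= c.size <= 8 for c in cells.cells)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_component_oracle_equivalence(self, connectivity):
        rng = np.random.default_rng(connectivity)
        for _ in range(5):
            shape = tuple(rng.integers(3, 13, size=3))
            m = fm.DetectionMask(rng.random(shape) > 0.6)
            params = fm.DetectionParams(connectivity=connectivity)
            cells = fm.find_cells(m, params)
            expected = set(brute_force_components(m.data, connectivity))
            got = {frozenset(c.voxels) for c in cells.cells + cells.artefacts}
            assert got == expected


class TestCellsToCounts:
    def test_empty_cellset_gives_zero_counts(self):
        counts = fm.cells_to_counts(fm.CellSet(cells=()), (4, 4, 4), (25, 25, 25))
        assert counts.total == 0

    def test_tie_centroid_rounds_toward_lower_index(self):
        cell = fm.Cell(voxels=((2, 2, 2), (2, 2, 3)), centroid=(2.0, 2.0, 2.5))
        counts = fm.cells_to_counts(fm.CellSet(cells=(cell,)), (5, 5, 5), (25, 25, 25))
        assert counts.data[2, 2, 2] == 1 and counts.total == 1

    def test_half_down_rounding_rule(self):
        assert _round_half_down(2.5) == 2
        assert _round_half_down(2.51) == 3
        assert _round_half_down(2.49) == 2

    def test_total_count_preserved(self):
        rng = np.random.default_rng(2)
        cells = tuple(
            fm.Cell(voxels=((z, y, x),), centroid=(float(z), float(y), float(x)))
            for z, y, x in rng.integers(0, 6, size=(20, 3))
        )
        counts = fm.cells_to_counts(fm.CellSet(cells=cells), (6, 6, 6), (25, 25, 25))
        assert counts.total == 20

    def test_centroid_outside_shape_rejected(self):
        cell = fm.Cell(voxels=((4, 4, 4),), centroid=(4.0, 4.0, 4.0))
        with pytest.raises(fm.DomainError):
            fm.cells_to_counts(fm.CellSet(cells=(cell,)), (4, 4, 4), (25, 25, 25))
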