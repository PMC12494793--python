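"""Structure/volume I/O, rasterization, morphology and pseudoatom conversion."""

import numpy as np
import pytest
from scipy import ndimage

from cryocrowd import structio as sio


def gaussian_sum_oracle(coords, weights, volume, sigma_voxels):
    """Direct evaluation of the per-atom Gaussian sum on the volume's grid."""
    nz, ny, nx = volume.grid.shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    centers = np.stack([xx, yy, zz], axis=-1) + 0.5  # voxel centers, voxel units
    out = np.zeros_like(volume.grid)
    norm = (2 * np.pi) ** 1.5 * sigma_voxels**3
    for w, c in zip(weights, coords):
        u = (c - volume.origin) / volume.voxel_size  # x, y, z in voxel units
        d2 = ((centers - u) ** 2).sum(axis=-1)
        out += w / norm * np.exp(-d2 / (2 * sigma_voxels**2))
    return out


class TestPdbIO:
    def test_roundtrip_with_dens_records(self, tmp_path):
        coords = np.array([[1.234, -2.5, 0.008], [10.0, 4.5, 3.25],
                           [7.125, 0.0, -9.875]])
        model = sio.AtomicModel(
            element=np.array(["C", "P", ""]),
            atomic_number=np.array([6, 15, 0]),
            name=np.array(["CA", "P", "DENS"]),
            res_id=np.array([1, 2, 3]),
            chain=np.array(["A", "B", "A"]),
            coords=coords,
            is_pseudo=np.array([False, False, True]),
        )
        path = tmp_path / "m.pdb"
        sio.write_pdb(model, path)
        back = sio.read_structure(path)
        assert len(back) == 3
        np.testing.assert_allclose(back.coords, coords, atol=1e-3)
        assert list(back.is_pseudo) == [False, False, True]
        assert list(back.atomic_number) == [6, 15, 0]
        assert list(back.chain) == ["A", "B", "A"]

    def test_pure_dens_file(self, tmp_path):
        path = tmp_path / "dens.pdb"
        lines = [
            f"DENS  {i + 1:5d} DENS MOL A{i + 1:4d}    "
            f"{1.0 + 3 * i:8.3f}{2.0 + 3 * i:8.3f}{3.0 + 3 * i:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}\n"
            for i in range(2)
        ]
        path.write_text("".join(lines))
        model = sio.read_structure(path)
        assert len(model) == 2
        assert model.is_pseudo.all()

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sio.read_structure(tmp_path / "nope.pdb")
        empty = tmp_path / "empty.pdb"
        empty.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(ValueError, match="no atoms"):
            sio.read_structure(empty)


class TestRasterize:
    def test_single_atom_peak_at_atom_voxel(self):
        m = sio.model_from_points([[32.0, 48.0, 16.0]], element="C")
        vol = sio.rasterize(m, 16.0)
        peak = np.unravel_index(np.argmax(vol.grid), vol.grid.shape)
        expect = np.floor((m.coords[0][::-1] - vol.origin[::-1]) / 16.0).astype(int)
        assert tuple(peak) == tuple(expect)

    def test_two_atoms_give_two_maxima_matching_direct_sum(self):
        m = sio.model_from_points([[0.0, 0.0, 0.0], [160.0, 0.0, 0.0]],
                                  element="C")
        vol = sio.rasterize(m, 16.0, sigma_voxels=1.0)
        oracle = gaussian_sum_oracle(m.coords, m.weights, vol, 1.0)
        # the implementation truncates each atom's kernel at 4 sigma
        np.testing.assert_allclose(vol.grid, oracle,
                                   atol=2e-4 * m.weights.max())
        labeled, n = ndimage.label(vol.grid > 0.9 * vol.grid.max())
        assert n == 2

    def test_total_density_proportional_to_atomic_numbers(self):
        m = sio.AtomicModel(
            element=np.array(["C", "N", "O"]),
            atomic_number=np.array([6, 7, 8]),
            name=np.array(["C", "N", "O"]),
            res_id=np.array([1, 2, 3]),
            chain=np.array(["A"] * 3),
            coords=np.array([[0.0, 0, 0], [30.0, 0, 0], [0.0, 30, 0]]),
            is_pseudo=np.zeros(3, bool),
        )
        vol = sio.rasterize(m, 10.0, sigma_voxels=1.0)
        assert vol.grid.sum() == pytest.approx(6 + 7 + 8, rel=1e-3)

    def test_mass_linearity_against_direct_sum(self, rng):
        coords = rng.uniform(0, 50, (5, 3))
        m = sio.model_from_points(coords, element="C")
        vol = sio.rasterize(m, 10.0, sigma_voxels=1.0)
        oracle = gaussian_sum_oracle(coords, m.weights, vol, 1.0)
        # rtol checks the bulk; atol absorbs the 4-sigma kernel truncation
        np.testing.assert_allclose(vol.grid, oracle, rtol=1e-6,
                                   atol=2e-4 * m.weights.max())

    def test_parameter_errors(self):
        m = sio.model_from_points([[0.0, 0, 0]], element="C")
        with pytest.raises(ValueError):
            sio.rasterize(m, -1.0)


class TestBinarize:
    def test_zero_and_constant_volumes(self):
        zeros = sio.DensityVolume(grid=np.zeros((6, 6, 6)), voxel_size=1.0)
        assert sio.binarize(zeros, threshold=5.0).count == 0
        const = sio.DensityVolume(grid=np.full((6, 6, 6), 10.0), voxel_size=1.0)
        assert sio.binarize(const, threshold=5.0).count == 6**3

    def test_impulse_matches_discrete_gaussian_kernel(self):
        v = 5000.0
        grid = np.zeros((17, 17, 17))
        grid[8, 8, 8] = v
        vol = sio.DensityVolume(grid=grid, voxel_size=1.0)
        mask = sio.binarize(vol, sigma=2.0, threshold=10.0)
        # ndimage's kernel: normalized samples of exp(-x^2/2s^2), truncate 4s
        x = np.arange(-8, 9)
        k1 = np.exp(-x**2 / 8.0)
        k1 /= k1.sum()
        expected = v * k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        np.testing.assert_array_equal(mask.grid, expected > 10.0)


class TestDilate:
    def test_single_voxel_radius_one_is_cross(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 2, 2] = True
        out = sio.dilate(sio.BinaryMask(grid=grid, voxel_size=1.0), 1)
        assert out.count == 7
        assert out.grid[2, 2, 2] and out.grid[1, 2, 2] and out.grid[2, 2, 3]

    def test_radius_zero_is_identity(self, rng):
        grid = rng.random((6, 6, 6)) > 0.7
        mask = sio.BinaryMask(grid=grid, voxel_size=1.0)
        np.testing.assert_array_equal(sio.dilate(mask, 0).grid, grid)

    def test_matches_brute_force_union_of_balls(self, rng):
        grid = rng.random((8, 8, 8)) > 0.8
        out = sio.dilate(sio.BinaryMask(grid=grid, voxel_size=1.0), 2)
        brute = np.zeros_like(grid)
        offs = [(dz, dy, dx) for dz in range(-2, 3) for dy in range(-2, 3)
                for dx in range(-2, 3) if dz*dz + dy*dy + dx*dx <= 4]
        for z, y, x in np.argwhere(grid):
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= c < 8 for c in p):
                    brute[p] = True
        np.testing.assert_array_equal(out.grid, brute)

    def test_negative_radius_rejected(self):
        mask = sio.BinaryMask(grid=np.ones((3, 3, 3), bool), voxel_size=1.0)
        with pytest.raises(ValueError):
            sio.dilate(mask, -1)

    def test_translation_equivariance_of_binarize_dilate(self, rng):
        grid = np.zeros((16, 16, 16))
        grid[4:8, 4:8, 4:8] = rng.random((4, 4, 4)) * 100
        vol = sio.DensityVolume(grid=grid, voxel_size=1.0)
        shifted = sio.DensityVolume(grid=np.roll(grid, (3, 2, 1), (0, 1, 2)),
                                    voxel_size=1.0)
        out = sio.dilate(sio.binarize(vol, 1.0, 5.0), 1).grid
        out_s = sio.dilate(sio.binarize(shifted, 1.0, 5.0), 1).grid
        np.testing.assert_array_equal(np.roll(out, (3, 2, 1), (0, 1, 2)), out_s)


class TestPseudoatoms:
    def _cube_volume(self):
        grid = np.zeros((7, 7, 7))
        grid[2:5, 2:5, 2:5] = 1.0
        return sio.DensityVolume(grid=grid, voxel_size=4.0)

    def test_27_voxels_ratio_one_third_gives_9_phosphorus(self):
        model = sio.volume_to_pseudoatoms(self._cube_volume(), sigma=0.0,
                                          threshold=0.5, relative=False,
                                          phosphorus_ratio=1 / 3)
        assert len(model) == 27
        assert (model.element == "P").sum() == 9
        assert (~model.is_pseudo).sum() == 9

    def test_ratio_zero_all_pseudo_and_bad_ratio_rejected(self):
        model = sio.volume_to_pseudoatoms(self._cube_volume(), sigma=0.0,
                                          threshold=0.5, relative=False,
                                          phosphorus_ratio=0.0)
        assert model.is_pseudo.all()
        with pytest.raises(ValueError):
            sio.volume_to_pseudoatoms(self._cube_volume(), phosphorus_ratio=1.5)

    def test_atom_count_equals_nonzero_voxels_random_blobs(self, rng):
        for _ in range(20):
            grid = ndimage.gaussian_filter(rng.random((10, 10, 10)), 1.5)
            vol = sio.DensityVolume(grid=grid * 100, voxel_size=2.0)
            mask = sio.binarize(vol, sigma=1.0, threshold=0.5, relative=True)
            if mask.count == 0:
                continue
            model = sio.volume_to_pseudoatoms(vol, sigma=1.0, threshold=0.5,
                                              relative=True, phosphorus_ratio=0.3)
            assert len(model) == mask.count

    def test_roundtrip_occupancy_overlap(self, ball_blob_model):
        vol = sio.rasterize(ball_blob_model, 8.0, sigma_voxels=1.0)
        mask1 = sio.binarize(vol, 2.0, 0.1, relative=True)
        pa = sio.volume_to_pseudoatoms(vol, sigma=2.0, threshold=0.1,
                                       relative=True, phosphorus_ratio=0.0)
        vol2 = sio.rasterize(pa, 8.0, sigma_voxels=0.5)
        mask2 = sio.binarize(vol2, 0.0, 0.3, relative=True)

        def centers(mask):
            idx = np.argwhere(mask.grid)
            return set(map(tuple, np.round(
                mask.voxel_centers_angstrom(idx) / 8.0).astype(int)))

        c1, c2 = centers(mask1), centers(mask2)
        assert len(c1 & c2) / len(c1 | c2) >= 0.9


class TestContrast:
    def test_single_candidate_returned(self, ball_blob_model):
        vol = sio.rasterize(ball_blob_model, 8.0)
        assert sio.tune_contrast_ratio(vol, 1.0, [0.25]) == 0.25

    def test_contrast_monotone_in_phosphorus_ratio(self, ball_blob_model):
        vol = sio.rasterize(ball_blob_model, 8.0)
        ratios = [0.0, 0.25, 1 / 3, 0.5, 1.0]
        contrasts = [
            sio.projection_contrast(
                sio.volume_to_pseudoatoms(vol, sigma=2.0, threshold=0.1,
                                          relative=True, phosphorus_ratio=r),
                8.0)
            for r in ratios
        ]
        assert all(b >= a for a, b in zip(contrasts, contrasts[1:]))

    def test_self_consistent_target_recovers_ratio(self, ball_blob_model):
        vol = sio.rasterize(ball_blob_model, 8.0)
        target = sio.projection_contrast(
            sio.volume_to_pseudoatoms(vol, sigma=2.0, threshold=0.1,
                                      relative=True, phosphorus_ratio=1 / 3),
            8.0)
        got = sio.tune_contrast_ratio(vol, target, [0.0, 0.25, 1 / 3, 0.5, 1.0])
        assert got == 1 / 3


class TestBinning:
    def test_factor_one_identity_and_ones(self, rng):
        vol = sio.DensityVolume(grid=rng.random((4, 4, 4)), voxel_size=2.0)
        np.testing.assert_array_equal(sio.bin_volume(vol, 1).grid, vol.grid)
        ones = sio.DensityVolume(grid=np.ones((4, 4, 4)), voxel_size=2.0)
        out = sio.bin_volume(ones, 2)
        assert out.grid.shape == (2, 2, 2)
        np.testing.assert_allclose(out.grid, 1.0)
        assert out.voxel_size == 4.0

    def test_block_mean_oracle(self, rng):
        grid = rng.random((8, 8, 8))
        out = sio.bin_volume(sio.DensityVolume(grid=grid, voxel_size=1.0), 2)
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    blk = grid[2*z:2*z+2, 2*y:2*y+2, 2*x:2*x+2]
                    assert out.grid[z, y, x] == pytest.approx(blk.mean())

    def test_bad_factor(self):
        vol = sio.DensityVolume(grid=np.ones((4, 4, 4)), voxel_size=1.0)
        with pytest.raises(ValueError):
            sio.bin_volume(vol, 0)


class TestMrc:
    def test_roundtrip_values_voxel_size_origin(self, tmp_path, rng):
        grid = rng.standard_normal((16, 16, 16)).astype(np.float32)
        vol = sio.DensityVolume(grid=grid, voxel_size=16.0,
                                origin=np.array([8.0, -4.0, 2.0]))
        path = tmp_path / "v.mrc"
        sio.write_mrc(vol, path)
        back = sio.read_mrc(path)
        np.testing.assert_array_equal(back.grid, grid)
        assert back.voxel_size == pytest.approx(16.0)
        np.testing.assert_allclose(back.origin, vol.origin)

    def test_axis_order_convention(self, tmp_path):
        grid = np.zeros((4, 5, 6), dtype=np.float32)
        grid[1, 2, 3] = 7.0
        path = tmp_path / "a.mrc"
        sio.write_mrc(sio.DensityVolume(grid=grid, voxel_size=2.0), path)
        back = sio.read_mrc(path)
        assert back.grid.shape == (4, 5, 6)
        assert back.grid[1, 2, 3] == 7.0
        assert back.grid.sum() == 7.0

    def test_bad_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.mrc"
        bad.write_bytes(b"not an mrc file at all" * 10)
        with pytest.raises(ValueError):
            sio.read_mrc(bad)
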