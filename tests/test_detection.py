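import numpy as np
import pytest

from cortibreak import (
    BinaryVolume,
    ContourSolid,
    DetectionParams,
    ValidationError,
    build_cortical_mask,
    detect_interruptions,
    summarize,
)

from .oracles import bf_build_mask, bf_detect

VX = 0.082


def bv(data):
    return BinaryVolume(data=np.asarray(data, bool), voxel_size_mm=VX)


def slab_setup(shape=(30, 21, 21), top=20, thickness=4):
    """Flat cortical slab: solid z<=top, mask the top `thickness` layers."""
    solid = np.zeros(shape, dtype=bool)
    solid[: top + 1] = True
    mask = build_cortical_mask(ContourSolid(solid=bv(solid)),
                               DetectionParams(mask_thickness_voxels=thickness))
    return solid, mask


def carve(bone, zlo, zhi, yc, xc, offsets):
    for dy, dx in offsets:
        bone[zlo:zhi, yc + dy, xc + dx] = False


PLUS = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]


class TestBuildCorticalMask:
    def test_cube_shell_voxel_count(self):
        solid = np.zeros((28, 28, 28), dtype=bool)
        solid[4:24, 4:24, 4:24] = True  # 20^3 cube
        mask = build_cortical_mask(ContourSolid(solid=bv(solid)))
        assert mask.shell.data.sum() == 20**3 - 12**3  # 6272

    def test_empty_solid_raises(self):
        with pytest.raises(ValidationError, match="empty"):
            build_cortical_mask(ContourSolid(solid=bv(np.zeros((5, 5, 5)))))

    def test_thin_ball_shell_is_whole_ball_with_warning(self):
        z, y, x = np.meshgrid(*(np.arange(12),) * 3, indexing="ij", sparse=True)
        ball = (z - 6) ** 2 + (y - 6) ** 2 + (x - 6) ** 2 <= 9
        with pytest.warns(UserWarning, match="endosteal"):
            mask = build_cortical_mask(ContourSolid(solid=bv(ball)))
        np.testing.assert_array_equal(mask.shell.data, ball)
        assert not mask.endosteal_face.data.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        from .conftest import random_solid

        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(20, 48, 3))
        solid = random_solid(rng, shape)
        p = DetectionParams(mask_thickness_voxels=int(rng.integers(2, 6)))
        mask = build_cortical_mask(ContourSolid(solid=bv(solid)), p)
        shell, peri, endo = bf_build_mask(solid, p.mask_thickness_voxels)
        np.testing.assert_array_equal(mask.shell.data, shell)
        np.testing.assert_array_equal(mask.periosteal_face.data, peri)
        np.testing.assert_array_equal(mask.endosteal_face.data, endo)

    def test_faces_subsets_and_disjoint_on_thick_solid(self):
        solid = np.zeros((30, 30, 30), dtype=bool)
        solid[5:25, 5:25, 5:25] = True
        mask = build_cortical_mask(ContourSolid(solid=bv(solid)))
        s = mask.shell.data
        assert mask.periosteal_face.data[~s].sum() == 0
        assert mask.endosteal_face.data[~s].sum() == 0
        assert not (mask.periosteal_face.data & mask.endosteal_face.data).any()


class TestDetectInterruptions:
    def test_minimal_plus_channel_detected_once(self):
        # 5-voxel plus cross-section through the 4-voxel mask: 3 consecutive
        # slices x 3 voxels wide = the smallest detectable interruption
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, PLUS)
        res = detect_interruptions(bv(bone), mask)
        assert res.n_interruptions == 1
        assert res.records[0].voxel_count == 20

    def test_two_voxel_wide_channel_not_detected(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, [(0, 0), (1, 0), (0, 1), (1, 1)])
        res = detect_interruptions(bv(bone), mask)
        assert res.n_interruptions == 0

    def test_blind_periosteal_pit_not_detected(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 19, 21, 10, 10, PLUS)  # 2 voxels deep from the surface
        res = detect_interruptions(bv(bone), mask)
        assert res.n_interruptions == 0

    def test_intracortical_cavity_not_detected(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        # large cavity strictly inside the mask, touching neither face
        bone[18:20, 6:15, 6:15] = False
        res = detect_interruptions(bv(bone), mask)
        assert res.n_interruptions == 0

    def test_two_disjoint_channels_counted_separately(self):
        solid, mask = slab_setup(shape=(30, 31, 21))
        bone = solid.copy()
        carve(bone, 10, 21, 7, 10, PLUS)
        carve(bone, 10, 21, 22, 10, PLUS)
        res = detect_interruptions(bv(bone), mask)
        assert res.n_interruptions == 2
        assert [r.voxel_count for r in res.records] == [20, 20]

    def test_lattice_mismatch_rejected(self):
        _, mask = slab_setup()
        with pytest.raises(ValidationError, match="lattice"):
            detect_interruptions(bv(np.zeros((5, 5, 5))), mask)

    def test_min_component_floor_enforced(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, PLUS)
        res = detect_interruptions(bv(bone), mask,
                                   DetectionParams(min_component_voxels=21))
        assert res.n_interruptions == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle_on_random_configurations(self, seed):
        from .conftest import random_solid

        rng = np.random.default_rng(100 + seed)
        shape = tuple(rng.integers(24, 48, 3))
        solid = random_solid(rng, shape)
        p = DetectionParams()
        mask = build_cortical_mask(ContourSolid(solid=bv(solid)), p)
        # bone = solid with random channels and holes punched through
        bone = solid.copy()
        for _ in range(rng.integers(2, 6)):
            axis = int(rng.integers(3))
            w = int(rng.integers(1, 5))
            pos = [int(rng.integers(2, s - 6)) for s in shape]
            sl = [slice(pos[a], pos[a] + w) for a in range(3)]
            sl[axis] = slice(None)
            bone[tuple(sl)] = False
        bone &= rng.random(shape) > 0.02  # speckle porosity
        res = detect_interruptions(bv(bone), mask, p)
        comps = bf_detect(bone, mask.shell.data, mask.periosteal_face.data,
                          mask.endosteal_face.data, p.dilation_radius_voxels,
                          p.min_component_voxels)
        got = {
            frozenset(map(tuple, np.argwhere(res.label_map.data == r.label)))
            for r in res.records
        }
        assert got == set(comps)

    def test_rotation_and_flip_invariance(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, PLUS)
        base = detect_interruptions(bv(bone), mask)
        for transform in (
            lambda a: a[::-1].copy(),
            lambda a: np.rot90(a, axes=(1, 2)).copy(),
            lambda a: a[:, ::-1].copy(),
        ):
            tb = transform(bone)
            ts = transform(solid)
            tmask = build_cortical_mask(ContourSolid(solid=bv(ts)))
            res = detect_interruptions(bv(tb), tmask)
            assert res.n_interruptions == base.n_interruptions
            assert sorted(r.voxel_count for r in res.records) == sorted(
                r.voxel_count for r in base.records
            )

    def test_adding_bone_never_increases_void(self):
        from .oracles import bf_dilate6

        rng = np.random.default_rng(9)
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, PLUS)
        carve(bone, 10, 21, 10, 4, [(dy, dx) for dy in range(3) for dx in range(3)])
        shell = mask.shell.data

        def void_vol(b):
            return (shell & ~bf_dilate6(b & shell, 1)).sum()

        v0 = void_vol(bone)
        extra = bone | (rng.random(bone.shape) > 0.7)
        assert void_vol(extra) <= v0

    def test_records_sorted_by_descending_size(self):
        solid, mask = slab_setup(shape=(30, 31, 21))
        bone = solid.copy()
        carve(bone, 10, 21, 7, 10, PLUS)
        carve(bone, 10, 21, 22, 10, [(dy, dx) for dy in range(-1, 2) for dx in range(-1, 2)])
        res = detect_interruptions(bv(bone), mask)
        counts = [r.voxel_count for r in res.records]
        assert counts == sorted(counts, reverse=True)
        assert [r.label for r in res.records] == [1, 2]


class TestSummaries:
    def test_single_record_volume_and_surface(self):
        solid, mask = slab_setup()
        bone = solid.copy()
        carve(bone, 10, 21, 10, 10, PLUS)
        res = detect_interruptions(bv(bone), mask)
        df = summarize(res)
        assert df.loc[0, "volume_mm3"] == pytest.approx(20 * 0.082**3)  # 0.011 mm^3
        assert df.loc[0, "surface_mm2"] == pytest.approx(20 * 0.082**3 / 0.328)

    def test_empty_result(self):
        solid, mask = slab_setup()
        res = detect_interruptions(bv(solid), mask)
        df = summarize(res)
        assert len(df) == 0
        assert df.attrs["n_interruptions"] == 0
        assert df.attrs["total_surface_mm2"] == 0.0

    def test_total_surface_additivity(self, fig2_result):
        _, _, _, _, res = fig2_result
        df = summarize(res)
        assert df.attrs["total_surface_mm2"] == pytest.approx(df["surface_mm2"].sum())


def test_generation2_parameter_arithmetic():
    # second-generation scanner: 61 µm voxels, 5-voxel mask
    p = DetectionParams(mask_thickness_voxels=5)
    assert p.mask_thickness_voxels * 0.061 == pytest.approx(0.305)
    assert 3 * 0.061 == pytest.approx(0.183)


def test_params_validation():
    with pytest.raises(ValidationError):
        DetectionParams(mask_thickness_voxels=1)
    with pytest.raises(ValidationError):
        DetectionParams(min_component_voxels=0)
    with pytest.raises(ValueError):
        DetectionParams(void_connectivity="knight")
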