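import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from projdense import (
    AxonPhantomSpec,
    ImageStack,
    ROISpec,
    RegionSummary,
    StackMeasurement,
    binarize_stack,
    generate_axon_stack,
    measure_stack,
    rad_ratio,
    region_rad,
    skeleton_length,
    skeletonize_stack,
    stack_volume,
)
from projdense.axon_quant import BinaryMask, skeleton_graph_from_voxels

from conftest import brute_force_skeleton_length_mm

SPACING = (0.27, 0.2, 0.2)


def _mask(arr):
    return BinaryMask(mask=arr.astype(bool), spacing_um=SPACING, threshold=0.5)


class TestBinarize:
    def test_fixed_threshold_on_binary_stack_is_idempotent(self):
        rng = np.random.default_rng(0)
        arr = (rng.random((8, 16, 16)) < 0.3).astype(np.float32)
        mask = binarize_stack(
            ImageStack(arr, SPACING), method=0.5, min_object_vox=1,
            smooth_sigma_vox=(0, 0, 0),
        )
        np.testing.assert_array_equal(mask.mask, arr.astype(bool))

    def test_otsu_matches_exhaustive_between_class_variance_search(self):
        rng = np.random.default_rng(1)
        img = np.where(
            rng.random((10, 20, 20)) < 0.2,
            rng.normal(100, 5, (10, 20, 20)),
            rng.normal(10, 2, (10, 20, 20)),
        ).astype(np.float32)
        mask = binarize_stack(
            ImageStack(img, SPACING), method="otsu", min_object_vox=1,
            smooth_sigma_vox=(0, 0, 0),
        )
        # oracle: exhaustive search maximizing between-class variance over
        # all candidate cuts of a 256-bin histogram
        counts, edges = np.histogram(img, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best_t, best_var = None, -1.0
        for cut in range(1, 256):
            w0, w1 = counts[:cut].sum(), counts[cut:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (counts[:cut] * centers[:cut]).sum() / w0
            m1 = (counts[cut:] * centers[cut:]).sum() / w1
            var = w0 * w1 * (m0 - m1) ** 2
            if var > best_var:
                best_var, best_t = var, centers[cut - 1]
        assert mask.threshold == pytest.approx(best_t, rel=1e-6)
        np.testing.assert_array_equal(mask.mask, img > best_t)

    def test_constant_stack_gives_empty_mask(self):
        mask = binarize_stack(ImageStack(np.full((4, 8, 8), 7.0), SPACING))
        assert not mask.mask.any()

    def test_out_of_range_fixed_threshold_warns(self):
        st_ = ImageStack(np.random.default_rng(2).random((4, 8, 8)), SPACING)
        with pytest.warns(UserWarning, match="outside intensity range"):
            mask = binarize_stack(st_, method=99.0, smooth_sigma_vox=(0, 0, 0))
        assert not mask.mask.any()

    def test_small_components_removed(self):
        arr = np.zeros((10, 10, 10))
        arr[1, 1, 1] = 1.0                    # single voxel speck
        arr[5:9, 5:9, 5:9] = 1.0              # 64-voxel block
        mask = binarize_stack(
            ImageStack(arr, SPACING), method=0.5, min_object_vox=27,
            smooth_sigma_vox=(0, 0, 0),
        )
        assert not mask.mask[1, 1, 1]
        assert mask.mask[6, 6, 6]


class TestSkeleton:
    def test_single_voxel_gives_one_node_no_edges(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[2, 2, 2] = True
        sk = skeletonize_stack(_mask(arr))
        assert (sk.n_nodes, sk.n_edges) == (1, 0)

    def test_straight_tube_skeletonizes_to_single_axial_path(self):
        arr = np.zeros((101, 11, 11), bool)
        arr[:, 4:7, 4:7] = True
        sk = skeletonize_stack(_mask(arr))
        degrees = [d for _, d in sk.graph.degree()]
        assert sk.n_nodes == 101 and sk.n_edges == 100
        assert max(degrees) == 2 and degrees.count(1) == 2
        # 100 steps of dz = 0.27 um
        assert skeleton_length(sk) * 1000 == pytest.approx(27.0, rel=1e-9)

    def test_l_shaped_tube_is_a_simple_path_through_the_corner(self):
        arr = np.zeros((5, 40, 40), bool)
        arr[1:4, 5:35, 5:8] = True
        arr[1:4, 32:35, 5:35] = True
        sk = skeletonize_stack(_mask(arr))
        degrees = [d for _, d in sk.graph.degree()]
        assert sum(1 for d in degrees if d > 2) == 0
        assert degrees.count(1) == 2

    def test_empty_mask_gives_empty_graph_zero_length(self):
        sk = skeletonize_stack(_mask(np.zeros((4, 4, 4))))
        assert sk.n_nodes == 0
        assert skeleton_length(sk) == 0.0


class TestSkeletonLength:
    def test_diagonal_inplane_path_is_analytic(self):
        arr = np.zeros((1, 51, 51), bool)
        for i in range(51):
            arr[0, i, i] = True
        sk = skeleton_graph_from_voxels(arr, SPACING)
        assert sk.n_edges == 50
        assert skeleton_length(sk) * 1000 == pytest.approx(50 * 0.2 * np.sqrt(2), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pairwise_oracle(self, seed, random_voxel_cloud):
        vox = random_voxel_cloud(seed)
        sk = skeleton_graph_from_voxels(vox, SPACING)
        assert skeleton_length(sk) == pytest.approx(
            brute_force_skeleton_length_mm(vox, SPACING), rel=1e-12
        )

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_oracle_equivalence_property(self, seed):
        vox = np.random.default_rng(seed).random((4, 5, 6)) < 0.2
        sk = skeleton_graph_from_voxels(vox, SPACING)
        assert skeleton_length(sk) == pytest.approx(
            brute_force_skeleton_length_mm(vox, SPACING), rel=1e-12
        )

    def test_nonpositive_spacing_rejected(self):
        sk = skeleton_graph_from_voxels(np.ones((1, 1, 2), bool), SPACING)
        with pytest.raises(ValueError, match="spacing"):
            skeleton_length(sk, spacing_um=(0.27, 0.0, 0.2))


class TestVolumeAndDensity:
    def test_volume_formula(self):
        assert stack_volume(ROISpec(0.01, 100, 0.27)) == pytest.approx(0.00027)
        assert stack_volume(ROISpec(1.0, 1, 1000.0)) == pytest.approx(1.0)

    def test_volume_additive_over_stacks(self):
        v = stack_volume(ROISpec(0.01, 100, 0.27))
        m = [StackMeasurement(1.0, v), StackMeasurement(2.0, v)]
        assert region_rad(m).total_volume_mm3 == pytest.approx(2 * v)

    def test_density_identity_and_linearity(self):
        s = region_rad([StackMeasurement(1.0, 0.001)])
        assert s.rad == pytest.approx(1000.0)
        doubled = region_rad([StackMeasurement(2.0, 0.001)])
        assert doubled.rad == pytest.approx(2 * s.rad)
        zero = region_rad([StackMeasurement(0.0, 0.001)])
        assert zero.rad == 0.0

    def test_rad_ratio_reproduces_reference_animals(self):
        # per-animal printed densities -> relative density at printed rounding
        assert rad_ratio(4539.63, 49215.43).value == pytest.approx(0.092, abs=5e-4)
        assert rad_ratio(29542.50, 7578.49).value == pytest.approx(3.90, abs=5e-3)

    def test_equal_densities_give_parity(self):
        a = RegionSummary("VTA", 1.0, 0.01)
        b = RegionSummary("NAc", 2.0, 0.02)
        assert rad_ratio(a, b).value == pytest.approx(1.0)

    def test_zero_nac_density_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rad_ratio(1.0, 0.0)


class TestPipelineRecovery:
    def test_anisotropy_rotating_tube_changes_length_as_predicted(self):
        # same tube, along z vs along x: measured lengths must match the
        # analytic physical lengths, not the voxel counts
        nz, nxy = 40, 72
        along_z = np.zeros((nz, 15, 15))
        along_z[:, 6:9, 6:9] = 1.0
        along_x = np.zeros((9, 15, nxy))
        along_x[3:6, 6:9, :] = 1.0
        lz = measure_stack(
            ImageStack(along_z, SPACING), method=0.5, smooth_sigma_vox=(0, 0, 0)
        ).axon_length_mm
        lx = measure_stack(
            ImageStack(along_x, SPACING), method=0.5, smooth_sigma_vox=(0, 0, 0)
        ).axon_length_mm
        assert lz * 1000 == pytest.approx((nz - 1) * SPACING[0], rel=0.05)
        assert lx * 1000 == pytest.approx((nxy - 1) * SPACING[2], rel=0.05)
        assert lz / lx == pytest.approx(((nz - 1) * 0.27) / ((nxy - 1) * 0.2), rel=0.05)

    def test_ground_truth_recovery_within_tolerance(self):
        errs = []
        for seed in range(10):
            spec = AxonPhantomSpec(
                n_axons=4, length_dist_um=(20, 60), shape_vox=(40, 128, 128), seed=seed
            )
            stack, truth = generate_axon_stack(spec)
            est = measure_stack(stack).axon_length_mm * 1000
            errs.append(abs(est - truth.total_length_um) / truth.total_length_um)
        assert np.median(errs) <= 0.15

    def test_error_degrades_monotonically_with_noise(self):
        # noise scales spanning the clean, moderate and threshold-collapse
        # regimes relative to the 100-unit signal amplitude
        sigmas = (0.0, 12.0, 16.0)
        med_errs = []
        for sigma in sigmas:
            errs = []
            for seed in range(6):
                noise = ("none",) if sigma == 0 else ("gaussian", sigma)
                spec = AxonPhantomSpec(
                    n_axons=3, length_dist_um=(20, 50), shape_vox=(32, 96, 96),
                    noise_model=noise, seed=seed,
                )
                stack, truth = generate_axon_stack(spec)
                est = measure_stack(stack).axon_length_mm * 1000
                errs.append(abs(est - truth.total_length_um) / truth.total_length_um)
            med_errs.append(np.median(errs))
        assert med_errs[0] <= med_errs[1] <= med_errs[2]
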