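"""Voxel morphometry: volumes, surface areas, skeletons, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoscope import (
    AcquisitionSpec,
    CellSpec,
    compare_populations,
    elongation_features,
    generate_field,
    mito_surface_area,
    mito_volume,
    mitochondrial_fraction,
    random_cells,
    rasterize_cylinder,
    segment_mito_voxels,
)

VOX = (0.3, 0.1038, 0.1038)


class TestVolumeAndSurface:
    def test_block_volume_is_count_times_voxel_volume(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[5:15, 5:15, 5:15] = True
        assert mito_volume(mask, (0.3, 0.1, 0.1)) == pytest.approx(
            1000 * 0.3 * 0.1 * 0.1
        )

    def test_single_voxel_surface_area(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        dz, dy, dx = VOX
        assert mito_surface_area(mask, VOX) == pytest.approx(
            2 * dy * dx + 2 * dz * dx + 2 * dz * dy
        )

    def test_boundary_voxels_count_exposed_faces(self):
        mask = np.ones((2, 2, 2), dtype=bool)  # cube: 6 faces x 4 voxels each
        dz, dy, dx = 1.0, 1.0, 1.0
        assert mito_surface_area(mask, (dz, dy, dx)) == pytest.approx(24.0)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_volume_additive_over_disjoint_masks(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((8, 8, 8)) < 0.3
        b = (rng.random((8, 8, 8)) < 0.3) & ~a
        assert mito_volume(a | b, VOX) == pytest.approx(
            mito_volume(a, VOX) + mito_volume(b, VOX), abs=1e-12
        )

    def test_doubling_z_step_doubles_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        v1 = mito_volume(mask, (0.3, 0.1, 0.1))
        v2 = mito_volume(mask, (0.6, 0.1, 0.1))
        assert v2 == pytest.approx(2 * v1)

    def test_cylinder_volume_close_to_analytic(self):
        spec = AcquisitionSpec(n_slices=12, frame_shape=(96, 96))
        r, length = 0.35, 5.0
        ext = spec.extent_um
        mask = rasterize_cylinder(
            spec, (ext[0] / 2, ext[1] / 2, ext[2] / 2), (0.0, 0.3, 1.0), r, length
        )
        assert mito_volume(mask, spec.voxel_dims) == pytest.approx(
            np.pi * r**2 * length, rel=0.10
        )


class TestSegmentMito:
    def test_all_zero_subvolume_gives_empty_mask(self):
        assert not segment_mito_voxels(np.zeros((8, 8, 8))).any()

    def test_uniform_noise_subvolume_gives_empty_or_tiny_mask(self):
        rng = np.random.default_rng(3)
        sub = rng.normal(50.0, 1.5, (12, 30, 30))
        mask = segment_mito_voxels(sub)
        assert mask.mean() < 0.01

    def test_deterministic(self, small_spec):
        rng = np.random.default_rng(1)
        sub = rng.gamma(2.0, 10.0, (10, 24, 24))
        assert np.array_equal(
            segment_mito_voxels(sub, small_spec), segment_mito_voxels(sub, small_spec)
        )

    def test_noiseless_tubule_cells_dice(self):
        spec = AcquisitionSpec(
            n_slices=16, frame_shape=(300, 300), noise_read_sd=0.0, photon_scale=None
        )
        cells = random_cells(
            spec, 9, seed=3, class_mix="mitochondrial", diameter_mean=4.0,
            diameter_sd=0.24, pitch_um=5.6, margin_um=2.8,
            mito_target_volume=1.5,
        )
        field, truth = generate_field(spec, cells, seed=9, channels=("gfp",))
        dices = []
        for lab in truth.cells["label"]:
            zs, ys, xs = np.nonzero(truth.cell_label_volume == lab)
            sl = (
                slice(zs.min(), zs.max() + 1),
                slice(ys.min(), ys.max() + 1),
                slice(xs.min(), xs.max() + 1),
            )
            mask = segment_mito_voxels(field["gfp"][sl], spec)
            tmask = truth.mito_label_volume[sl] == lab
            dices.append(2 * (mask & tmask).sum() / (mask.sum() + tmask.sum()))
        assert np.mean(dices) >= 0.8


class TestElongationFeatures:
    def test_empty_mask_gives_zeros(self):
        assert elongation_features(np.zeros((5, 5, 5), dtype=bool), VOX) == (0.0, 0, 0)

    def test_straight_cylinder_skeleton(self):
        spec = AcquisitionSpec(n_slices=10, frame_shape=(80, 80))
        ext = spec.extent_um
        mask = rasterize_cylinder(
            spec, (ext[0] / 2, ext[1] / 2, ext[2] / 2), (0.0, 0.0, 1.0), 0.3, 5.0
        )
        length, branches, components = elongation_features(mask, spec.voxel_dims)
        # skeletonization recedes from each flat cap by about one tubule
        # radius, so the centerline of an L=5, r=0.3 cylinder is ~4.4 um
        assert length == pytest.approx(5.0 - 2 * 0.3, abs=0.5)
        assert branches == 0
        assert components == 1

    def test_fragmented_network_has_more_components_at_equal_volume(self):
        spec = AcquisitionSpec(n_slices=16, frame_shape=(300, 300))
        out = {}
        for name, tubules in [
            ("fragmented", (8, 0.6, 0.28)),  # many short tubules
            ("fused", (2, 3.6, 0.28)),       # few long tubules, same volume
        ]:
            cells = random_cells(
                spec, 9, seed=11, class_mix="mitochondrial", diameter_mean=4.0,
                pitch_um=5.6, margin_um=2.8, tubule_params=tubules,
                mito_target_volume=2.0,
            )
            _, truth = generate_field(spec, cells, seed=12, channels=("gfp",))
            comps, vols = [], []
            for lab in truth.cells["label"]:
                m = truth.mito_label_volume == lab
                _, _, c = elongation_features(m, spec.voxel_dims)
                comps.append(c)
                vols.append(mito_volume(m, spec.voxel_dims))
            out[name] = (np.mean(comps), np.mean(vols))
        assert out["fragmented"][0] > out["fused"][0]
        assert out["fragmented"][1] == pytest.approx(out["fused"][1], rel=0.10)


class TestMitochondrialFraction:
    def test_fraction_is_mito_over_strain_mean_cell_volume(self):
        frac, summary = mitochondrial_fraction(
            [3.0] * 50, [30.0] * 50, min_cells=50
        )
        assert np.allclose(frac, 0.1)
        assert summary["mean"] == pytest.approx(0.1)
        assert not summary["low_coverage"]

    def test_zero_mito_volumes_give_zero_fractions(self):
        frac, _ = mitochondrial_fraction([0.0] * 60, [25.0] * 60)
        assert (frac == 0).all()

    def test_low_coverage_warns_and_flags(self):
        with pytest.warns(UserWarning, match="low-coverage"):
            _, summary = mitochondrial_fraction([1.0] * 10, [20.0] * 10)
        assert summary["low_coverage"]

    def test_per_cell_mode_divides_each_cell(self):
        frac, _ = mitochondrial_fraction(
            [1.0, 2.0] * 30, [10.0, 40.0] * 30, per_cell_volume=True
        )
        assert frac.iloc[0] == pytest.approx(0.1)
        assert frac.iloc[1] == pytest.approx(0.05)


class TestComparePopulations:
    def test_identical_groups_give_zero_t_and_unity_p(self):
        g = np.linspace(0, 1, 50)
        res = compare_populations({"a": g, "b": g.copy()})
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=1e-9)

    def test_large_effect_is_overwhelmingly_significant(self):
        rng = np.random.default_rng(0)
        res = compare_populations(
            {"a": rng.normal(0, 1, 50), "b": rng.normal(5, 1, 50)}
        )
        assert res["p"] < 1e-6

    def test_three_groups_dispatch_to_anova_tukey(self):
        rng = np.random.default_rng(1)
        res = compare_populations(
            {k: rng.normal(0, 1, 20) for k in ("a", "b", "c")}
        )
        assert res["test"] == "anova_tukey"
        assert len(res["pairwise"]) == 3

    @pytest.mark.parametrize(
        "groups, match",
        [
            ({"a": [1.0], "b": [1.0, 2.0]}, "a"),
            ({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0]}, "a"),
        ],
    )
    def test_degenerate_group_named_in_error(self, groups, match):
        with pytest.raises(ValueError, match=match):
            compare_populations(groups)
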