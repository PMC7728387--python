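"""Generator correctness: determinism, geometry, optics, ground truth."""

import numpy as np
import pytest

from phenoscope import (
    AcquisitionSpec,
    CellSpec,
    generate_field,
    generate_growth_curve,
    generate_screen_dataset,
    random_cells,
)
from phenoscope.simulate import volume_matched_tubule_params


def test_same_seed_is_bit_identical(small_spec):
    cells = random_cells(small_spec, 8, seed=1)
    f1, t1 = generate_field(small_spec, cells, seed=42)
    f2, t2 = generate_field(small_spec, cells, seed=42)
    for ch in f1.channels:
        assert np.array_equal(f1[ch], f2[ch])
    assert np.array_equal(t1.cell_label_volume, t2.cell_label_volume)
    assert t1.cells.equals(t2.cells)


def test_different_seed_changes_noise(small_spec):
    cells = random_cells(small_spec, 4, seed=1)
    f1, _ = generate_field(small_spec, cells, seed=1)
    f2, _ = generate_field(small_spec, cells, seed=2)
    assert not np.array_equal(f1["gfp"], f2["gfp"])


def test_zero_intensity_cell_renders_dark_gfp(one_cell, clean_spec):
    field, _ = one_cell(spec=clean_spec, intensity_scale=0.0)
    assert np.all(field["gfp"] == 0.0)


def test_sphere_cell_volume_matches_closed_form(one_cell, clean_spec):
    field, truth = one_cell(spec=clean_spec, diameter=4.0)
    analytic = 4.0 / 3.0 * np.pi * 2.0**3
    voxelized = truth.cells.loc[0, "cell_volume_um3"]
    # one voxel shell at r=2 um: ~4 pi r^2 * dz worth of ambiguity
    shell = 4 * np.pi * 2.0**2 * clean_spec.z_step
    assert abs(voxelized - analytic) < shell
    assert voxelized == pytest.approx(analytic, rel=0.10)


def test_ground_truth_volume_is_voxel_count_times_voxel_volume(mixed_field):
    _, truth = mixed_field
    counts = np.bincount(truth.cell_label_volume.ravel())
    for _, row in truth.cells.iterrows():
        assert row["cell_volume_um3"] == pytest.approx(
            counts[row["label"]] * truth.voxel_volume, abs=1e-12
        )


def test_nucleus_and_mito_labels_lie_inside_their_cell(small_spec):
    cells = random_cells(
        small_spec, 8, seed=3,
        class_mix={"nuclear": 0.5, "mitochondrial": 0.5},
        diameter_mean=3.5, diameter_sd=0.2, pitch_um=4.8, margin_um=2.3,
    )
    _, truth = generate_field(small_spec, cells, seed=8)
    for organelle in (truth.nucleus_label_volume, truth.mito_label_volume):
        inside = organelle > 0
        assert np.array_equal(
            organelle[inside], truth.cell_label_volume[inside]
        )


def test_psf_conserves_total_intensity_for_interior_cell():
    # deep stack so the cell is interior along z as well as laterally
    spec_nonoise = AcquisitionSpec(
        n_slices=24, frame_shape=(160, 160),
        noise_read_sd=0.0, photon_scale=None,
    )
    spec_nopsf = AcquisitionSpec(
        n_slices=24, frame_shape=(160, 160),
        psf_sigma_xy=0.0, psf_sigma_z=0.0, noise_read_sd=0.0, photon_scale=None,
    )
    ext = spec_nonoise.extent_um
    cell = [CellSpec(center=(ext[0] / 2, ext[1] / 2, ext[2] / 2), diameter=3.0)]
    blurred, _ = generate_field(spec_nonoise, cell, seed=1)
    sharp, _ = generate_field(spec_nopsf, cell, seed=1)
    assert blurred["gfp"].sum() == pytest.approx(sharp["gfp"].sum(), rel=0.005)


@pytest.mark.parametrize(
    "loc_class, lo, hi",
    [("nuclear", 2.0, np.inf), ("cytoplasmic", 0.8, 1.2)],
)
def test_class_separability_of_nuclear_vs_cytoplasmic(
    one_cell, clean_spec, loc_class, lo, hi
):
    field, truth = one_cell(spec=clean_spec, localization_class=loc_class)
    nuc = truth.nucleus_label_volume == 1
    cyto = (truth.cell_label_volume == 1) & ~nuc
    ratio = field["gfp"][nuc].mean() / field["gfp"][cyto].mean()
    assert lo < ratio < hi


def test_cell_outside_frame_raises(small_spec):
    with pytest.raises(ValueError, match="frame too small"):
        generate_field(
            small_spec, [CellSpec(center=(1.8, 0.5, 8.0), diameter=4.0)], seed=0
        )


def test_overlap_budget_rejects_coincident_cells(small_spec):
    ext = small_spec.extent_um
    c = (ext[0] / 2, ext[1] / 2, ext[2] / 2)
    cells = [CellSpec(center=c, diameter=4.0), CellSpec(center=c, diameter=4.0)]
    with pytest.raises(ValueError, match="overlapping-cell budget"):
        generate_field(small_spec, cells, seed=0)


def test_mito_target_volume_injection_is_accurate(small_spec):
    ext = small_spec.extent_um
    cell = CellSpec(
        center=(ext[0] / 2, ext[1] / 2, ext[2] / 2), diameter=4.5,
        localization_class="mitochondrial", mito_target_volume=2.0,
    )
    _, truth = generate_field(small_spec, [cell], seed=4)
    assert truth.cells.loc[0, "mito_volume_um3"] == pytest.approx(2.0, rel=0.05)


def test_volume_matched_tubule_params_closed_form():
    n, length, r = volume_matched_tubule_params(2.0, 4, 0.28)
    per_tubule = np.pi * r**2 * length + 4.0 / 3.0 * np.pi * r**3
    assert n * per_tubule == pytest.approx(2.0, abs=1e-12)
    with pytest.raises(ValueError):
        volume_matched_tubule_params(0.01, 10, 0.28)


class TestScreenDataset:
    def test_null_plan_injects_unity_folds(self):
        pairs = list(
            generate_screen_dataset(
                4, {}, AcquisitionSpec(n_slices=2, frame_shape=(150, 150)),
                seed=0, cells_per_field=4, n_fields=1, diameter_mean=2.4,
            )
        )
        assert [p.true_fold for p in pairs] == [1.0] * 4

    def test_injected_fold_scales_true_mean_intensity(self):
        spec = AcquisitionSpec(n_slices=2, frame_shape=(200, 200))
        (pair,) = generate_screen_dataset(
            1, {"G1": ("cytoplasmic", "cytoplasmic", 1.65)}, spec,
            seed=3, cells_per_field=12, n_fields=2, diameter_mean=2.6,
        )
        wt = np.concatenate(
            [t.cells["true_mean_gfp_maxproj"] for _, t in pair.wt]
        )
        mut = np.concatenate(
            [t.cells["true_mean_gfp_maxproj"] for _, t in pair.mut]
        )
        assert mut.mean() / wt.mean() == pytest.approx(1.65, rel=0.12)

    def test_duplicate_gene_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            list(generate_screen_dataset(2, {}, seed=0, gene_names=["A", "A"]))

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            list(
                generate_screen_dataset(
                    2, {"A": ("cytoplasmic", "cytoplasmic", 0.0)}, seed=0
                )
            )


class TestGrowthCurve:
    def test_one_doubling_in_pure_exponential_phase(self):
        curve = generate_growth_curve(
            od0=0.1, doubling_time_h=1.5, carrying_capacity=1000.0,
            duration_h=2.0, noise_sd=0.0,
        )
        od_at = np.interp(1.5, curve["time_h"], curve["od600"])
        assert od_at == pytest.approx(0.2, rel=1e-3)

    def test_noiseless_curve_is_monotone(self):
        curve = generate_growth_curve(0.05, 2.0, noise_sd=0.0)
        assert (np.diff(curve["od600"]) >= 0).all()

    def test_saturates_at_carrying_capacity(self):
        curve = generate_growth_curve(0.1, 1.0, carrying_capacity=1.5, duration_h=48)
        assert curve["od600"].iloc[-1] == pytest.approx(1.5, rel=1e-3)
        assert curve["od600"].max() <= 1.5 + 1e-9

    def test_seeded_noise_is_reproducible(self):
        a = generate_growth_curve(0.1, 1.5, noise_sd=0.01, seed=5)
        b = generate_growth_curve(0.1, 1.5, noise_sd=0.01, seed=5)
        assert np.array_equal(a["od600"], b["od600"])

    @pytest.mark.parametrize(
        "kwargs", [{"od0": -0.1}, {"doubling_time_h": 0.0}, {"carrying_capacity": 0.05}]
    )
    def test_invalid_parameters_raise(self, kwargs):
        base = dict(od0=0.1, doubling_time_h=1.5)
        base.update(kwargs)
        with pytest.raises(ValueError):
            generate_growth_curve(**base)
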