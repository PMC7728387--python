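"""Per-cell intensity measurement, fold-change pairing, ranking, confirmation."""

import numpy as np
import pandas as pd
import pytest

from phenoscope import (
    AcquisitionSpec,
    LowCoverageError,
    confirm_hits,
    field_fold_change,
    generate_screen_dataset,
    mean_intensity_per_cell,
    pair_fold_change,
    rank_and_call,
)
from phenoscope.screen import run_screen


@pytest.fixture()
def toy_labels():
    labels = np.zeros((20, 20), dtype=np.int32)
    labels[2:8, 2:8] = 1
    labels[12:18, 12:18] = 2
    return labels


class TestMeanIntensity:
    def test_uniform_image_gives_that_value_for_every_cell(self, toy_labels):
        vol = np.full((5, 20, 20), 7.25)
        means = mean_intensity_per_cell(vol, toy_labels)
        assert list(means.index) == [1, 2]
        assert np.allclose(means, 7.25)

    def test_linearity_under_intensity_scaling(self, toy_labels):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 10, (5, 20, 20))
        m1 = mean_intensity_per_cell(vol, toy_labels)
        m2 = mean_intensity_per_cell(2.0 * vol, toy_labels)
        assert np.allclose(m2, 2.0 * m1)

    def test_background_excluded(self, toy_labels):
        vol = np.zeros((3, 20, 20))
        vol[:, 2:8, 2:8] = 4.0
        means = mean_intensity_per_cell(vol, toy_labels, projection="max")
        assert means.loc[1] == pytest.approx(4.0)
        assert means.loc[2] == pytest.approx(0.0)

    def test_shape_mismatch_raises(self, toy_labels):
        with pytest.raises(ValueError, match="label map"):
            mean_intensity_per_cell(np.zeros((3, 10, 10)), toy_labels)

    def test_mean_projection_estimator_is_unbiased(self):
        # >=100 rendered cells with noise: per-cell estimates on the
        # ground-truth footprint track the noise-free truth within 2%
        spec = AcquisitionSpec(n_slices=3, frame_shape=(248, 248))
        est, truth_vals = [], []
        for pair in generate_screen_dataset(1, {}, spec, seed=9, n_fields=3):
            for field, truth in pair.wt + pair.mut:
                labels2d = truth.cell_label_volume.max(axis=0)
                means = mean_intensity_per_cell(
                    field["gfp"], labels2d, projection="mean"
                )
                tt = truth.cells.set_index("label")
                for lab in means.index:
                    est.append(means.loc[lab])
                    truth_vals.append(tt.loc[lab, "true_mean_gfp_meanproj"])
        est, truth_vals = np.asarray(est), np.asarray(truth_vals)
        assert len(est) >= 100
        assert est.mean() / truth_vals.mean() == pytest.approx(1.0, abs=0.02)


class TestFoldChange:
    def test_identical_populations_give_unity(self):
        vals = np.linspace(50, 150, 40)
        assert field_fold_change(vals, vals) == pytest.approx(1.0)

    def test_swapping_arguments_gives_reciprocal(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(10, 100, 50), rng.uniform(10, 100, 50)
        assert field_fold_change(a, b) == pytest.approx(
            1.0 / field_fold_change(b, a)
        )

    def test_low_coverage_raises(self):
        with pytest.raises(LowCoverageError):
            field_fold_change(np.ones(10), np.ones(40))

    def test_zero_wt_mean_raises(self):
        with pytest.raises(ValueError, match="zero"):
            field_fold_change(np.ones(40), np.zeros(40))

    def test_paired_fields_average_their_ratios(self):
        mut = [np.full(40, 120.0), np.full(40, 180.0)]
        wt = [np.full(40, 100.0), np.full(40, 100.0)]
        assert pair_fold_change(mut, wt) == pytest.approx((1.2 + 1.8) / 2)


class TestRankAndCall:
    def test_exemplar_hits_called_with_direction(self):
        res = rank_and_call({"GSY2": 1.65, "ACO2": 0.51, "NULL": 1.02}).set_index(
            "gene"
        )
        assert res.loc["GSY2", "primary_hit"] and res.loc["GSY2", "direction"] == "up"
        assert res.loc["ACO2", "primary_hit"] and res.loc["ACO2", "direction"] == "down"
        assert not res.loc["NULL", "primary_hit"]

    def test_boundary_values_are_not_hits(self):
        res = rank_and_call({"A": 1.30, "B": 0.70}).set_index("gene")
        assert not res["primary_hit"].any()
        assert (res["direction"] == "none").all()

    def test_ranks_are_a_permutation_sorted_by_fold(self):
        folds = {f"G{i}": 0.5 + 0.1 * i for i in range(10)}
        res = rank_and_call(folds)
        assert sorted(res["rank"]) == list(range(1, 11))
        assert res["fold_change"].is_monotonic_decreasing

    def test_ties_break_by_gene_name(self):
        res = rank_and_call({"B": 1.5, "A": 1.5, "C": 1.5})
        assert list(res["gene"]) == ["A", "B", "C"]

    def test_higher_fold_never_ranks_lower(self):
        folds = {"X": 1.2, "Y": 1.5, "Z": 0.9}
        res = rank_and_call(folds).set_index("gene")
        assert res.loc["Y", "rank"] < res.loc["X", "rank"] < res.loc["Z", "rank"]

    def test_invalid_folds_raise(self):
        with pytest.raises(ValueError, match="finite and positive"):
            rank_and_call({"A": -1.0})


class TestConfirmHits:
    def _round(self, folds):
        return rank_and_call(folds)

    def test_hit_in_both_rounds_is_confirmed(self):
        conf = confirm_hits(self._round({"A": 1.6}), self._round({"A": 1.7}))
        assert bool(conf.set_index("gene").loc["A", "confirmed"])

    def test_hit_that_regresses_is_not_confirmed(self):
        conf = confirm_hits(self._round({"A": 1.6}), self._round({"A": 1.1}))
        assert not bool(conf.set_index("gene").loc["A", "confirmed"])

    def test_direction_flip_is_not_confirmed(self):
        conf = confirm_hits(self._round({"A": 1.6}), self._round({"A": 0.5}))
        assert not bool(conf.set_index("gene").loc["A", "confirmed"])

    def test_missing_gene_leaves_confirmation_unknown(self):
        conf = confirm_hits(
            self._round({"A": 1.6, "B": 1.0}), self._round({"B": 1.0})
        ).set_index("gene")
        assert pd.isna(conf.loc["A", "confirmed"])
        assert conf.loc["B", "confirmed"] == False  # noqa: E712


def test_fold_change_invariant_to_global_intensity_scale():
    spec = AcquisitionSpec(n_slices=2, frame_shape=(248, 248))
    (pair,) = generate_screen_dataset(
        1, {"G": ("cytoplasmic", "cytoplasmic", 1.65)}, spec, seed=4
    )

    def fold(scale):
        per = {"wt": [], "mut": []}
        for geno, fields in (("wt", pair.wt), ("mut", pair.mut)):
            for field, truth in fields:
                labels2d = truth.cell_label_volume.max(axis=0)
                per[geno].append(
                    mean_intensity_per_cell(field["gfp"] * scale, labels2d).to_numpy()
                )
        return pair_fold_change(per["mut"], per["wt"])

    assert fold(1.0) == pytest.approx(fold(17.3), rel=1e-12)


def test_run_screen_recovers_injected_fold_end_to_end():
    hit_plan = {"DUR1": ("cytoplasmic", "cytoplasmic", 3.77)}
    res = run_screen(generate_screen_dataset(6, hit_plan, seed=13)).set_index("gene")
    # a single-gene estimate carries ~3% cell-sampling noise on top of
    # the rendering tolerance
    assert res.loc["DUR1", "fold_change"] == pytest.approx(3.77, rel=0.08)
    assert res.loc["DUR1", "rank"] == 1
    assert res.loc["DUR1", "direction"] == "up"
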