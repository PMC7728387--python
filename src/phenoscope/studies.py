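"""End-to-end synthetic studies with known ground truth.

Each function builds a complete experiment — generator, measurement,
statistics — under fixed study conditions and reports how well the
pipeline recovers the injected truth. They are the package's validation
benchmarks: the unit of reporting is a recovery rate, an error, or a
test statistic, never a raw image.

Problem sizes (field counts, cells per field, stack depths) are chosen
so a full validation run completes on a laptop in minutes; the
statistical design of each study (paired fields, two-round
confirmation, per-replicate aggregation, cell-count floors) mirrors the
screen being emulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acquisition import AcquisitionSpec
from .assay_stats import doubling_time, welch_t
from .mito import mito_volume, mitochondrial_fraction, segment_mito_voxels
from .profiles import (
    classify_change,
    extract_features,
    line_profile,
    mean_profile,
    percent_nuclear,
    summarize_features,
)
from .screen import confirm_hits, run_screen
from .segmentation import detect_nuclei, segment_cells
from .simulate import (
    generate_field,
    generate_growth_curve,
    generate_screen_dataset,
    random_cells,
)

__all__ = [
    "segmentation_fidelity_study",
    "screen_recovery_study",
    "mito_fraction_study",
    "localization_study",
    "growth_roundtrip_study",
    "SEGMENTATION_SPEC",
    "MITO_SPEC",
    "LOCALIZATION_SPEC",
]

#: Acquisition used for segmentation-fidelity fields (40 cells / field).
SEGMENTATION_SPEC = AcquisitionSpec(n_slices=8, frame_shape=(296, 296))
#: Acquisition used for mitochondrial morphometry (cells up to ~5 μm).
MITO_SPEC = AcquisitionSpec(n_slices=18, frame_shape=(300, 300))
#: Acquisition used for localization profiling (60 cells / field).
LOCALIZATION_SPEC = AcquisitionSpec(n_slices=10, frame_shape=(344, 344))

#: Injected screen effect sizes: the screen's own exemplar fold changes
#: (an up-hit, a down-hit and a strong up-hit).
SCREEN_EFFECT_FOLDS = (1.65, 0.51, 3.77)


def _sub_seed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(seed), *keys]).generate_state(1)[0] % 2**31)


def segmentation_fidelity_study(
    seed: int,
    n_fields: int = 10,
    cells_per_field: int = 40,
    spec: AcquisitionSpec = SEGMENTATION_SPEC,
) -> dict:
    """Score brightfield segmentation against ground-truth label maps.

    ``n_fields`` fields of ``cells_per_field`` non-touching cells are
    rendered; each truth cell is matched to the segmented region that
    covers most of its footprint and scored by intersection-over-union.

    Returns ``recall`` (matched truth cells / truth cells), ``mean_iou``
    and ``frac_iou_ge_080`` over matches, and ``n_cells``.
    """
    ious: list[float] = []
    n_truth = 0
    n_matched = 0
    for k in range(n_fields):
        cells = random_cells(
            spec, cells_per_field, _sub_seed(seed, 10, k),
            class_mix={"cytoplasmic": 0.5, "nuclear": 0.3, "punctate": 0.2},
            diameter_mean=3.0, diameter_sd=0.2, pitch_um=4.2, margin_um=2.6,
        )
        field, truth = generate_field(
            spec, cells, _sub_seed(seed, 11, k), channels=("brightfield", "gfp")
        )
        labels, table = segment_cells(field["brightfield"], spec)
        kept = set(table["label"])
        truth2d = truth.cell_label_volume.max(axis=0)
        for tl in np.unique(truth2d)[1:]:
            n_truth += 1
            tmask = truth2d == tl
            votes = labels[tmask]
            votes = votes[votes > 0]
            if len(votes) == 0:
                continue
            sl = np.bincount(votes).argmax()
            if sl not in kept:
                continue
            smask = labels == sl
            iou = (smask & tmask).sum() / (smask | tmask).sum()
            n_matched += 1
            ious.append(float(iou))
    ious_arr = np.asarray(ious)
    return {
        "recall": n_matched / n_truth,
        "mean_iou": float(ious_arr.mean()),
        "frac_iou_ge_080": float((ious_arr >= 0.8).mean()),
        "n_cells": n_truth,
    }


def screen_recovery_study(
    seed: int,
    n_genes: int = 360,
    n_hits: int = 20,
    folds: tuple[float, ...] = SCREEN_EFFECT_FOLDS,
    **dataset_kwargs,
) -> dict:
    """Full two-round paired screen with injected intensity hits.

    ``n_hits`` genes receive mutant/WT intensity folds cycling through
    ``folds``; the rest are null. Both rounds are independent
    acquisitions (fresh fields, same design); hits must be called in
    the same direction twice to be confirmed.

    Returns ``sensitivity`` (confirmed injected / injected),
    ``false_confirmed`` and ``n_confirmed`` counts, ``fdr`` (non-injected
    fraction of confirmed calls), and the confirmed result table.
    """
    hit_plan = {
        f"HIT{i:03d}": ("cytoplasmic", "cytoplasmic", folds[i % len(folds)])
        for i in range(n_hits)
    }
    round1 = run_screen(
        generate_screen_dataset(
            n_genes, hit_plan, seed=_sub_seed(seed, 20), **dataset_kwargs
        )
    )
    round2 = run_screen(
        generate_screen_dataset(
            n_genes, hit_plan, seed=_sub_seed(seed, 21), **dataset_kwargs
        )
    )
    result = confirm_hits(round1, round2)
    confirmed = result[result["confirmed"].fillna(False)]
    injected = set(hit_plan)
    n_true = int(confirmed["gene"].isin(injected).sum())
    n_false = len(confirmed) - n_true
    return {
        "sensitivity": n_true / len(injected),
        "n_confirmed": len(confirmed),
        "false_confirmed": n_false,
        "fdr": n_false / max(len(confirmed), 1),
        "result": result,
    }


def _strain_fractions(
    spec: AcquisitionSpec,
    seed: int,
    n_replicates: int,
    cells_per_replicate: int,
    diameter_um: float,
    mito_volume_um3: float,
    n_tubules: int,
) -> tuple[np.ndarray, float, float]:
    """Render one strain, segment cells and mitochondria, return
    (per-cell fractions, truth mito mean, truth cell-volume mean)."""
    fractions = []
    truth_mito = []
    truth_cell = []
    for rep in range(n_replicates):
        cells = random_cells(
            spec, cells_per_replicate, _sub_seed(seed, 30, rep),
            class_mix="mitochondrial",
            diameter_mean=diameter_um, diameter_sd=diameter_um * 0.06,
            pitch_um=diameter_um + 1.0, margin_um=diameter_um / 2 + 0.7,
            tubule_params=(n_tubules, 1.2, 0.28),
            mito_target_volume=mito_volume_um3,
        )
        field, truth = generate_field(
            spec, cells, _sub_seed(seed, 31, rep), channels=("brightfield", "gfp")
        )
        truth_mito.append(truth.cells["mito_volume_um3"].mean())
        truth_cell.append(truth.cells["cell_volume_um3"].mean())
        labels, table = segment_cells(field["brightfield"], spec, max_area_px=8000)
        volumes = []
        for _, row in table.iterrows():
            ys, xs = np.nonzero(labels == row["label"])
            sub = field["gfp"][:, ys.min() : ys.max() + 1, xs.min() : xs.max() + 1]
            volumes.append(
                mito_volume(segment_mito_voxels(sub, spec), spec.voxel_dims)
            )
        frac, _ = mitochondrial_fraction(
            volumes, table["cell_volume_um3"], min_cells=cells_per_replicate // 2
        )
        fractions.append(frac.to_numpy())
    return np.concatenate(fractions), float(np.mean(truth_mito)), float(np.mean(truth_cell))


def mito_fraction_study(
    seed: int,
    mito_fold: float = 3.0,
    cell_volume_fold: float = 1.76,
    n_replicates: int = 3,
    cells_per_replicate: int = 18,
    wt_diameter_um: float = 4.0,
    wt_mito_volume_um3: float = 1.5,
    spec: AcquisitionSpec = MITO_SPEC,
) -> dict:
    """WT vs mutant mitochondrial-fraction comparison with injected folds.

    The mutant's mitochondrial network volume is ``mito_fold`` × WT and
    its cell volume ``cell_volume_fold`` × WT (diameters scale by the
    cube root), so the injected fraction ratio is their quotient. The
    pipeline runs blind: brightfield segmentation for cell volumes,
    per-cell GFP thresholding for mitochondrial volumes, fractions
    against the strain-mean cell volume, Welch's t-test between strains.

    Returns per-strain fraction arrays, the estimated and injected
    ratios, the Welch p-value, and the rendered truth ratios.
    """
    wt, wt_truth_mito, wt_truth_cell = _strain_fractions(
        spec, _sub_seed(seed, 1), n_replicates, cells_per_replicate,
        wt_diameter_um, wt_mito_volume_um3, n_tubules=5,
    )
    mut, mut_truth_mito, mut_truth_cell = _strain_fractions(
        spec, _sub_seed(seed, 2), n_replicates, cells_per_replicate,
        wt_diameter_um * cell_volume_fold ** (1 / 3),
        wt_mito_volume_um3 * mito_fold, n_tubules=7,
    )
    ratio = float(mut.mean() / wt.mean())
    injected = mito_fold / cell_volume_fold
    return {
        "wt_fractions": wt,
        "mut_fractions": mut,
        "ratio": ratio,
        "injected_ratio": injected,
        "relative_error": ratio / injected - 1.0,
        "welch_p": welch_t({"wt": wt, "mut": mut})["p"],
        "truth_mito_ratio": mut_truth_mito / wt_truth_mito,
        "truth_cell_ratio": mut_truth_cell / wt_truth_cell,
        "n_wt": len(wt),
        "n_mut": len(mut),
    }


def _field_features(
    spec: AcquisitionSpec,
    class_mix,
    seed: int,
    n_cells: int,
    intensity_factor: float = 1.0,
    **cell_kwargs,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a population and extract per-cell localization features."""
    cells = random_cells(
        spec, n_cells, _sub_seed(seed, 40),
        class_mix=class_mix, diameter_mean=3.4, diameter_sd=0.25,
        pitch_um=4.3, margin_um=2.4, intensity_factor=intensity_factor,
        **cell_kwargs,
    )
    field, _ = generate_field(spec, cells, _sub_seed(seed, 41))
    labels, table = segment_cells(field["brightfield"], spec)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    if len(table):
        keep[table["label"].to_numpy()] = True
    labels = np.where(keep[labels], labels, 0)
    nuclei = detect_nuclei(field["dapi"], labels)
    proj = field["gfp"].max(axis=0)
    features = extract_features(proj, labels, nuclei, spec.pixel_size_xy)
    return features, proj, labels, nuclei

#: The six-category benchmark: expected category, WT class (+kwargs),
#: mutant class (+kwargs), injected intensity fold.
CATEGORY_BENCHMARK = [
    (
        "mitochondrial elongation",
        ("mitochondrial", {"mito_target_volume": 1.0}),
        ("mitochondrial", {"mito_target_volume": 3.0, "tubule_params": (7, 1.2, 0.28)}),
        1.0,
    ),
    ("cytoplasm to punctate", ("cytoplasmic", {}), ("punctate", {}), 1.65),
    ("nucleus to cytoplasm", ("nuclear", {}), ("cytoplasmic", {}), 1.0),
    ("cytoplasm to nucleus", ("cytoplasmic", {}), ("nuclear", {}), 1.0),
    ("cell periphery to cytoplasm", ("periphery", {}), ("cytoplasmic", {}), 1.0),
    ("increased abundance", ("cytoplasmic", {}), ("cytoplasmic", {}), 1.65),
    ("no change", ("cytoplasmic", {}), ("cytoplasmic", {}), 1.0),
]


def localization_study(
    seed: int,
    n_cells: int = 60,
    benchmark_cells: int = 40,
    nuclear_fraction: float = 0.8,
    spec: AcquisitionSpec = LOCALIZATION_SPEC,
) -> dict:
    """Nuclear-enrichment scoring plus the six-category change benchmark.

    Part one renders a mixed population (``nuclear_fraction`` of cells
    nuclear-class, the rest cytoplasmic), scores percent-nuclear via
    the nc-ratio flag, and extracts nucleus-centered line profiles for
    the nuclear and dispersed subpopulations. Part two renders a paired
    WT/mutant population for every benchmark category and runs the
    rule-based classifier.

    Returns the percent-nuclear estimate and its generated truth, the
    center/edge profile contrasts, and per-category classification
    results with overall accuracy.
    """
    mix = {"nuclear": nuclear_fraction, "cytoplasmic": 1.0 - nuclear_fraction}
    features, proj, labels, nuclei = _field_features(spec, mix, seed, n_cells)
    pct = percent_nuclear(features, min_cells=min(50, len(features)))

    # profiles: nuclear-enriched cells peak at the center sample
    nuc_idx = nuclei.set_index("label")
    profiles_nuclear, profiles_dispersed = [], []
    for _, row in features.iterrows():
        if not nuc_idx.loc[row["label"], "has_nucleus"]:
            continue
        prof = line_profile(
            proj,
            (nuc_idx.loc[row["label"], "nucleus_y"], nuc_idx.loc[row["label"], "nucleus_x"]),
            cell_label=int(row["label"]),
        )
        if row["nc_ratio"] > 1.5:
            profiles_nuclear.append(prof)
        else:
            profiles_dispersed.append(prof)

    def center_edge(profiles):
        curve = mean_profile(profiles)
        center = curve[len(curve) // 2]
        edge = np.nanmean([curve[5], curve[-6]])
        return float(center / edge) if edge > 0 else float("nan")

    contrast_nuclear = center_edge(profiles_nuclear)
    contrast_dispersed = center_edge(profiles_dispersed)

    rows = []
    for ci, (expected, (cls_wt, kw_wt), (cls_mut, kw_mut), fold) in enumerate(
        CATEGORY_BENCHMARK
    ):
        wt_feats, *_ = _field_features(
            spec, cls_wt, _sub_seed(seed, 50, ci), benchmark_cells, **kw_wt
        )
        mut_feats, *_ = _field_features(
            spec, cls_mut, _sub_seed(seed, 51, ci), benchmark_cells,
            intensity_factor=fold, **kw_mut,
        )
        called = classify_change(
            summarize_features(wt_feats), summarize_features(mut_feats), fold
        )
        rows.append({"expected": expected, "called": called, "correct": called == expected})
    bench = pd.DataFrame(rows)
    return {
        "percent_nuclear": pct,
        "true_percent_nuclear": 100.0 * nuclear_fraction,
        "contrast_nuclear": contrast_nuclear,
        "contrast_dispersed": contrast_dispersed,
        "benchmark": bench,
        "category_accuracy": float(bench["correct"].mean()),
    }


def growth_roundtrip_study(
    seed: int,
    doubling_times_h: tuple[float, ...] = (1.5, 2.0, 3.0),
) -> dict:
    """Recover known doubling times from noiseless logistic curves.

    Carrying capacity is set high relative to the OD reached inside the
    3–7.5 h fit window so the trajectory is purely exponential there —
    the regime in which the doubling-time estimator is defined.
    """
    rows = []
    for td in doubling_times_h:
        curve = generate_growth_curve(
            od0=0.01, doubling_time_h=td, carrying_capacity=20.0,
            duration_h=8.0, noise_sd=0.0, seed=seed,
        )
        est = doubling_time(curve["time_h"], curve["od600"])
        rows.append({"true_h": td, "estimated_h": est, "rel_error": est / td - 1.0})
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "max_abs_rel_error": float(table["rel_error"].abs().max()),
    }
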