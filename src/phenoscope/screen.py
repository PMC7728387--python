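"""Paired fold-change intensity screen: per-cell GFP means, gene ranking,
primary-hit calls at the 1.3 / 0.7 cut-offs and two-round confirmation.

The screen statistic is the mean-of-cell-means ratio: per field, every
cell's mean GFP grey value is measured over its segmented region of
interest on a z-projection; the field average of those per-cell means for
the mutant is divided by the same quantity for its paired wild-type
field. Genes are ranked by fold change and called as primary hits when
the fold exceeds 1.3 or falls below 0.7 (strict inequalities); hits are
confirmed when an independent second round reproduces the call in the
same direction.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import AcquisitionSpec, FieldImage
from .segmentation import segment_cells

__all__ = [
    "mean_intensity_per_cell",
    "field_fold_change",
    "pair_fold_change",
    "rank_and_call",
    "confirm_hits",
    "run_screen",
    "LowCoverageError",
    "SCREEN_RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Column order of the per-gene screen-result table.
SCREEN_RESULT_COLUMNS = [
    "gene",
    "n_cells_wt",
    "n_cells_mut",
    "mean_of_cell_means_wt",
    "mean_of_cell_means_mut",
    "fold_change",
    "rank",
    "primary_hit",
    "direction",
]


class LowCoverageError(ValueError):
    """Raised when a genotype has fewer cells than the coverage floor."""


def _project(volume: np.ndarray, projection: str) -> np.ndarray:
    volume = np.asarray(volume, dtype=float)
    if volume.ndim == 2:
        return volume
    if volume.ndim != 3:
        raise ValueError(f"expected 2D or 3D GFP data, got shape {volume.shape}")
    if projection == "max":
        return volume.max(axis=0)
    if projection == "sum":
        return volume.sum(axis=0)
    if projection == "mean":
        return volume.mean(axis=0)
    raise ValueError(f"unknown projection {projection!r}; use max, sum or mean")


def mean_intensity_per_cell(
    gfp_volume: np.ndarray,
    cell_labels: np.ndarray,
    projection: str = "max",
) -> pd.Series:
    """Mean projected GFP grey value over each cell's region of interest.

    The z-stack is compressed by ``projection`` (default maximum-intensity)
    and the mean pixel value inside each labeled region is returned as a
    Series indexed by cell label. Background (label 0) is excluded.
    """
    proj = _project(gfp_volume, projection)
    cell_labels = np.asarray(cell_labels)
    if proj.shape != cell_labels.shape:
        raise ValueError(
            f"label map {cell_labels.shape} does not match the GFP frame {proj.shape}"
        )
    ids = np.unique(cell_labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        return pd.Series(dtype=float, name="mean_gfp")
    means = ndimage.mean(proj, labels=cell_labels, index=ids)
    return pd.Series(means, index=pd.Index(ids, name="label"), name="mean_gfp")


def field_fold_change(
    per_cell_mut: Iterable[float],
    per_cell_wt: Iterable[float],
    min_cells: int = 35,
) -> float:
    """Mutant / wild-type ratio of the field averages of per-cell means.

    Both genotypes must reach ``min_cells`` cells (default 35, the
    screen's per-field acquisition floor); otherwise the gene is low
    coverage and excluded rather than scored.
    """
    mut = np.asarray(list(per_cell_mut), dtype=float)
    wt = np.asarray(list(per_cell_wt), dtype=float)
    if len(mut) < min_cells or len(wt) < min_cells:
        raise LowCoverageError(
            f"need at least {min_cells} cells per genotype, "
            f"got mutant={len(mut)}, WT={len(wt)}"
        )
    wt_mean = wt.mean()
    if wt_mean == 0:
        raise ValueError("WT mean intensity is zero; fold change undefined")
    return float(mut.mean() / wt_mean)


def pair_fold_change(
    mut_fields: list[Iterable[float]],
    wt_fields: list[Iterable[float]],
    min_cells: int = 35,
) -> float:
    """Fold change over paired fields: field k of the mutant is ratioed
    against field k of the wild type and the per-pair ratios averaged."""
    if len(mut_fields) != len(wt_fields) or not mut_fields:
        raise ValueError("need equal, nonzero numbers of mutant and WT fields")
    ratios = [
        field_fold_change(m, w, min_cells=min_cells)
        for m, w in zip(mut_fields, wt_fields)
    ]
    return float(np.mean(ratios))


def rank_and_call(
    fold_changes: Mapping[str, float],
    up_cut: float = 1.3,
    down_cut: float = 0.7,
    *,
    n_cells: Mapping[str, tuple[int, int]] | None = None,
    means: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Rank genes by fold change and call primary hits.

    Genes sort by fold change descending (rank 1 = largest increase),
    ties broken by gene name ascending. A gene is a primary hit when its
    fold change strictly exceeds ``up_cut`` (direction ``up``) or falls
    strictly below ``down_cut`` (direction ``down``); boundary values are
    not hits.
    """
    if up_cut <= down_cut:
        raise ValueError("up_cut must exceed down_cut")
    genes = list(fold_changes)
    fc = np.array([fold_changes[g] for g in genes], dtype=float)
    if not np.all(np.isfinite(fc)) or np.any(fc <= 0):
        bad = [g for g, v in zip(genes, fc) if not np.isfinite(v) or v <= 0]
        raise ValueError(f"fold changes must be finite and positive: {bad}")
    df = pd.DataFrame({"gene": genes, "fold_change": fc})
    if n_cells is not None:
        df["n_cells_wt"] = [n_cells[g][0] for g in genes]
        df["n_cells_mut"] = [n_cells[g][1] for g in genes]
    else:
        df["n_cells_wt"] = pd.NA
        df["n_cells_mut"] = pd.NA
    if means is not None:
        df["mean_of_cell_means_wt"] = [means[g][0] for g in genes]
        df["mean_of_cell_means_mut"] = [means[g][1] for g in genes]
    else:
        df["mean_of_cell_means_wt"] = np.nan
        df["mean_of_cell_means_mut"] = np.nan
    df = df.sort_values(
        ["fold_change", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["primary_hit"] = (df["fold_change"] > up_cut) | (df["fold_change"] < down_cut)
    df["direction"] = np.where(
        df["fold_change"] > up_cut, "up",
        np.where(df["fold_change"] < down_cut, "down", "none"),
    )
    return df[SCREEN_RESULT_COLUMNS]


def confirm_hits(primary: pd.DataFrame, second_round: pd.DataFrame) -> pd.DataFrame:
    """Confirm primary hits against an independent second round.

    A gene is confirmed when it is a primary hit in round one and a hit
    with the same direction in round two. Primary hits missing from the
    second round get ``confirmed = <NA>`` with a logged warning;
    non-hits get ``confirmed = False``.
    """
    second = second_round.set_index("gene")
    out = primary.copy()
    confirmed: list[object] = []
    for _, row in out.iterrows():
        if not row["primary_hit"]:
            confirmed.append(False)
            continue
        if row["gene"] not in second.index:
            logger.warning(
                "gene %s missing from confirmation round; confirmation unknown",
                row["gene"],
            )
            confirmed.append(pd.NA)
            continue
        s = second.loc[row["gene"]]
        confirmed.append(bool(s["primary_hit"]) and s["direction"] == row["direction"])
    out["confirmed"] = pd.array(confirmed, dtype="boolean")
    return out


def run_screen(
    dataset,
    spec: AcquisitionSpec | None = None,
    *,
    projection: str = "max",
    min_cells: int = 35,
    up_cut: float = 1.3,
    down_cut: float = 0.7,
    use_ground_truth_labels: bool = False,
    segment_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Measure and rank one full screen round from paired field sets.

    ``dataset`` iterates over :class:`~phenoscope.simulate.GenePair`
    records (or any object with ``gene``, ``wt`` and ``mut`` lists of
    ``(FieldImage, GroundTruth)`` pairs). Each field is segmented from
    its brightfield channel (or scored on its ground-truth footprint
    when ``use_ground_truth_labels``), per-cell mean GFP is taken on the
    ``projection``, and the paired-field fold change feeds
    :func:`rank_and_call`. Low-coverage genes are excluded with a log
    message.
    """
    segment_kwargs = segment_kwargs or {}
    folds: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    means: dict[str, tuple[float, float]] = {}
    for pair in dataset:
        per_geno: dict[str, list[np.ndarray]] = {"wt": [], "mut": []}
        for geno, fields in (("wt", pair.wt), ("mut", pair.mut)):
            for field, truth in fields:
                if use_ground_truth_labels:
                    labels = truth.cell_label_volume.max(axis=0)
                else:
                    field_spec = spec if spec is not None else field.spec
                    labels, table = segment_cells(
                        field["brightfield"], field_spec, **segment_kwargs
                    )
                    keep = np.zeros(labels.max() + 1, dtype=bool)
                    if len(table):
                        keep[table["label"].to_numpy()] = True
                    labels = np.where(keep[labels], labels, 0)
                cell_means = mean_intensity_per_cell(
                    field["gfp"], labels, projection=projection
                )
                per_geno[geno].append(cell_means.to_numpy())
        try:
            fold = pair_fold_change(
                per_geno["mut"], per_geno["wt"], min_cells=min_cells
            )
        except LowCoverageError as err:
            logger.warning("gene %s excluded: %s", pair.gene, err)
            continue
        folds[pair.gene] = fold
        counts[pair.gene] = (
            sum(len(v) for v in per_geno["wt"]),
            sum(len(v) for v in per_geno["mut"]),
        )
        means[pair.gene] = (
            float(np.mean(np.concatenate(per_geno["wt"]))),
            float(np.mean(np.concatenate(per_geno["mut"]))),
        )
    return rank_and_call(
        folds, up_cut=up_cut, down_cut=down_cut, n_cells=counts, means=means
    )
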