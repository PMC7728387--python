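"""Closed-form assay computations and shared hypothesis-test machinery.

Growth-curve doubling time (least-squares slope of log OD600 over the
3–7.5 h exponential window, reducing to Δt·log 2 / log(OD2/OD1) for two
points), ΔΔCt relative expression against a reference gene (TDH3 by
default), total-protein band normalization, WT-normalized readouts, and
the Welch t-test / one-way ANOVA + Tukey HSD used by every population
comparison in the pipeline.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "doubling_time",
    "delta_delta_ct",
    "normalize_to_total",
    "normalize_to_wt",
    "welch_t",
    "anova_tukey",
    "compare_groups",
    "NoGrowthError",
]


class NoGrowthError(ValueError):
    """Raised when the log-OD slope over the fit window is not positive."""


def doubling_time(
    times_h: Iterable[float],
    od600: Iterable[float],
    window: tuple[float, float] = (3.0, 7.5),
) -> float:
    """Culture doubling time in hours from an OD600 trajectory.

    ln(OD) is regressed on time by least squares over the closed
    ``window`` (hours), and the doubling time is ln 2 / slope. With
    exactly two in-window points this is algebraically the two-point
    formula Δt·log 2 / log(OD2/OD1) — the log base cancels in the ratio,
    so natural log is used throughout. Multiplying every OD reading by a
    positive constant leaves the result unchanged.
    """
    t = np.asarray(list(times_h), dtype=float)
    od = np.asarray(list(od600), dtype=float)
    if t.shape != od.shape:
        raise ValueError("times and OD readings must have equal length")
    if np.any(od <= 0):
        raise ValueError("OD600 readings must be strictly positive")
    in_window = (t >= window[0]) & (t <= window[1])
    if in_window.sum() < 2:
        raise ValueError(
            f"need at least 2 samples inside the {window} h window, "
            f"got {int(in_window.sum())}"
        )
    slope = np.polyfit(t[in_window], np.log(od[in_window]), 1)[0]
    if slope <= 0:
        raise NoGrowthError(
            f"log-OD slope {slope:.3g}/h is not positive: no growth in window"
        )
    return float(np.log(2.0) / slope)


def delta_delta_ct(
    table: pd.DataFrame,
    baseline_strain: str,
    target_gene: str,
    reference_gene: str = "TDH3",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the ΔΔCt method.

    ``table`` is long-form with columns ``strain, replicate, gene, ct``.
    Per replicate, ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the
    baseline strain's mean ΔCt, and relative expression is 2^−ΔΔCt
    (amplification efficiency fixed at 2). Adding a constant to every Ct
    value leaves the result unchanged. The baseline strain's geometric
    mean expression is 1 by construction.

    Returns ``(per_replicate, per_strain)`` DataFrames; the per-strain
    table carries the arithmetic mean and sd of replicate expressions.
    """
    required = {"strain", "replicate", "gene", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if not np.all(np.isfinite(table["ct"])):
        raise ValueError("Ct values must be finite")
    wide = table.pivot_table(
        index=["strain", "replicate"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValueError(
                f"gene {gene!r} missing (or incomplete) in the Ct table"
            )
    out = wide.reset_index()[["strain", "replicate"]].copy()
    out["delta_ct"] = (wide[target_gene] - wide[reference_gene]).to_numpy()
    if baseline_strain not in set(out["strain"]):
        raise ValueError(f"baseline strain {baseline_strain!r} not in table")
    baseline = out.loc[out["strain"] == baseline_strain, "delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - baseline
    out["relative_expression"] = 2.0 ** (-out["delta_delta_ct"])
    per_strain = (
        out.groupby("strain", sort=False)["relative_expression"]
        .agg(mean_expression="mean", sd_expression="std", n_replicates="size")
        .reset_index()
    )
    return out, per_strain


def normalize_to_total(
    band_intensity: Iterable[float], total_protein_signal: Iterable[float]
) -> np.ndarray:
    """Elementwise band ÷ total-protein ratio (loading normalization)."""
    band = np.asarray(list(band_intensity), dtype=float)
    total = np.asarray(list(total_protein_signal), dtype=float)
    if band.shape != total.shape:
        raise ValueError("band and total-protein arrays must have equal length")
    zero = np.nonzero(total == 0)[0]
    if len(zero):
        raise ValueError(f"total-protein signal is zero for lane(s) {zero.tolist()}")
    return band / total


def normalize_to_wt(
    values_per_strain: Mapping[str, Iterable[float]], wt_strain: str
) -> dict[str, np.ndarray]:
    """Express each strain's readouts as fold over the WT strain mean.

    The WT strain's mean becomes exactly 1; the ratios are invariant to
    sample ordering within a strain.
    """
    if wt_strain not in values_per_strain:
        raise ValueError(f"WT strain {wt_strain!r} not present")
    wt_mean = float(np.mean(np.asarray(list(values_per_strain[wt_strain]), float)))
    if wt_mean == 0:
        raise ValueError(f"WT strain {wt_strain!r} has zero mean; cannot normalize")
    return {
        strain: np.asarray(list(vals), dtype=float) / wt_mean
        for strain, vals in values_per_strain.items()
    }


def _validate_groups(groups: Mapping[str, Iterable[float]], min_groups: int):
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(arrays) < min_groups:
        raise ValueError(f"need at least {min_groups} groups, got {len(arrays)}")
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        if np.ptp(arr) == 0:
            raise ValueError(f"group {name!r} has zero variance")
    return arrays


def welch_t(groups: Mapping[str, Iterable[float]]) -> dict:
    """Welch's unequal-variance t-test for exactly two groups."""
    arrays = _validate_groups(groups, 2)
    if len(arrays) != 2:
        raise ValueError("welch_t compares exactly two groups")
    (name_a, a), (name_b, b) = arrays.items()
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "test": "welch_t",
        "groups": [name_a, name_b],
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": float(res.df),
        "significant": bool(res.pvalue < 0.05),
    }


def anova_tukey(groups: Mapping[str, Iterable[float]], alpha: float = 0.05) -> dict:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Returns the ANOVA F and p plus a table of all pairwise comparisons
    with Tukey-adjusted p-values at family-wise level ``alpha``.
    """
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
    names = list(arrays)
    f_stat, f_p = stats.f_oneway(*arrays.values())
    tk = stats.tukey_hsd(*arrays.values())
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": float(arrays[names[i]].mean() - arrays[names[j]].mean()),
                "p_adj": float(tk.pvalue[i, j]),
                "significant": bool(tk.pvalue[i, j] < alpha),
            }
        )
    return {
        "test": "anova_tukey",
        "F": float(f_stat),
        "p": float(f_p),
        "alpha": alpha,
        "pairwise": pd.DataFrame(rows),
    }


def compare_groups(groups: Mapping[str, Iterable[float]]) -> dict:
    """Dispatch: two groups → Welch t-test, more → ANOVA + Tukey HSD."""
    arrays = _validate_groups(groups, 2)
    if len(arrays) == 2:
        return welch_t(arrays)
    return anova_tukey(arrays)
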