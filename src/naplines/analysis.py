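"""Reaction-time statistics for the odd-one-out search task.

The pipeline follows standard practice for skewed RT data: summarize each
participant x condition x changed-variant cell by its median, then test
across participants.  Per condition, a one-tailed related-samples t-test
asks whether nonaccidental changes are detected faster than metric ones
(alternative: median_MP - median_NAP > 0), Bonferroni-corrected over the
13 conditions.  A 2x2 fully within-subject ANOVA contrasts the
nonaccidental advantage between two conditions; for a single-df
within-subject interaction, F equals the squared paired t on each
participant's difference of differences, which is how it is computed
here.  Finally, per-triplet behavioral advantages are correlated with the
GaborJet similarity asymmetry to ask how much of the behavior a V1-like
front end could explain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "compute_medians",
    "paired_t_one_tailed",
    "bonferroni_flags",
    "rm_interaction_2x2",
    "accuracy_summary",
    "rt_summary",
    "rt_diff_by_triplet",
    "model_behavior_correlation",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    tail: str  # "one" | "two"
    kind: str  # "paired_t" | "rm_interaction_F"
    label: str = ""
    alpha: float = float("nan")
    n_comparisons: int = 0
    significant_bonferroni: bool | None = None


def compute_medians(responses: pd.DataFrame, correct_only: bool = True
                    ) -> pd.DataFrame:
    """Median RT per participant x condition x changed-variant cell.

    Medians use the usual midpoint convention for even cell counts.
    Raises if any participant lacks (usable) trials in some cell.
    """
    df = responses[responses["correct"]] if correct_only else responses
    cells = (
        df.groupby(["participant", "condition", "variant_changed"],
                   observed=True)["rt"]
        .agg(median_rt="median", n_trials_used="count")
        .reset_index()
    )
    full = (
        responses.groupby(["participant", "condition", "variant_changed"],
                          observed=True)
        .size()
        .reset_index()[["participant", "condition", "variant_changed"]]
    )
    merged = full.merge(cells, how="left",
                        on=["participant", "condition", "variant_changed"])
    missing = merged[merged["median_rt"].isna()]
    if len(missing):
        row = missing.iloc[0]
        raise ValueError(
            "empty cell after filtering: participant "
            f"{row['participant']}, condition {row['condition']!r}, "
            f"variant {row['variant_changed']!r}"
        )
    return merged


def _paired_diffs(med: pd.DataFrame, condition: str) -> np.ndarray:
    sub = med[med["condition"] == condition]
    wide = sub.pivot(index="participant", columns="variant_changed",
                     values="median_rt")
    if wide.isna().any().any() or not {"metric", "nonaccidental"} <= set(wide):
        raise ValueError(f"incomplete cells for condition {condition!r}")
    return (wide["metric"] - wide["nonaccidental"]).to_numpy()


def _t_to_p_one_tailed(t: float, df: int) -> float:
    return float(stats.t.sf(t, df))


def paired_t_one_tailed(med: pd.DataFrame, condition: str) -> TestResult:
    """Related-samples t-test on median_MP - median_NAP per participant.

    One-tailed against the alternative that the mean difference is
    positive (nonaccidental changes detected faster).  Degenerate inputs:
    zero-variance nonzero differences give the limiting p (0 or 1);
    all-zero differences give t = 0, p = 0.5.
    """
    d = _paired_diffs(med, condition)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 participants with both cells")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, n - 1, 0.5, "one", "paired_t", condition)
        t = math.inf if mean > 0 else -math.inf
        return TestResult(t, n - 1, 0.0 if mean > 0 else 1.0, "one",
                          "paired_t", condition)
    t = mean / (sd / math.sqrt(n))
    return TestResult(float(t), n - 1, _t_to_p_one_tailed(t, n - 1), "one",
                      "paired_t", condition)


def bonferroni_flags(results: list[TestResult], alpha: float = 0.05,
                     n_comparisons: int = 13) -> list[TestResult]:
    """Flag results significant under the Bonferroni-corrected level.

    Strict inequality: p exactly at alpha/n_comparisons is not flagged.
    """
    if n_comparisons < len(results):
        raise ValueError("n_comparisons must cover all results")
    thresh = alpha / n_comparisons
    return [
        dc_replace(r, alpha=alpha, n_comparisons=n_comparisons,
                   significant_bonferroni=bool(r.p < thresh))
        for r in results
    ]


def rm_interaction_2x2(med: pd.DataFrame, condition_a: str, condition_b: str
                       ) -> TestResult:
    """Condition x distance-type interaction in a 2x2 within-subject design.

    Computed from each participant's difference of differences
    (A_MP - A_NAP) - (B_MP - B_NAP): the interaction F(1, n-1) is exactly
    the square of the paired t on those values; p is two-tailed.
    """
    da = _paired_diffs(med, condition_a)
    db = _paired_diffs(med, condition_b)
    if da.size != db.size:
        raise ValueError("conditions observed on different participant sets")
    dod = da - db
    n = dod.size
    sd = dod.std(ddof=1)
    if sd == 0.0:
        F = 0.0 if dod.mean() == 0.0 else math.inf
        p = 1.0 if dod.mean() == 0.0 else 0.0
        return TestResult(F, (1, n - 1), p, "two", "rm_interaction_F",
                          f"{condition_a} x {condition_b}")
    t = dod.mean() / (sd / math.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    return TestResult(float(F), (1, n - 1), p, "two", "rm_interaction_F",
                      f"{condition_a} x {condition_b}")


def accuracy_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy with binomial standard errors.

    Rows: each condition x changed-variant cell plus an "(all)" margin per
    variant.  Purely descriptive; the ceiling-level accuracies are not
    tested inferentially.
    """
    def _summarize(df: pd.DataFrame, condition: str, variant: str) -> dict:
        p = df["correct"].mean()
        n = len(df)
        return {
            "condition": condition,
            "variant_changed": variant,
            "accuracy": p,
            "se": math.sqrt(p * (1 - p) / n) if n else float("nan"),
            "n_trials": n,
        }

    rows = [
        _summarize(g, cond, v)
        for (cond, v), g in responses.groupby(
            ["condition", "variant_changed"], observed=True)
    ]
    rows += [
        _summarize(g, "(all)", v)
        for v, g in responses.groupby("variant_changed", observed=True)
    ]
    return pd.DataFrame(rows)


def rt_summary(med: pd.DataFrame) -> pd.DataFrame:
    """Across-participant mean of per-participant medians, with SEM.

    The condition x variant summary behind the usual bar-plot figure.
    """
    g = med.groupby(["condition", "variant_changed"], observed=True)["median_rt"]
    return g.agg(mean_median_rt="mean", sem="sem",
                 n_participants="count").reset_index()


def rt_diff_by_triplet(responses: pd.DataFrame, correct_only: bool = True
                       ) -> pd.DataFrame:
    """Per-triplet mean RT difference, nonaccidental minus metric (ms)."""
    df = responses[responses["correct"]] if correct_only else responses
    m = (
        df.groupby(["triplet_id", "variant_changed"], observed=True)["rt"]
        .mean()
        .unstack()
    )
    return pd.DataFrame(
        {"triplet_id": m.index,
         "rt_diff_nap_minus_mp": (m["nonaccidental"] - m["metric"]).to_numpy()}
    ).reset_index(drop=True)


def model_behavior_correlation(
    rt_by_triplet: pd.DataFrame,
    audit: pd.DataFrame,
    similarity_sign: str = "nap_minus_mp",
) -> tuple[float, float]:
    """Pearson correlation between behavioral and model asymmetries.

    Pairs each triplet's mean RT difference (NAP - MP) with its GaborJet
    similarity difference sim_nap_base - sim_mp_base (or the negated,
    dissimilarity-based convention).  Returns (r, two-tailed p).
    """
    merged = rt_by_triplet.merge(audit, on="triplet_id")
    x = (merged["sim_nap_base"] - merged["sim_mp_base"]).to_numpy()
    if similarity_sign == "mp_minus_nap":
        x = -x
    elif similarity_sign != "nap_minus_mp":
        raise ValueError(f"unknown similarity_sign {similarity_sign!r}")
    y = merged["rt_diff_nap_minus_mp"].to_numpy()
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
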