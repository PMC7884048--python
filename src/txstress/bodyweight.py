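"""Body-weight area-under-the-curve ledger.

The procedure takes weekly body weights from the intervention start through
the last week at which every group still has >= 80% Kaplan–Meier survival,
drops animals that died within that window, log10-transforms the weights,
expresses each animal relative to its own baseline, shifts everything by the
lowest baseline in the dataset (a pure display normalization with no effect
on group contrasts), integrates each animal's trajectory by the trapezoid
rule, screens the pooled AUC values once with a two-sided Grubbs test at
alpha = 0.01, and compares group means by Welch's unequal-variances t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import kaplan_meier

__all__ = [
    "auc_interval",
    "normalize_weights",
    "trapezoid_auc",
    "grubbs_critical_value",
    "grubbs_screen",
    "welch_compare",
    "auc_analysis",
    "AUCResult",
]


def _check_weights(weights: pd.DataFrame) -> None:
    for col in ("animal_id", "group", "week", "weight_g"):
        if col not in weights.columns:
            raise ValueError(f"weight table missing column {col!r}")
    if (weights["weight_g"] <= 0).any():
        raise ValueError("weights must be > 0")
    if weights.duplicated(["animal_id", "week"]).any():
        raise ValueError("at most one weight per animal-week")


def auc_interval(
    weights: pd.DataFrame, survival: pd.DataFrame, start_week: int
) -> int:
    """Largest week with >= 80% KM survival in *every* group.

    Scans integer weeks from ``start_week`` to the last observed weight week
    and returns the largest week w with KM S(w) >= 0.80 (inclusive at
    exactly 0.80) for all groups appearing in the weight table.
    """
    _check_weights(weights)
    groups = sorted(set(weights["group"]))
    missing = set(groups) - set(survival["group"])
    if missing:
        raise ValueError(f"groups without survival records: {sorted(missing)}")
    curves = {g: kaplan_meier(survival, g) for g in groups}
    last_week = int(weights["week"].max())
    end = None
    for w in range(int(start_week), last_week + 1):
        if all(curves[g].survival_at(w) >= 0.80 - 1e-12 for g in groups):
            end = w
        else:
            break
    if end is None:
        raise ValueError(
            f"no week >= {start_week} has >= 80% survival in every group"
        )
    return end


def normalize_weights(weights: pd.DataFrame, start_week: int) -> pd.DataFrame:
    """Log10 weights shifted by the global minimum baseline.

    Each value becomes ``log10(weight) - min over animals of
    log10(baseline)`` where an animal's baseline is its weight at
    ``start_week``.  Equivalent to subtracting the animal's own log10
    baseline and adding back its offset from the lowest baseline, so the
    normalization is a pure additive shift: within-animal differences and
    between-group contrasts are unchanged.  Animals with no start-week
    weight are excluded with a warning.

    Returns the weight table restricted to ``week >= start_week`` with an
    extra ``normalized`` column.
    """
    _check_weights(weights)
    base = weights[weights["week"] == start_week].set_index("animal_id")["weight_g"]
    animals = weights["animal_id"].unique()
    without = [a for a in animals if a not in base.index]
    if without:
        warnings.warn(
            f"excluding {len(without)} animal(s) without a week-{start_week} weight: "
            f"{without[:5]}",
            stacklevel=2,
        )
    keep = weights[
        weights["animal_id"].isin(base.index) & (weights["week"] >= start_week)
    ].copy()
    global_min = np.log10(base.min())
    keep["normalized"] = np.log10(keep["weight_g"]) - global_min
    return keep


def trapezoid_auc(weeks: np.ndarray, values: np.ndarray) -> float:
    """Trapezoid-rule AUC of one animal's series.

    Interior missing weeks are bridged by the trapezoid between the flanking
    observed weeks (linear interpolation).  Requires >= 2 observations.
    """
    weeks = np.asarray(weeks, dtype=float)
    values = np.asarray(values, dtype=float)
    if weeks.size < 2:
        raise ValueError("trapezoid AUC needs at least 2 observations")
    order = np.argsort(weeks)
    return float(np.trapezoid(values[order], weeks[order]))


def grubbs_critical_value(n: int, alpha: float = 0.01) -> float:
    """Two-sided single-outlier Grubbs critical value.

    ``((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2))`` with t the upper
    ``alpha/(2n)`` quantile of Student t with n-2 df.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


def grubbs_screen(
    values: np.ndarray, alpha: float = 0.01, ids: list | None = None
) -> list:
    """One-pass two-sided Grubbs screen; flags at most one value.

    ``G = max|x - mean| / sd`` is compared against
    :func:`grubbs_critical_value`; the test is applied once (no iteration),
    so at most one point is removed per experiment-wide application.
    Returns the flagged id list (indices when ``ids`` is None).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    if ids is None:
        ids = list(range(n))
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance; Grubbs screen flags nothing", stacklevel=2)
        return []
    dev = np.abs(x - x.mean())
    g = dev.max() / sd
    if g > grubbs_critical_value(n, alpha):
        return [ids[int(np.argmax(dev))]]
    return []


def welch_compare(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's unequal-variances t test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test needs >= 2 values per group")
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass(frozen=True)
class AUCResult:
    """Full ledger of one body-weight AUC comparison."""

    start_week: int
    end_week: int
    auc: pd.Series                      # per-animal AUC, log10-g * weeks
    groups: pd.Series                   # animal_id -> group
    excluded_died: list = field(default_factory=list)
    outliers_removed: list = field(default_factory=list)
    welch_t: float = float("nan")
    welch_df: float = float("nan")
    p_value: float = float("nan")


def auc_analysis(
    weights: pd.DataFrame,
    survival: pd.DataFrame,
    group_a: str,
    group_b: str,
    start_week: int,
    alpha: float = 0.01,
) -> AUCResult:
    """End-to-end body-weight AUC comparison of two groups.

    Determines the >= 80%-survival interval from all groups in the weight
    table, excludes animals that died within it, normalizes, integrates,
    Grubbs-screens the pooled AUCs once at ``alpha``, and Welch-compares the
    two requested groups.
    """
    end_week = auc_interval(weights, survival, start_week)

    died = survival[
        (survival["event"] == 1) & (survival["time_weeks"] <= end_week)
    ]["animal_id"].tolist()
    kept = weights[~weights["animal_id"].isin(died)]
    norm = normalize_weights(kept, start_week)
    norm = norm[norm["week"] <= end_week]

    aucs, groups = {}, {}
    for animal, block in norm.groupby("animal_id", sort=False):
        if len(block) < 2:
            warnings.warn(f"animal {animal!r} has < 2 observations; skipped", stacklevel=2)
            continue
        aucs[animal] = trapezoid_auc(block["week"].to_numpy(), block["normalized"].to_numpy())
        groups[animal] = block["group"].iloc[0]
    auc = pd.Series(aucs, name="auc")
    grp = pd.Series(groups, name="group")

    outliers = grubbs_screen(auc.to_numpy(), alpha=alpha, ids=auc.index.tolist())
    auc_clean = auc.drop(outliers)
    grp_clean = grp.drop(outliers)

    a = auc_clean[grp_clean == group_a].to_numpy()
    b = auc_clean[grp_clean == group_b].to_numpy()
    t, df, p = welch_compare(a, b)
    return AUCResult(
        start_week=start_week,
        end_week=end_week,
        auc=auc_clean,
        groups=grp_clean,
        excluded_died=died,
        outliers_removed=outliers,
        welch_t=t,
        welch_df=df,
        p_value=p,
    )
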