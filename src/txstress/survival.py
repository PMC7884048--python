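"""Time-to-event statistics for lifespan and phenotype-onset analyses.

Kaplan–Meier product-limit curves, the (optionally stratified) two-group
log-rank test with explicit observed/expected/variance bookkeeping, log
hazard-ratio effect sizes with 95% confidence intervals, and forest-table
assembly.

Conventions: times are in weeks and must be >= 0; ``event`` is 1 for an
observed event and 0 for censoring; deaths precede censorings at equal
recorded times (censored animals at time t are still at risk for the deaths
at t).  For onset-of-phenotype analyses the same machinery applies with the
phenotype onset as the event and death-before-onset coded as censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "HazardRatioResult",
    "kaplan_meier",
    "logrank",
    "log_hazard_ratio",
    "onset_analysis",
    "forest_assemble",
]

REQUIRED_COLUMNS = ("animal_id", "group", "time_weeks", "event")


def _check_table(table: pd.DataFrame) -> None:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if table["animal_id"].duplicated().any():
        dup = table.loc[table["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValueError(f"duplicate animal_id: {dup!r}")
    if (table["time_weeks"] < 0).any():
        raise ValueError("times must be >= 0")
    if not table["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival just after each distinct event time."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) after each event time
    n_at_risk: np.ndarray   # risk-set size just before each event time
    n_events: np.ndarray    # events at each event time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5 (nan if never reached)."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.times,
                "survival": self.survival,
                "n_at_risk": self.n_at_risk,
                "n_events": self.n_events,
            }
        )


def kaplan_meier(table: pd.DataFrame, group: str) -> KMCurve:
    """Kaplan–Meier curve for one group of a survival table."""
    _check_table(table)
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no records for group {group!r}")
    t = sub["time_weeks"].to_numpy(dtype=float)
    e = sub["event"].to_numpy(dtype=int)

    event_times = np.unique(t[e == 1])
    times, surv, risk, deaths = [], [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))  # censored at et still at risk
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        times.append(et)
        surv.append(s)
        risk.append(n_risk)
        deaths.append(d)
    return KMCurve(
        times=np.array(times, dtype=float),
        survival=np.array(surv, dtype=float),
        n_at_risk=np.array(risk, dtype=int),
        n_events=np.array(deaths, dtype=int),
    )


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank test with per-group O and E and total variance V."""

    chi2: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]
    variance: float
    stratified_by: str | None = None


def _oev(t: np.ndarray, e: np.ndarray, in_a: np.ndarray) -> tuple[float, float, float, float]:
    """Observed/expected events in group A and hypergeometric variance.

    At each distinct event time: ``E_A += d * nA/n`` and
    ``V += d * (nA/n) * (1 - nA/n) * (n - d)/(n - 1)``.
    """
    o_a = e_a = v = o_total = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((t == et) & (e == 1)).sum())
        d_a = int(((t == et) & (e == 1) & in_a).sum())
        o_a += d_a
        o_total += d
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1.0 - n_a / n) * (n - d) / (n - 1)
    return o_a, e_a, v, o_total


def logrank(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    strata: str | None = None,
) -> LogRankResult:
    """Two-group log-rank test, optionally stratified on a covariate column.

    When ``strata`` names a column (e.g. ``"sex"``), O−E and V are summed
    over strata; a stratum lacking either group is dropped with a warning.
    Zero total events gives chi2 = 0, p = 1 with a warning.
    """
    _check_table(table)
    sub = table[table["group"].isin([group_a, group_b])]
    for g in (group_a, group_b):
        if not (sub["group"] == g).any():
            raise ValueError(f"group not present: {g!r}")

    if strata is None:
        parts = [sub]
    else:
        if strata not in sub.columns:
            raise ValueError(f"stratum column not in table: {strata!r}")
        parts = []
        for value, block in sub.groupby(strata, sort=True):
            if (block["group"] == group_a).any() and (block["group"] == group_b).any():
                parts.append(block)
            else:
                warnings.warn(
                    f"stratum {strata}={value!r} lacks one group; dropped",
                    stacklevel=2,
                )
        if not parts:
            raise ValueError("no stratum contains both groups")

    o_a = e_a = v = o_tot = 0.0
    for block in parts:
        t = block["time_weeks"].to_numpy(dtype=float)
        e = block["event"].to_numpy(dtype=int)
        in_a = (block["group"] == group_a).to_numpy()
        oa, ea, vv, ot = _oev(t, e, in_a)
        o_a += oa
        e_a += ea
        v += vv
        o_tot += ot

    o_b = o_tot - o_a
    e_b = o_tot - e_a
    if o_tot == 0 or v == 0:
        warnings.warn("no events (or zero variance); log-rank p set to 1", stacklevel=2)
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(
        chi2=float(chi2),
        df=1,
        p_value=p,
        observed={group_a: o_a, group_b: o_b},
        expected={group_a: e_a, group_b: e_b},
        variance=float(v),
        stratified_by=strata,
    )


@dataclass(frozen=True)
class HazardRatioResult:
    """log(HR) of group A versus group B with normal-theory 95% CI.

    Negative values mean fewer events (protection) in the first-listed group.
    """

    log_hr: float
    se: float
    ci95: tuple[float, float]
    estimator: str

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo < hi:
            raise ValueError("confidence interval must have low < high")


def log_hazard_ratio(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    estimator: str = "mantel-haenszel",
    strata: str | None = None,
) -> HazardRatioResult:
    """Log hazard ratio of A vs B from log-rank O/E/V bookkeeping.

    mantel-haenszel: ``log_hr = ln((O_A/E_A)/(O_B/E_B))``,
    ``se = sqrt(1/E_A + 1/E_B)``.
    score: ``log_hr = (O_A - E_A)/V``, ``se = 1/sqrt(V)``.
    """
    if estimator not in ("mantel-haenszel", "score"):
        raise ValueError(f"unknown estimator: {estimator!r}")
    lr = logrank(table, group_a, group_b, strata=strata)
    o_a, o_b = lr.observed[group_a], lr.observed[group_b]
    e_a, e_b = lr.expected[group_a], lr.expected[group_b]
    if o_a == 0 or o_b == 0:
        raise ValueError("log hazard ratio undefined: a group has zero events")
    if estimator == "mantel-haenszel":
        log_hr = float(np.log((o_a / e_a) / (o_b / e_b)))
        se = float(np.sqrt(1.0 / e_a + 1.0 / e_b))
    else:
        log_hr = float((o_a - e_a) / lr.variance)
        se = float(1.0 / np.sqrt(lr.variance))
    return HazardRatioResult(
        log_hr=log_hr,
        se=se,
        ci95=(log_hr - 1.96 * se, log_hr + 1.96 * se),
        estimator=estimator,
    )


def onset_analysis(
    table: pd.DataFrame, group_a: str, group_b: str, strata: str | None = None
) -> tuple[dict[str, KMCurve], LogRankResult]:
    """KM curves and log-rank test for phenotype-onset tables.

    The table has survival-table semantics with phenotype onset (tremor,
    imbalance, kyphosis) as the event and death-before-onset coded censored.
    """
    curves = {g: kaplan_meier(table, g) for g in (group_a, group_b)}
    return curves, logrank(table, group_a, group_b, strata=strata)


def forest_assemble(
    results: Sequence[tuple[str, HazardRatioResult]]
) -> pd.DataFrame:
    """Ordered forest-plot table of labelled hazard-ratio results.

    Preserves input order and applies no numeric transformation.
    """
    if len(results) == 0:
        raise ValueError("no results to assemble")
    rows = [
        (label, r.log_hr, r.ci95[0], r.ci95[1], r.se, r.estimator)
        for label, r in results
    ]
    return pd.DataFrame(
        rows, columns=["label", "log_hr", "ci_low", "ci_high", "se", "estimator"]
    )
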