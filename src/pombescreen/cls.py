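"""Chronological-lifespan (CLS) analysis from colony-forming-unit counts.

Stationary-phase cultures are plated every day; colony-forming units (CFU)
normalised to the first assay day give percent viability, with day 0 defined
as 100% survival.  Conditions are compared with a grouped log-rank test
built from the CFU counts (day-to-day decrements as deaths, the previous
day's count as the at-risk number) and with the trapezoidal area under the
viability curve (AUC, percent x days) with a bootstrap confidence interval.

The log-rank chi-square statistic is the standard grouped (O - E)^2 / V form
with one degree of freedom.  Its default p-value, however, is computed by
permuting replicate labels between the two conditions (exact enumeration
when feasible, seeded Monte Carlo otherwise) rather than from the chi-square
tail: successive CFU counts are independent plating samples, so decrements
are overdispersed relative to the hypergeometric variance and the asymptotic
tail is grossly anticonservative.  The asymptotic p is still reported as
``p_asymptotic`` for comparison with conventional practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SurvivalSeries:
    """CFU counts per day for one condition, one row per replicate series."""

    condition: str
    days: np.ndarray
    cfu: np.ndarray  # shape (n_replicates, n_days)
    n_biological: int = 1
    n_technical: int | None = None

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cfu = np.atleast_2d(np.asarray(self.cfu, dtype=float))
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if self.cfu.shape[1] != self.days.size:
            raise ValueError(
                f"cfu has {self.cfu.shape[1]} day columns for {self.days.size} days"
            )
        if np.any(self.cfu < 0):
            raise ValueError("CFU counts must be >= 0")
        if self.n_technical is None:
            self.n_technical = self.cfu.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.cfu.shape[0]

    def viability(self) -> np.ndarray:
        """Percent viability per replicate, V_t = 100 * CFU_t / CFU_0.

        Replicates with CFU_0 = 0 are dropped with a warning; every retained
        replicate has V_0 = 100 by construction.
        """
        cfu0 = self.cfu[:, 0]
        keep = cfu0 > 0
        if not keep.all():
            warnings.warn(
                f"{self.condition}: dropping {int((~keep).sum())} replicate(s) with CFU_0 = 0",
                stacklevel=2,
            )
        if not keep.any():
            raise ValueError(f"{self.condition}: no replicate with CFU_0 > 0")
        return 100.0 * self.cfu[keep] / cfu0[keep, None]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: str | None = None) -> "SurvivalSeries":
        """Build from a tidy CFU table (condition, biological_rep,
        technical_rep, day, cfu)."""
        if condition is not None:
            df = df[df["condition"] == condition]
        elif df["condition"].nunique() != 1:
            raise ValueError("table holds several conditions; pass one explicitly")
        cond = str(df["condition"].iloc[0])
        wide = df.pivot_table(
            index=["biological_rep", "technical_rep"], columns="day", values="cfu"
        ).sort_index(axis=1)
        if wide.isna().any().any():
            raise ValueError(f"{cond}: missing CFU entries in the day grid")
        return cls(
            condition=cond,
            days=wide.columns.to_numpy(dtype=float),
            cfu=wide.to_numpy(dtype=float),
            n_biological=int(df["biological_rep"].nunique()),
            n_technical=int(df["technical_rep"].nunique()),
        )


def viability_curve(series: SurvivalSeries) -> pd.DataFrame:
    """Condition-level viability: per-day mean across replicates with dispersion."""
    v = series.viability()
    return pd.DataFrame(
        {
            "day": series.days,
            "mean_viability": v.mean(axis=0),
            "sd": v.std(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros(v.shape[1]),
            "n_replicates": v.shape[0],
        }
    )


# -- grouped log-rank -----------------------------------------------------


def _grouped_logrank(ca: np.ndarray, cb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised grouped log-rank pieces for count matrices (n, n_days).

    Returns (O1 - E1, V, O1) summed over days for each of the n rows; at-risk
    numbers are the previous day's counts, events the non-negative decrements.
    """
    ca = np.atleast_2d(ca)
    cb = np.atleast_2d(cb)
    n1 = ca[:, :-1]
    n2 = cb[:, :-1]
    e1 = np.clip(ca[:, :-1] - ca[:, 1:], 0, None)
    e2 = np.clip(cb[:, :-1] - cb[:, 1:], 0, None)
    d = e1 + e2
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n > 0, n1 / np.maximum(n, 1), 0.0)
        exp1 = d * p1
        var = d * p1 * np.where(n > 0, n2 / np.maximum(n, 1), 0.0)
        var *= np.where(n > 1, (n - d) / np.maximum(n - 1, 1), 0.0)
    return (e1 - exp1).sum(axis=1), var.sum(axis=1), e1.sum(axis=1)


def _pooled_counts(series: SurvivalSeries, days: np.ndarray, mode: str) -> np.ndarray:
    idx = [int(np.nonzero(series.days == d)[0][0]) for d in days]
    counts = series.cfu[:, idx]
    if mode == "mean":
        counts = counts.mean(axis=0, keepdims=True)
    return np.rint(counts)


@dataclass
class LogRankResult:
    """Grouped log-rank comparison of two CFU series."""

    chi_square: float
    p_value: float
    p_asymptotic: float
    observed: np.ndarray  # per-group event totals
    expected: np.ndarray  # per-group expected totals
    method: str
    n_permutations: int = 0
    flag: str = ""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"LogRankResult(chi_square={self.chi_square:.3f}, "
            f"p={self.p_value:.4g}, method={self.method!r})"
        )


def logrank_test(
    series_a: SurvivalSeries,
    series_b: SurvivalSeries,
    method: str = "auto",
    n_permutations: int = 10_000,
    seed: int | None = None,
    mode: str = "pooled",
) -> LogRankResult:
    """Grouped log-rank test between two conditions.

    ``method``: "auto" enumerates all replicate-label assignments when their
    number is at most ``n_permutations``, otherwise samples that many
    permutations; "permutation" forces Monte Carlo; "asymptotic" takes the
    chi-square tail.  ``mode="pooled"`` sums CFU over replicates (default);
    ``"mean"`` averages replicates first.
    """
    days = np.intersect1d(series_a.days, series_b.days)
    if days.size < 2:
        raise ValueError("need at least two shared days for a log-rank test")
    ra = _pooled_counts(series_a, days, mode)
    rb = _pooled_counts(series_b, days, mode)
    ca = ra.sum(axis=0, keepdims=True)
    cb = rb.sum(axis=0, keepdims=True)

    u, v, o1 = _grouped_logrank(ca, cb)
    u, v, o1 = float(u[0]), float(v[0]), float(o1[0])
    _, _, o2 = _grouped_logrank(cb, ca)
    o2 = float(o2[0])
    flag = ""
    if v <= 0:
        chi = 0.0
        flag = "no_events"
    else:
        chi = u * u / v
    p_asym = 1.0 if flag else float(stats.chi2.sf(chi, df=1))
    observed = np.array([o1, o2])
    expected = np.array([o1 - u, o2 + u])

    if method == "asymptotic" or flag:
        return LogRankResult(chi, p_asym, p_asym, observed, expected, "asymptotic", 0, flag)

    # permutation of replicate series between the two groups
    stacked = np.vstack([ra, rb])
    n_a, n_total = ra.shape[0], stacked.shape[0]
    if n_total < 3:
        warnings.warn("too few replicate series to permute; falling back to asymptotic p",
                      stacklevel=2)
        return LogRankResult(chi, p_asym, p_asym, observed, expected, "asymptotic", 0,
                             "too_few_replicates")
    n_exact = math.comb(n_total, n_a)
    if method == "auto" and n_exact <= n_permutations:
        assign = np.zeros((n_exact, n_total), dtype=bool)
        for i, combo in enumerate(combinations(range(n_total), n_a)):
            assign[i, list(combo)] = True
        used_method, n_used = "exact", n_exact
    else:
        rng = np.random.default_rng(seed)
        assign = np.zeros((n_permutations, n_total), dtype=bool)
        for i in range(n_permutations):
            assign[i, rng.choice(n_total, size=n_a, replace=False)] = True
        used_method, n_used = "permutation", n_permutations

    grp_a = assign.astype(float) @ stacked
    grp_b = (~assign).astype(float) @ stacked
    u_all, v_all, _ = _grouped_logrank(grp_a, grp_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_all = np.where(v_all > 0, u_all**2 / np.maximum(v_all, 1e-300), 0.0)
    tol = 1e-9 * max(1.0, abs(chi))  # float-rounding slack for re-summed counts
    if used_method == "exact":
        p = float((chi_all >= chi - tol).sum() / n_exact)
    else:
        p = float((1 + (chi_all >= chi - tol).sum()) / (1 + n_permutations))
    return LogRankResult(chi, p, p_asym, observed, expected, used_method, n_used, flag)


# -- AUC ------------------------------------------------------------------


@dataclass
class AucResult:
    """Trapezoidal AUC of the mean viability curve, percent x days."""

    auc: float
    ci_low: float
    ci_high: float
    n_boot: int


def survival_auc(
    series: SurvivalSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> AucResult:
    """Area under the mean viability curve with a bootstrap CI.

    Replicate series are resampled with replacement ``n_boot`` times; the CI
    is the central ``ci`` percentile interval of the resampled AUCs.
    """
    if series.days.size < 2:
        raise ValueError("AUC needs at least two time points")
    v = series.viability()
    auc = float(np.trapezoid(v.mean(axis=0), series.days))
    rng = np.random.default_rng(seed)
    n_rep = v.shape[0]
    idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
    boot = np.trapezoid(v[idx].mean(axis=1), series.days, axis=1)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    return AucResult(auc, float(lo), float(hi), n_boot)


def auc_difference(
    series_a: SurvivalSeries,
    series_b: SurvivalSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> tuple[float, float, float]:
    """Bootstrap difference AUC(a) - AUC(b) with a percentile CI."""
    va, vb = series_a.viability(), series_b.viability()
    rng = np.random.default_rng(seed)
    delta = float(
        np.trapezoid(va.mean(axis=0), series_a.days)
        - np.trapezoid(vb.mean(axis=0), series_b.days)
    )
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ia = rng.integers(0, va.shape[0], va.shape[0])
        ib = rng.integers(0, vb.shape[0], vb.shape[0])
        boots[i] = np.trapezoid(va[ia].mean(axis=0), series_a.days) - np.trapezoid(
            vb[ib].mean(axis=0), series_b.days
        )
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boots, [alpha, 1 - alpha])
    return delta, float(lo), float(hi)


def compare_lifespans(
    series_list: Sequence[SurvivalSeries],
    reference: str | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise log-rank and AUC contrasts against a reference condition.

    Returns one row per non-reference condition with the log-rank chi-square
    and p, both AUCs, and the bootstrap CI of the AUC difference.
    """
    if len(series_list) < 2:
        raise ValueError("need at least two conditions to compare")
    by_name = {s.condition: s for s in series_list}
    ref_name = reference if reference is not None else series_list[0].condition
    if ref_name not in by_name:
        raise ValueError(f"reference condition {ref_name!r} not among the series")
    ref = by_name[ref_name]
    ref_auc = survival_auc(ref, n_boot=n_boot, seed=seed)
    rows = []
    for s in series_list:
        if s.condition == ref_name:
            continue
        lr = logrank_test(ref, s, seed=seed)
        auc = survival_auc(s, n_boot=n_boot, seed=seed)
        delta, lo, hi = auc_difference(s, ref, n_boot=n_boot, seed=seed)
        rows.append(
            (
                s.condition,
                ref_name,
                lr.chi_square,
                lr.p_value,
                lr.p_asymptotic,
                auc.auc,
                ref_auc.auc,
                delta,
                lo,
                hi,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "reference",
            "chi_square",
            "p_value",
            "p_asymptotic",
            "auc",
            "auc_reference",
            "delta_auc",
            "delta_auc_ci_low",
            "delta_auc_ci_high",
        ],
    )


def plot_survival(series_list: Sequence[SurvivalSeries], ax=None):
    """Mean viability curves per condition with replicate scatter."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s in series_list:
        curve = viability_curve(s)
        ax.plot(curve["day"], curve["mean_viability"], marker="o", label=s.condition)
        ax.fill_between(
            curve["day"],
            curve["mean_viability"] - curve["sd"],
            curve["mean_viability"] + curve["sd"],
            alpha=0.2,
        )
    ax.set_xlabel("day")
    ax.set_ylabel("viability (%)")
    ax.legend()
    return ax
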