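"""Supporting micro-statistics: septation index, cell-size comparison and
relative qPCR quantification (ddCt).

Septation index is the percentage of cells showing a division septum among
~200 scored cells, a proxy for mitotic progression in fission yeast.  Cell
lengths at division (50-100 septated cells per group) are compared with the
two-sided Wilcoxon rank-sum (Mann-Whitney U) test.  qPCR fold changes use
the ddCt method with an alpha-tubulin reference gene (atb2 by default):
fold = 2^(-ddCt) where ddCt = dCt_treated - dCt_control and
dCt = Ct_target - Ct_reference per condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CellSample:
    """Scored cells for one condition/timepoint."""

    condition: str
    timepoint_min: float = 0.0
    septated_count: int = 0
    total_count: int = 0
    division_lengths: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.division_lengths = np.asarray(self.division_lengths, dtype=float)
        if not 0 <= self.septated_count <= self.total_count:
            raise ValueError(
                f"need 0 <= septated ({self.septated_count}) <= total ({self.total_count})"
            )
        if (self.division_lengths <= 0).any():
            raise ValueError("division lengths must be > 0")


def septation_index(sample: CellSample) -> tuple[float, float]:
    """Percent septated cells and its binomial standard error.

    SE = 100 * sqrt(p(1-p)/n) with p the septated fraction.
    """
    if sample.total_count < 1:
        raise ValueError("total_count must be >= 1")
    p = sample.septated_count / sample.total_count
    se = math.sqrt(p * (1 - p) / sample.total_count)
    return 100.0 * p, 100.0 * se


def wilcoxon_ranksum(
    lengths_a: Sequence[float], lengths_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test on two independent samples.

    Exact enumeration of rank assignments when n_a + n_b <= 12 and the pooled
    data are tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.  Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(lengths_a, dtype=float)
    b = np.asarray(lengths_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# -- qPCR -----------------------------------------------------------------


@dataclass
class QpcrMeasurement:
    """Triplicate Ct values for one gene in one condition."""

    gene: str
    condition: str
    ct_values: np.ndarray
    reference_gene: str = "atb2"

    def __post_init__(self) -> None:
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        if self.ct_values.size < 1:
            raise ValueError("need at least one Ct replicate")
        if (self.ct_values <= 0).any():
            raise ValueError("Ct values must be > 0")


@dataclass
class DdctResult:
    """ddCt fold change of a target gene, treated vs control."""

    gene: str
    fold: float
    ddct: float
    dct_treated: np.ndarray
    dct_control: np.ndarray
    se_log2: float
    t_stat: float
    p_value: float


def ddct_fold_change(
    target_treated: QpcrMeasurement,
    target_control: QpcrMeasurement,
    reference_treated: QpcrMeasurement,
    reference_control: QpcrMeasurement,
) -> DdctResult:
    """Relative expression by the ddCt method.

    Per-replicate dCt subtracts the mean reference Ct of the same condition;
    ddCt is the difference of mean dCt values and fold = 2^(-ddCt).
    Significance is a two-sided Welch t-test on the replicate dCt sets, and
    ``se_log2`` propagates both conditions' dCt dispersion on the log2 scale.
    """
    if target_treated.gene != target_control.gene:
        raise ValueError("target measurements are for different genes")
    for m, cond in ((target_treated, reference_treated), (target_control, reference_control)):
        if m.condition != cond.condition:
            raise ValueError(
                f"target ({m.condition}) and reference ({cond.condition}) conditions differ"
            )
    dct_t = target_treated.ct_values - reference_treated.ct_values.mean()
    dct_c = target_control.ct_values - reference_control.ct_values.mean()
    ddct = float(dct_t.mean() - dct_c.mean())
    fold = float(2.0 ** (-ddct))
    se = float(
        np.sqrt(
            (dct_t.var(ddof=1) / dct_t.size if dct_t.size > 1 else 0.0)
            + (dct_c.var(ddof=1) / dct_c.size if dct_c.size > 1 else 0.0)
        )
    )
    if dct_t.size > 1 and dct_c.size > 1:
        t_stat, p = stats.ttest_ind(dct_t, dct_c, equal_var=False)
    else:
        t_stat, p = float("nan"), float("nan")
    return DdctResult(
        gene=target_treated.gene,
        fold=fold,
        ddct=ddct,
        dct_treated=dct_t,
        dct_control=dct_c,
        se_log2=se,
        t_stat=float(t_stat),
        p_value=float(p),
    )


def ddct_from_table(
    ct: pd.DataFrame,
    gene: str,
    reference_gene: str = "atb2",
    treated: str = "treated",
    control: str = "control",
) -> DdctResult:
    """Convenience wrapper taking a tidy Ct table (gene, condition, replicate, ct)."""

    def measure(g: str, cond: str) -> QpcrMeasurement:
        sel = ct[(ct["gene"] == g) & (ct["condition"] == cond)]
        if sel.empty:
            raise ValueError(f"no Ct rows for gene={g!r}, condition={cond!r}")
        return QpcrMeasurement(g, cond, sel["ct"].to_numpy(), reference_gene)

    return ddct_fold_change(
        measure(gene, treated),
        measure(gene, control),
        measure(reference_gene, treated),
        measure(reference_gene, control),
    )
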