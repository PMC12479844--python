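"""Genome-wide fitness screening from colony arrays.

The chain: normalize every plate to its median, take the median over the
(up to four) replicate spots of each strain under treatment and on untreated
rich medium, form the fitness ratio

    f = median_treated / median_control,

and call a strain resistant when f > 1.35, sensitive when f < 0.65 (strict
inequalities), neutral otherwise.  Two screens are compared by the Pearson
correlation of their fitness ratios over shared strains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScreenConfig
from .plates import PlateGrid

LABELS = ("sensitive", "neutral", "resistant")


def plate_median_normalize(plate: PlateGrid) -> PlateGrid:
    """Divide every colony size by the plate median of non-missing sizes.

    The output plate has median exactly 1, which removes plate-to-plate scale
    (inoculum, incubation time, imaging) before strains are compared.
    """
    finite = np.isfinite(plate.sizes)
    if not finite.any():
        raise ValueError(f"plate {plate.plate_id}: all positions missing")
    med = float(np.nanmedian(plate.sizes))
    if med <= 0:
        raise ValueError(f"plate {plate.plate_id}: non-positive plate median {med}")
    return plate.with_sizes(plate.sizes / med)


def strain_median(
    plates: Sequence[PlateGrid],
    strain_id: str,
    condition: str | None = None,
    strategy: str = "pooled",
    missing_policy: str = "drop",
) -> tuple[float, int]:
    """Median colony size of one strain over its replicate spots.

    Returns ``(median, n_replicates_used)``; ``(nan, 0)`` when no usable
    replicate exists.  ``strategy="pooled"`` pools all spots across plates;
    ``"per-plate"`` takes per-plate medians first.  ``missing_policy="zero"``
    counts missing spots as zero-size colonies.
    """
    per_plate: list[np.ndarray] = []
    for plate in plates:
        if condition is not None and plate.condition != condition:
            continue
        vals = plate.strain_values(strain_id)
        if missing_policy == "zero":
            vals = np.nan_to_num(vals, nan=0.0)
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_plate.append(vals)
    if not per_plate:
        return float("nan"), 0
    n_used = int(sum(v.size for v in per_plate))
    if strategy == "per-plate":
        return float(np.median([np.median(v) for v in per_plate])), n_used
    return float(np.median(np.concatenate(per_plate))), n_used


def fitness_ratio(median_treated: float, median_control: float) -> float:
    """f = median_treated / median_control; NaN when the control median is 0."""
    if not median_control > 0:
        return float("nan")
    return float(median_treated) / float(median_control)


def classify_fitness(f: float, config: ScreenConfig | None = None) -> str:
    """Resistant above, sensitive below the cutoffs; strict inequalities."""
    config = config or ScreenConfig()
    if not np.isfinite(f) or f < 0:
        raise ValueError(f"fitness ratio must be finite and >= 0, got {f}")
    if f > config.resistant_cutoff:
        return "resistant"
    if f < config.sensitive_cutoff:
        return "sensitive"
    return "neutral"


def screen_fitness(
    treated: Sequence[PlateGrid],
    control: Sequence[PlateGrid],
    config: ScreenConfig | None = None,
    condition: str | None = None,
) -> pd.DataFrame:
    """Full screen: plates -> per-strain fitness records.

    Returns a tidy frame with columns strain_id, condition, median_treated,
    median_control, fitness_ratio, label, n_replicates_used, flag.  Strains
    without usable replicates or with a zero control median keep a row but
    carry a flag and no label; strains with fewer than two replicates on
    either arm are labelled but flagged ``low_confidence``.
    """
    config = config or ScreenConfig()
    if config.normalize_plates:
        treated = [plate_median_normalize(p) for p in treated]
        control = [plate_median_normalize(p) for p in control]
    cond = condition or (treated[0].condition if treated else "")

    strains: dict[str, None] = {}
    for plate in list(treated) + list(control):
        for s in plate.strains():
            strains.setdefault(s, None)

    rows = []
    for strain in strains:
        mt, nt = strain_median(
            treated, strain, strategy=config.replicate_strategy
        )
        mc, nc = strain_median(
            control,
            strain,
            strategy=config.replicate_strategy,
            missing_policy=config.control_missing_policy,
        )
        flag = ""
        label = ""
        f = float("nan")
        if nt == 0 or nc == 0:
            flag = "no_replicates"
        else:
            f = fitness_ratio(mt, mc)
            if not np.isfinite(f):
                flag = "zero_control"
            else:
                label = classify_fitness(f, config)
                if min(nt, nc) < 2:
                    flag = "low_confidence"
        rows.append((strain, cond, mt, mc, f, label, min(nt, nc), flag))
    return pd.DataFrame(
        rows,
        columns=[
            "strain_id",
            "condition",
            "median_treated",
            "median_control",
            "fitness_ratio",
            "label",
            "n_replicates_used",
            "flag",
        ],
    )


@dataclass
class ScreenComparison:
    """Pearson agreement of fitness ratios between two screens."""

    n_shared: int
    pearson_r: float
    p_value: float
    pairs: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScreenComparison(n_shared={self.n_shared}, "
            f"pearson_r={self.pearson_r:.3f})"
        )


def compare_screens(records_a: pd.DataFrame, records_b: pd.DataFrame) -> ScreenComparison:
    """Pearson correlation of fitness ratios over shared, finite strains."""
    a = records_a[["strain_id", "fitness_ratio"]].dropna()
    b = records_b[["strain_id", "fitness_ratio"]].dropna()
    merged = a.merge(b, on="strain_id", suffixes=("_a", "_b"))
    merged = merged[np.isfinite(merged["fitness_ratio_a"]) & np.isfinite(merged["fitness_ratio_b"])]
    if len(merged) < 3:
        raise ValueError(f"need >= 3 shared strains with finite ratios, got {len(merged)}")
    xa = merged["fitness_ratio_a"].to_numpy()
    xb = merged["fitness_ratio_b"].to_numpy()
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise ValueError("zero variance in one screen; correlation undefined")
    r, p = stats.pearsonr(xa, xb)
    return ScreenComparison(len(merged), float(r), float(p), merged)


def fitness_density(
    records: pd.DataFrame | Iterable[float],
    bw_method: float | str | None = None,
    gridsize: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of fitness ratios on an evaluation grid.

    Returns ``(grid, density)``; the density integrates to ~1 over the grid,
    which spans the data range padded by three bandwidths.
    """
    if isinstance(records, pd.DataFrame):
        values = records["fitness_ratio"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(records), dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 10:
        raise ValueError(f"need >= 10 finite ratios for a density, got {values.size}")
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    bw = np.sqrt(kde.covariance[0, 0])
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, gridsize)
    return grid, kde(grid)


def plot_fitness_density(
    records: pd.DataFrame,
    config: ScreenConfig | None = None,
    ax=None,
    **kde_kwargs,
):
    """Density of fitness ratios with the sensitive/resistant cutoff verticals."""
    import matplotlib.pyplot as plt

    config = config or ScreenConfig()
    grid, dens = fitness_density(records, **kde_kwargs)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(grid, dens)
    ax.axvline(config.sensitive_cutoff, linestyle=":", color="tab:blue")
    ax.axvline(config.resistant_cutoff, linestyle=":", color="tab:red")
    ax.set_xlabel("fitness ratio")
    ax.set_ylabel("density")
    return ax
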