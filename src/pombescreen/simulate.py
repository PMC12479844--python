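"""Synthetic experiments with known injected truth.

Every analysis stage in this package has a generator here that emulates its
input data — 1536-density colony arrays with quadruplicate spots, lognormal
colony noise, plate-level factors and separable row/column gradients; SGA
double-mutant arrays under a multiplicative fitness model with injected
interactions and a linkage-suppression band around the query locus;
Weibull-decay CFU time courses with Poisson plating noise; and Ct tables
with chosen fold changes.  Each generator returns a :class:`SyntheticTruth`
carrying exactly the parameters used, so recovery tests can compare pipeline
output against ground truth without any external data.

All generators are deterministic under a seed (numpy Generator).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import StrainAnnotation, annotation_map
from .cls import SurvivalSeries
from .plates import DENSITY_1536, LAYOUT_COLUMNS, PlateGrid

#: S. pombe chromosome lengths (bp), used as the default genome shape
POMBE_CHROMOSOMES = {"I": 5_579_133, "II": 4_539_804, "III": 2_452_883}

BASE_COLONY_PX = 400.0


@dataclass
class SyntheticTruth:
    """Ground truth injected by the generators.

    ``strain_effects`` are multiplicative treatment fitness effects (1 =
    neutral); ``sga_interactions`` are injected interaction multipliers
    (observed double size = expected x eps); ``linked_set`` /
    ``control_linked_set`` are the genes inside the linkage window of the
    query / control-query locus; ``cls_params`` holds per-condition Weibull
    scale/shape and n0; ``qpcr_folds`` the true expression fold changes.
    """

    strain_effects: dict = field(default_factory=dict)
    sga_interactions: dict = field(default_factory=dict)
    linked_set: set = field(default_factory=set)
    control_linked_set: set = field(default_factory=set)
    cls_params: dict = field(default_factory=dict)
    qpcr_folds: dict = field(default_factory=dict)
    query_id: str | None = None
    control_query_id: str | None = None
    seed: int | None = None

    @property
    def sensitive_set(self) -> set:
        return {s for s, e in self.strain_effects.items() if e < 1}

    @property
    def resistant_set(self) -> set:
        return {s for s, e in self.strain_effects.items() if e > 1}

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["linked_set"] = sorted(self.linked_set)
        d["control_linked_set"] = sorted(self.control_linked_set)
        Path(path).write_text(json.dumps(d, indent=2, default=str))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    if cv < 0:
        raise ValueError(f"noise CV must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


# -- genome ---------------------------------------------------------------


def gen_genome(
    n_genes: int,
    chromosome_lengths: dict[str, int] | None = None,
    seed: int | np.random.Generator | None = None,
    min_spacing: int = 1000,
) -> list[StrainAnnotation]:
    """Place ``n_genes`` at uniform positions across chromosomes.

    Genes are allocated to chromosomes proportionally to length (multinomial)
    and positioned on a ``min_spacing`` grid without collisions; coordinates
    are 1-based.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lengths = dict(chromosome_lengths or POMBE_CHROMOSOMES)
    rng = _rng(seed)
    slots = {c: max(length // min_spacing, 0) for c, length in lengths.items()}
    total_slots = sum(slots.values())
    if n_genes > total_slots:
        raise ValueError(
            f"{n_genes} genes do not fit in {total_slots} slots "
            f"(total length / min_spacing={min_spacing})"
        )
    total_len = sum(lengths.values())
    probs = np.array([lengths[c] / total_len for c in lengths])
    counts = rng.multinomial(n_genes, probs)
    # redistribute any chromosome overflow to spare capacity elsewhere
    counts = dict(zip(lengths, counts))
    spare = {c: slots[c] - counts[c] for c in lengths}
    for c in lengths:
        if spare[c] < 0:
            excess = -spare[c]
            counts[c] = slots[c]
            for other in lengths:
                if excess == 0:
                    break
                take = min(excess, max(spare[other], 0))
                counts[other] += take
                spare[other] -= take
                excess -= take

    records: list[tuple[str, int]] = []
    for chrom in lengths:
        k = counts[chrom]
        if k == 0:
            continue
        chosen = np.sort(rng.choice(slots[chrom], size=k, replace=False))
        for slot in chosen:
            records.append((chrom, int(slot) * min_spacing + 1))
    records.sort(key=lambda rc: (list(lengths).index(rc[0]), rc[1]))
    width = max(4, len(str(n_genes)))
    return [
        StrainAnnotation(f"SPG{i + 1:0{width}d}", chrom, pos)
        for i, (chrom, pos) in enumerate(records)
    ]


# -- colony-array layouts -------------------------------------------------


def quadruplicate_layouts(
    strain_ids: list[str], plate_prefix: str = "plate"
) -> dict[str, pd.DataFrame]:
    """Assign strains to 2x2 quadruplicate blocks on 32x48 plates.

    Standard 384 -> 1536 pinning: each plate carries 384 strains, each as
    four adjacent spots (replicates 1..4).
    """
    n_rows, n_cols = DENSITY_1536
    per_plate = (n_rows // 2) * (n_cols // 2)
    layouts: dict[str, pd.DataFrame] = {}
    for p, start in enumerate(range(0, len(strain_ids), per_plate), start=1):
        chunk = strain_ids[start : start + per_plate]
        rows = []
        for b, strain in enumerate(chunk):
            br, bc = divmod(b, n_cols // 2)
            for rep, (dr, dc) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)], start=1):
                rows.append((2 * br + 1 + dr, 2 * bc + 1 + dc, strain, rep))
        layouts[f"{plate_prefix}{p:02d}"] = pd.DataFrame(rows, columns=LAYOUT_COLUMNS)
    return layouts


def _render_plates(
    layouts: dict[str, pd.DataFrame],
    fitness: dict[str, float],
    rng: np.random.Generator,
    noise_cv: float,
    plate_effect_sd: float,
    rowcol_gradient: float,
    base_size: float,
    condition: str,
    missing_rate: float = 0.0,
) -> list[PlateGrid]:
    """Colony size = base x plate x row x col x fitness x lognormal noise.

    The row/column gradient is a deterministic function of plate geometry
    (same ramp for every arm rendered from the same layouts), emulating
    robot/incubator positional effects; the plate factor is drawn per plate.
    """
    n_rows, n_cols = DENSITY_1536
    xr = (np.arange(n_rows) / max(n_rows - 1, 1)) - 0.5
    xc = (np.arange(n_cols) / max(n_cols - 1, 1)) - 0.5
    row_f = np.exp(rowcol_gradient * xr)
    col_f = np.exp(-rowcol_gradient * xc)
    plates = []
    for plate_id, lay in layouts.items():
        plate_factor = float(_lognormal_noise(rng, plate_effect_sd, ()))
        sizes = np.full((n_rows, n_cols), np.nan)
        r = lay["row"].to_numpy(int) - 1
        c = lay["col"].to_numpy(int) - 1
        eff = np.array([fitness.get(s, 1.0) for s in lay["strain_id"]])
        noise = _lognormal_noise(rng, noise_cv, len(lay))
        sizes[r, c] = base_size * plate_factor * row_f[r] * col_f[c] * eff * noise
        if missing_rate > 0:
            drop = rng.random(len(lay)) < missing_rate
            sizes[r[drop], c[drop]] = np.nan
        plates.append(
            PlateGrid(plate_id=plate_id, sizes=sizes, layout=lay, condition=condition)
        )
    return plates


# -- library fitness screen -----------------------------------------------


def gen_library_screen(
    annotations: list[StrainAnnotation],
    frac_sensitive: float = 0.05,
    frac_resistant: float = 0.05,
    effect_size: float = 2.0,
    noise_cv: float = 0.15,
    plate_effect_sd: float = 0.10,
    rowcol_gradient: float = 0.05,
    missing_rate: float = 0.0,
    base_size: float = BASE_COLONY_PX,
    condition: str = "treated",
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PlateGrid], list[PlateGrid], SyntheticTruth]:
    """Treated and untreated copies of a deletion-library array.

    A chosen fraction of strains is made drug-sensitive (size multiplier
    1/effect_size on the treated arm) or resistant (multiplier effect_size);
    quadruplicate spots are drawn independently.
    """
    if frac_sensitive < 0 or frac_resistant < 0 or frac_sensitive + frac_resistant >= 1:
        raise ValueError("class fractions must be >= 0 and sum to < 1")
    if effect_size <= 0:
        raise ValueError("effect_size must be > 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    strains = [a.strain_id for a in annotations if a.viable]
    n = len(strains)
    n_sens = round(frac_sensitive * n)
    n_res = round(frac_resistant * n)
    chosen = rng.choice(n, size=n_sens + n_res, replace=False)
    effects = {s: 1.0 for s in strains}
    for i in chosen[:n_sens]:
        effects[strains[i]] = 1.0 / effect_size
    for i in chosen[n_sens:]:
        effects[strains[i]] = effect_size

    layouts = quadruplicate_layouts(strains)
    common = dict(
        rng=rng,
        noise_cv=noise_cv,
        plate_effect_sd=plate_effect_sd,
        rowcol_gradient=rowcol_gradient,
        base_size=base_size,
        missing_rate=missing_rate,
    )
    treated = _render_plates(layouts, effects, condition=condition, **common)
    control = _render_plates(layouts, {}, condition="YES", **common)
    truth = SyntheticTruth(strain_effects=effects)
    return treated, control, truth


# -- SGA ------------------------------------------------------------------


def gen_sga_experiment(
    annotations: list[StrainAnnotation],
    query_id: str,
    interactions: dict[str, float] | None = None,
    linkage_window: int = 30_000,
    linkage_eps: float = 0.05,
    control_query_id: str | None = None,
    query_fitness: float = 0.9,
    library_fitness_cv: float = 0.2,
    noise_cv: float = 0.1,
    plate_effect_sd: float = 0.05,
    rowcol_gradient: float = 0.0,
    base_size: float = BASE_COLONY_PX,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[PlateGrid], list[PlateGrid], SyntheticTruth]:
    """Query and control-query double-mutant arrays.

    Double-mutant size follows the multiplicative model
    single_library x single_query x eps: injected interactions set eps per
    gene on the query array; genes inside the linkage window of an array's
    own query locus get eps = ``linkage_eps`` (the artefactual negative band
    that quality control later removes).  The control query is neutral
    (fitness 1) with its own linkage zone at the control locus.
    """
    amap = annotation_map(annotations)
    if query_id not in amap:
        raise ValueError(f"query {query_id!r} not in annotations")
    interactions = dict(interactions or {})
    unknown = sorted(set(interactions) - set(amap))
    if unknown:
        raise ValueError(f"interactions specified for unannotated genes: {unknown[:5]}")
    if any(e <= 0 for e in interactions.values()) or linkage_eps <= 0:
        raise ValueError("interaction multipliers must be > 0")
    rng = _rng(seed)

    if control_query_id is None:
        q_chrom = amap[query_id].chromosome
        others = [a.strain_id for a in annotations if a.chromosome != q_chrom]
        if not others:
            raise ValueError("cannot pick a control query on a different chromosome")
        control_query_id = others[0]
    elif control_query_id not in amap:
        raise ValueError(f"control query {control_query_id!r} not in annotations")

    from .sga import linkage_filter  # local import avoids a cycle

    q_ann, c_ann = amap[query_id], amap[control_query_id]
    linked = linkage_filter(amap, (q_ann.chromosome, q_ann.position_bp), linkage_window)
    ctrl_linked = linkage_filter(amap, (c_ann.chromosome, c_ann.position_bp), linkage_window)

    strains = [a.strain_id for a in annotations if a.viable]
    lib_fitness = dict(zip(strains, _lognormal_noise(rng, library_fitness_cv, len(strains))))

    def eps_query(g: str) -> float:
        return linkage_eps if g in linked else interactions.get(g, 1.0)

    def eps_control(g: str) -> float:
        return linkage_eps if g in ctrl_linked else 1.0

    fit_query = {g: lib_fitness[g] * query_fitness * eps_query(g) for g in strains}
    fit_control = {g: lib_fitness[g] * eps_control(g) for g in strains}

    layouts = quadruplicate_layouts(strains)
    common = dict(
        rng=rng,
        noise_cv=noise_cv,
        plate_effect_sd=plate_effect_sd,
        rowcol_gradient=rowcol_gradient,
        base_size=base_size,
    )
    query_plates = _render_plates(layouts, fit_query, condition=f"{query_id}_sga", **common)
    control_plates = _render_plates(
        layouts, fit_control, condition=f"{control_query_id}_sga", **common
    )
    truth = SyntheticTruth(
        sga_interactions=interactions,
        linked_set=linked,
        control_linked_set=ctrl_linked,
        query_id=query_id,
        control_query_id=control_query_id,
    )
    return query_plates, control_plates, truth


# -- CLS ------------------------------------------------------------------


def gen_cls_experiment(
    n0: int = 500,
    days: np.ndarray | list[float] | None = None,
    lambda_by_condition: dict[str, float] | None = None,
    k: float | dict[str, float] = 2.0,
    n_technical: int = 3,
    n_biological: int = 2,
    seed: int | np.random.Generator | None = None,
) -> tuple[dict[str, SurvivalSeries], SyntheticTruth]:
    """Weibull-decay CFU time courses with Poisson plating noise.

    Expected CFU at day t is ``n0 * exp(-(t / lambda)^k)``; observed counts
    are Poisson around the expectation, independently per replicate series
    (``n_biological x n_technical`` series per condition).
    """
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    days = np.asarray(days if days is not None else np.arange(8), dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    lambda_by_condition = dict(lambda_by_condition or {"control": 3.0})
    rng = _rng(seed)
    series: dict[str, SurvivalSeries] = {}
    params: dict[str, dict] = {}
    for cond, lam in lambda_by_condition.items():
        kk = k[cond] if isinstance(k, dict) else k
        if lam <= 0 or kk <= 0:
            raise ValueError("Weibull scale and shape must be > 0")
        expected = n0 * np.exp(-((days / lam) ** kk))
        counts = rng.poisson(expected, size=(n_biological * n_technical, days.size))
        series[cond] = SurvivalSeries(
            condition=cond,
            days=days,
            cfu=counts.astype(float),
            n_biological=n_biological,
            n_technical=n_technical,
        )
        params[cond] = {"lambda_days": lam, "k": kk, "n0": n0}
    return series, SyntheticTruth(cls_params=params)


# -- qPCR -----------------------------------------------------------------


def gen_qpcr(
    genes: list[str] | tuple[str, ...] = ("agm1", "agm2", "agm3"),
    true_folds: dict[str, float] | None = None,
    ct_ref: float = 16.0,
    noise_sd: float = 0.1,
    n_triplicates: int = 3,
    reference_gene: str = "atb2",
    base_ct: float = 22.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Tidy Ct table (gene, condition, replicate, ct) with known fold changes.

    Treated target Ct = control Ct - log2(fold) + noise; the reference gene
    is constant across conditions up to noise.
    """
    if n_triplicates < 1:
        raise ValueError("n_triplicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    true_folds = dict(true_folds or {g: 1.0 for g in genes})
    if any(f <= 0 for f in true_folds.values()):
        raise ValueError("fold changes must be > 0")
    rng = _rng(seed)
    rows = []
    for i, gene in enumerate(genes):
        fold = true_folds.get(gene, 1.0)
        base = base_ct + 1.5 * i
        for rep in range(1, n_triplicates + 1):
            rows.append((gene, "control", rep, base + rng.normal(0, noise_sd)))
        for rep in range(1, n_triplicates + 1):
            rows.append(
                (gene, "treated", rep, base - np.log2(fold) + rng.normal(0, noise_sd))
            )
    for cond in ("control", "treated"):
        for rep in range(1, n_triplicates + 1):
            rows.append((reference_gene, cond, rep, ct_ref + rng.normal(0, noise_sd)))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return table, SyntheticTruth(qpcr_folds=true_folds)
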