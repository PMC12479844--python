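"""Synthetic genetic array (SGA) interaction scoring.

Double mutants between a query deletion and every library deletion are
pinned in quadruplicate; colony size proxies double-mutant fitness.  Under a
multiplicative null, the expected double-mutant fitness is the library
single-mutant fitness, which the control-query array (a neutral marker such
as ade6) measures directly.  The interaction score is

    I = score_scale * log10(median_query_double / median_control_double)

computed on plate-median- and row/column-normalized sizes: negative I means
the double mutant is less fit than expected (synthetic sick/lethal),
positive I better than expected (suppression/epistasis).  Quality control
removes library genes linked to either query locus (within 30 kb on the same
chromosome), genes with tiny control colonies (< 50 px raw), and genes with
high replicate variability; flagged genes carry no interaction label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import StrainAnnotation, annotation_map
from .config import ScreenConfig
from .plates import PlateGrid
from .screen import plate_median_normalize

QC_FLAGS = ("linked", "small_control", "high_variability", "insufficient_replicates", "unannotated")


@dataclass
class SGAExperiment:
    """One SGA: query-array plates, control-array plates and annotations."""

    query_id: str
    query_plates: Sequence[PlateGrid]
    control_plates: Sequence[PlateGrid]
    annotations: Mapping[str, StrainAnnotation]
    control_query_id: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.annotations, Mapping):
            self.annotations = annotation_map(self.annotations)
        if self.query_id not in self.annotations:
            raise ValueError(f"query {self.query_id!r} is not annotated")


# -- filters --------------------------------------------------------------


def linkage_filter(
    annotations: Mapping[str, StrainAnnotation] | Iterable[StrainAnnotation],
    query_position: tuple[str, int],
    window_bp: int = 30_000,
) -> set[str]:
    """Genes within ``window_bp`` (inclusive) of the query locus, same chromosome.

    Meiotic recombination cannot separate markers this close, so the double
    mutant never forms and the score is an artefact; these genes are excluded.
    """
    amap = annotations if isinstance(annotations, Mapping) else annotation_map(annotations)
    chrom, pos = query_position
    return {
        gene
        for gene, ann in amap.items()
        if ann.chromosome == chrom and abs(ann.position_bp - pos) <= window_bp
    }


def control_size_filter(
    control_medians: Mapping[str, float] | pd.Series,
    min_px: float = 50.0,
) -> set[str]:
    """Genes whose raw control-array median double-mutant size is < min_px.

    Such colonies carry too little material for a reliable interaction value;
    the boundary is strict (a median of exactly min_px is retained).
    """
    items = control_medians.items()
    return {gene for gene, med in items if np.isfinite(med) and med < min_px}


def replicate_cv(values: np.ndarray) -> float:
    """Coefficient of variation (sd/mean, ddof=1) of replicate spot sizes."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("inf")
    return float(values.std(ddof=1) / mean)


def variability_filter(values: np.ndarray, cv_max: float = 0.5) -> str:
    """QC outcome for one gene's replicate sizes: "", "high_variability"
    or "insufficient_replicates"."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        return "insufficient_replicates"
    if replicate_cv(values) > cv_max:
        return "high_variability"
    return ""


# -- normalization --------------------------------------------------------


def _axis_median_factors(sizes: np.ndarray, axis: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(sizes, axis=axis)
    empty = ~np.isfinite(med) | (med <= 0)
    if empty.any():
        which = "columns" if axis == 0 else "rows"
        warnings.warn(
            f"{int(empty.sum())} {which} entirely missing or non-positive; factor set to 1",
            stacklevel=3,
        )
        med = np.where(empty, 1.0, med)
    return med


def rowcol_normalize(
    plate: PlateGrid, method: str = "sequential", max_iter: int = 10, tol: float = 1e-9
) -> PlateGrid:
    """Remove row- and column-specific effects (pinning, drying gradients).

    ``sequential`` (default) divides by row medians, then by the column
    medians of the result; ``polish`` iterates the two steps until the
    factors converge (median polish in the multiplicative domain).  The
    output is re-centred so the plate median is 1.  A separable plate
    value = r(row) * c(col) becomes exactly constant.
    """
    sizes = plate.sizes.copy()
    if method not in ("sequential", "polish"):
        raise ValueError(f"unknown method {method!r}")
    n_iter = 1 if method == "sequential" else max_iter
    for _ in range(n_iter):
        row_med = _axis_median_factors(sizes, axis=1)
        sizes = sizes / row_med[:, None]
        col_med = _axis_median_factors(sizes, axis=0)
        sizes = sizes / col_med[None, :]
        if method == "polish" and (
            np.abs(np.log(row_med)).max() < tol and np.abs(np.log(col_med)).max() < tol
        ):
            break
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(sizes)
    if np.isfinite(med) and med > 0:
        sizes = sizes / med
    return plate.with_sizes(sizes)


# -- scoring --------------------------------------------------------------


def interaction_score(
    query_double_median: float,
    control_double_median: float,
    config: ScreenConfig | None = None,
) -> float:
    """I = score_scale * log10(query median / control median).

    Both medians come from the same normalization chain; the control-array
    median is the expected double-mutant fitness under no interaction.
    """
    config = config or ScreenConfig()
    if not (query_double_median > 0 and control_double_median > 0):
        raise ValueError(
            "both medians must be > 0; got "
            f"query={query_double_median}, control={control_double_median}"
        )
    return float(config.score_scale * np.log10(query_double_median / control_double_median))


def classify_interaction(score: float, config: ScreenConfig | None = None) -> str:
    """negative below -cutoff, positive above +cutoff, none otherwise."""
    config = config or ScreenConfig()
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score}")
    if score < -config.interaction_cutoff:
        return "negative"
    if score > config.interaction_cutoff:
        return "positive"
    return "none"


def _gene_values(plates: Sequence[PlateGrid]) -> dict[str, np.ndarray]:
    out: dict[str, list[np.ndarray]] = {}
    for plate in plates:
        lay = plate.layout
        vals = plate.sizes[lay["row"].to_numpy(int) - 1, lay["col"].to_numpy(int) - 1]
        for gene, v in zip(lay["strain_id"].to_numpy(), vals):
            out.setdefault(gene, []).append(v)
    return {g: np.asarray(v, dtype=float) for g, v in out.items()}


def _normalized(plates: Sequence[PlateGrid], rowcol_method: str) -> list[PlateGrid]:
    return [rowcol_normalize(plate_median_normalize(p), method=rowcol_method) for p in plates]


def score_sga(
    experiment: SGAExperiment,
    config: ScreenConfig | None = None,
    rowcol_method: str = "sequential",
) -> pd.DataFrame:
    """Run the full filter -> normalize -> score -> classify chain.

    Returns one row per library gene with columns library_gene, score, label,
    qc (semicolon-joined flags), replicate_cv, n_query_reps, n_control_reps,
    chromosome, position_bp.  Scores are reported for every gene with positive
    medians (so linkage artefacts remain visible in physical maps), but any
    flagged gene carries an empty label and is excluded from classification
    counts.
    """
    config = config or ScreenConfig()
    amap = experiment.annotations
    query_ann = amap[experiment.query_id]

    # raw control medians feed the small-colony filter (pixel units)
    raw_control = {
        g: float(np.nanmedian(v)) if np.isfinite(v).any() else float("nan")
        for g, v in _gene_values(experiment.control_plates).items()
    }
    small = control_size_filter(raw_control, config.min_control_colony_px)

    linked = linkage_filter(
        amap, (query_ann.chromosome, query_ann.position_bp), config.linkage_window_bp
    )
    if experiment.control_query_id is not None:
        ctrl_ann = amap[experiment.control_query_id]
        linked |= linkage_filter(
            amap, (ctrl_ann.chromosome, ctrl_ann.position_bp), config.linkage_window_bp
        )

    q_vals = _gene_values(_normalized(experiment.query_plates, rowcol_method))
    c_vals = _gene_values(_normalized(experiment.control_plates, rowcol_method))

    rows = []
    for gene in sorted(set(q_vals) | set(c_vals)):
        qv = q_vals.get(gene, np.array([]))
        cv = c_vals.get(gene, np.array([]))
        qv = qv[np.isfinite(qv)]
        cv = cv[np.isfinite(cv)]
        flags = []
        if gene not in amap:
            flags.append("unannotated")
        elif gene in linked:
            flags.append("linked")
        if gene in small:
            flags.append("small_control")
        # variability is judged per array; either arm too noisy flags the gene
        var_q = variability_filter(qv, config.cv_max)
        var_c = variability_filter(cv, config.cv_max)
        var_flag = var_q or var_c
        if var_flag:
            flags.append(var_flag)

        q_med = float(np.median(qv)) if qv.size else float("nan")
        c_med = float(np.median(cv)) if cv.size else float("nan")
        score = float("nan")
        if q_med > 0 and c_med > 0:
            score = interaction_score(q_med, c_med, config)
        elif not flags:
            flags.append("small_control" if not c_med > 0 else "insufficient_replicates")

        label = ""
        if not flags and np.isfinite(score):
            label = classify_interaction(score, config)

        ann = amap.get(gene)
        rows.append(
            (
                gene,
                score,
                label,
                ";".join(dict.fromkeys(flags)),
                replicate_cv(qv),
                qv.size,
                cv.size,
                ann.chromosome if ann else None,
                ann.position_bp if ann else pd.NA,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "library_gene",
            "score",
            "label",
            "qc",
            "replicate_cv",
            "n_query_reps",
            "n_control_reps",
            "chromosome",
            "position_bp",
        ],
    )


def interaction_counts(records: pd.DataFrame) -> dict[str, int]:
    """Counts of negative / none / positive among unflagged scored genes."""
    ok = records[(records["qc"] == "") & records["label"].isin(["negative", "none", "positive"])]
    return {
        "negative": int((ok["label"] == "negative").sum()),
        "none": int((ok["label"] == "none").sum()),
        "positive": int((ok["label"] == "positive").sum()),
        "scored": int(len(ok)),
    }


# -- physical mapping -----------------------------------------------------


@dataclass
class PhysicalMap:
    """Interaction scores ordered along the genome, with locus summaries."""

    track: pd.DataFrame
    loci: dict[str, tuple[str, int]]
    window_bp: int
    summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def physical_map(
    records: pd.DataFrame,
    annotations: Mapping[str, StrainAnnotation] | Iterable[StrainAnnotation],
    loci: Mapping[str, tuple[str, int]] | None = None,
    window_bp: int = 30_000,
) -> PhysicalMap:
    """Order scored genes by (chromosome, position) and summarise each locus.

    ``loci`` maps a name (e.g. the query and control-query genes) to a
    (chromosome, bp) position; the summary reports the mean score of genes
    inside vs outside ``window_bp`` of each locus.  An empty record list
    yields an empty track.
    """
    amap = annotations if isinstance(annotations, Mapping) else annotation_map(annotations)
    loci = dict(loci or {})
    track = records.copy()
    if "chromosome" not in track.columns or track["chromosome"].isna().all():
        track["chromosome"] = [
            amap[g].chromosome if g in amap else None for g in track["library_gene"]
        ]
        track["position_bp"] = [
            amap[g].position_bp if g in amap else pd.NA for g in track["library_gene"]
        ]
    track = track.dropna(subset=["chromosome", "position_bp"])
    track = track.sort_values(["chromosome", "position_bp"], kind="mergesort").reset_index(drop=True)

    rows = []
    scores = track["score"].to_numpy(dtype=float)
    for name, (chrom, pos) in loci.items():
        near = (
            (track["chromosome"] == chrom)
            & ((track["position_bp"].astype(np.int64) - pos).abs() <= window_bp)
        ).to_numpy()
        finite = np.isfinite(scores)
        inside = scores[near & finite]
        outside = scores[~near & finite]
        rows.append(
            (
                name,
                chrom,
                pos,
                inside.size,
                float(inside.mean()) if inside.size else float("nan"),
                float(outside.mean()) if outside.size else float("nan"),
            )
        )
    summary = pd.DataFrame(
        rows,
        columns=["locus", "chromosome", "position_bp", "n_within", "mean_within", "mean_outside"],
    )
    return PhysicalMap(track=track, loci=loci, window_bp=window_bp, summary=summary)
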