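"""Strain annotations: gene identity plus genome coordinate.

Coordinates are 1-based representative positions (e.g. the midpoint of the
deleted ORF); they drive the linkage-exclusion rule and physical mapping of
interaction scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class StrainAnnotation:
    """One library strain: systematic id, chromosome and coordinate."""

    strain_id: str
    chromosome: str
    position_bp: int
    viable: bool = True

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(
                f"position_bp must be >= 1 (1-based), got {self.position_bp} "
                f"for {self.strain_id}"
            )


def annotation_map(strains: Iterable[StrainAnnotation]) -> dict[str, StrainAnnotation]:
    """Index annotations by strain id, enforcing uniqueness."""
    out: dict[str, StrainAnnotation] = {}
    for s in strains:
        if s.strain_id in out:
            raise ValueError(f"duplicate strain_id in annotation set: {s.strain_id}")
        out[s.strain_id] = s
    return out


def read_annotations(path: str | Path) -> list[StrainAnnotation]:
    """Read a CSV with columns strain_id, chromosome, position_bp[, viable]."""
    df = pd.read_csv(path)
    required = {"strain_id", "chromosome", "position_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    viable = df["viable"].astype(bool) if "viable" in df.columns else [True] * len(df)
    return [
        StrainAnnotation(str(r.strain_id), str(r.chromosome), int(r.position_bp), bool(v))
        for r, v in zip(df.itertuples(index=False), viable)
    ]


def write_annotations(strains: Iterable[StrainAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(s.strain_id, s.chromosome, s.position_bp, s.viable) for s in strains],
        columns=["strain_id", "chromosome", "position_bp", "viable"],
    ).to_csv(path, index=False)


def attach_annotation(
    strains: Iterable[StrainAnnotation] | Mapping[str, StrainAnnotation],
    layout: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Resolve every strain id in a plate layout against an annotation set.

    Returns the layout with ``chromosome`` / ``position_bp`` columns attached
    (NaN where unresolved) and the sorted list of unannotated ids.  Unresolved
    ids are reported, never fatal.
    """
    amap = strains if isinstance(strains, Mapping) else annotation_map(strains)
    annotated = layout.copy()
    annotated["chromosome"] = [
        amap[s].chromosome if s in amap else None for s in annotated["strain_id"]
    ]
    annotated["position_bp"] = [
        amap[s].position_bp if s in amap else pd.NA for s in annotated["strain_id"]
    ]
    unannotated = sorted(set(annotated["strain_id"]) - set(amap))
    return annotated, unannotated
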