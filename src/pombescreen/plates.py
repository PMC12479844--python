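"""Colony-array plates.

A :class:`PlateGrid` holds one plate's colony sizes indexed by (row, col) —
1536 density is a 32 x 48 grid with each library strain pinned as four
adjacent spots — together with the layout mapping positions to
(strain, replicate).  Sizes are pixel areas from plate-image quantification
(gitter-style tables); missing colonies are NaN, never zero, because zero is
a legitimate measured size after a drug treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: grid dimensions at 1536-spot density
DENSITY_1536 = (32, 48)

LAYOUT_COLUMNS = ["row", "col", "strain_id", "replicate"]


@dataclass
class PlateGrid:
    """One plate: sizes per (row, col) plus the position -> strain layout.

    ``sizes`` is an ``(n_rows, n_cols)`` float array with NaN for missing
    positions; ``layout`` has columns row, col, strain_id, replicate with
    1-based row/col and replicate in 1..4.
    """

    plate_id: str
    n_rows: int = DENSITY_1536[0]
    n_cols: int = DENSITY_1536[1]
    sizes: np.ndarray = field(default=None)  # type: ignore[assignment]
    layout: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    condition: str = ""

    def __post_init__(self) -> None:
        if self.sizes is None:
            self.sizes = np.full((self.n_rows, self.n_cols), np.nan)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"sizes shape {self.sizes.shape} != grid ({self.n_rows}, {self.n_cols})"
            )
        finite = self.sizes[np.isfinite(self.sizes)]
        if (finite < 0).any():
            raise ValueError("colony sizes must be >= 0")
        if self.layout is None:
            self.layout = pd.DataFrame(columns=LAYOUT_COLUMNS)
        missing_cols = set(LAYOUT_COLUMNS) - set(self.layout.columns)
        if missing_cols:
            raise ValueError(f"layout lacks columns: {sorted(missing_cols)}")
        self._validate_layout()

    def _validate_layout(self) -> None:
        lay = self.layout
        if len(lay) == 0:
            return
        rows = lay["row"].to_numpy()
        cols = lay["col"].to_numpy()
        if ((rows < 1) | (rows > self.n_rows) | (cols < 1) | (cols > self.n_cols)).any():
            raise ValueError(f"layout positions outside {self.n_rows}x{self.n_cols} grid")
        if lay.duplicated(subset=["row", "col"]).any():
            dupes = lay[lay.duplicated(subset=["row", "col"], keep=False)]
            raise ValueError(
                "layout maps some positions to more than one strain: "
                f"{sorted(set(zip(dupes['row'], dupes['col'])))[:5]}"
            )
        reps = lay["replicate"].to_numpy()
        if not np.isin(reps, [1, 2, 3, 4]).all():
            raise ValueError("replicate index must be in {1, 2, 3, 4}")

    # -- convenience ------------------------------------------------------

    @property
    def n_missing(self) -> int:
        """Number of grid positions without a measured size."""
        return int(np.isnan(self.sizes).sum())

    def copy(self) -> "PlateGrid":
        return replace(self, sizes=self.sizes.copy(), layout=self.layout.copy())

    def with_sizes(self, sizes: np.ndarray) -> "PlateGrid":
        return replace(self, sizes=np.asarray(sizes, dtype=float), layout=self.layout)

    def strain_values(self, strain_id: str) -> np.ndarray:
        """Sizes at the positions of one strain (NaN kept for missing spots)."""
        sel = self.layout[self.layout["strain_id"] == strain_id]
        rows = sel["row"].to_numpy(dtype=int) - 1
        cols = sel["col"].to_numpy(dtype=int) - 1
        return self.sizes[rows, cols]

    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.layout["strain_id"]))


# -- colony tables (gitter-style row/col/size) ----------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".dat", ".tsv"} else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] == 1:  # wrong delimiter guess, try the other one
        df = pd.read_csv(path, sep="," if sep == "\t" else "\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_colony_table(
    path: str | Path,
    plate_id: str,
    layout: pd.DataFrame | None = None,
    n_rows: int = DENSITY_1536[0],
    n_cols: int = DENSITY_1536[1],
    condition: str = "",
) -> PlateGrid:
    """Read a per-colony table (columns row, col, size) into a PlateGrid.

    Duplicate or out-of-grid positions are hard errors.  Non-numeric sizes are
    record-level errors: the offending positions are reported in a warning and
    enter the grid as missing.
    """
    df = _read_table(path)
    required = {"row", "col", "size"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: colony table needs columns {sorted(required)}")
    rows = pd.to_numeric(df["row"], errors="raise").astype(int).to_numpy()
    cols = pd.to_numeric(df["col"], errors="raise").astype(int).to_numpy()
    if ((rows < 1) | (rows > n_rows) | (cols < 1) | (cols > n_cols)).any():
        bad = [(int(r), int(c)) for r, c in zip(rows, cols)
               if not (1 <= r <= n_rows and 1 <= c <= n_cols)]
        raise ValueError(f"{path}: positions outside {n_rows}x{n_cols} grid: {bad[:5]}")
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)]
    if len(set(pairs)) != len(pairs):
        seen: set = set()
        dupes = sorted({p for p in pairs if p in seen or seen.add(p)})
        raise ValueError(f"{path}: duplicate positions {dupes[:5]}")
    size = pd.to_numeric(df["size"], errors="coerce")
    bad_mask = size.isna() & df["size"].notna()
    if bad_mask.any():
        positions = [(int(r), int(c)) for r, c in zip(rows[bad_mask], cols[bad_mask])]
        warnings.warn(
            f"{path}: non-numeric size at positions {positions[:10]}; set to missing",
            stacklevel=2,
        )
    sizes = np.full((n_rows, n_cols), np.nan)
    sizes[rows - 1, cols - 1] = size.to_numpy(dtype=float)
    return PlateGrid(
        plate_id=plate_id,
        n_rows=n_rows,
        n_cols=n_cols,
        sizes=sizes,
        layout=layout,
        condition=condition,
    )


def write_colony_table(plate: PlateGrid, path: str | Path) -> None:
    """Write every measured position as one row/col/size record (TSV or CSV)."""
    rows, cols = np.nonzero(np.isfinite(plate.sizes))
    df = pd.DataFrame(
        {"row": rows + 1, "col": cols + 1, "size": plate.sizes[rows, cols]}
    )
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".dat", ".tsv"} else ","
    df.to_csv(path, sep=sep, index=False)


# -- layout maps ----------------------------------------------------------


def read_layouts(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a layout CSV (plate_id, row, col, strain_id, replicate) per plate."""
    df = pd.read_csv(path)
    required = {"plate_id", *LAYOUT_COLUMNS}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: layout needs columns {sorted(required)}")
    return {
        str(pid): g[LAYOUT_COLUMNS].reset_index(drop=True)
        for pid, g in df.groupby("plate_id", sort=False)
    }


def write_layouts(layouts: dict[str, pd.DataFrame], path: str | Path) -> None:
    parts = []
    for pid, lay in layouts.items():
        part = lay[LAYOUT_COLUMNS].copy()
        part.insert(0, "plate_id", pid)
        parts.append(part)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
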