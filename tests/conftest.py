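import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pombescreen import PlateGrid, ScreenConfig

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def config() -> ScreenConfig:
    return ScreenConfig()


def make_plate(sizes, plate_id="p1", condition="", strain_prefix="S") -> PlateGrid:
    """Small plate where every position carries its own strain (replicate 1)."""
    sizes = np.asarray(sizes, dtype=float)
    n_rows, n_cols = sizes.shape
    rows, cols = np.meshgrid(np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij")
    layout = pd.DataFrame(
        {
            "row": rows.ravel(),
            "col": cols.ravel(),
            "strain_id": [f"{strain_prefix}{r}_{c}" for r, c in zip(rows.ravel(), cols.ravel())],
            "replicate": 1,
        }
    )
    return PlateGrid(
        plate_id=plate_id, n_rows=n_rows, n_cols=n_cols, sizes=sizes,
        layout=layout, condition=condition,
    )


def quad_plate(values_by_strain, plate_id="p1", condition="") -> PlateGrid:
    """Plate holding each strain as four explicit replicate spots.

    ``values_by_strain`` maps strain -> sequence of 4 sizes (NaN allowed).
    """
    strains = list(values_by_strain)
    n_rows = 2 * ((len(strains) + 1) // 2)
    rows, layout_rows = np.full((max(n_rows, 2), 4), np.nan), []
    for i, strain in enumerate(strains):
        vals = values_by_strain[strain]
        for rep, (dr, dc) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)], start=1):
            r, c = 2 * (i // 2) + dr, 2 * (i % 2) + dc
            rows[r, c] = vals[rep - 1]
            layout_rows.append((r + 1, c + 1, strain, rep))
    layout = pd.DataFrame(layout_rows, columns=["row", "col", "strain_id", "replicate"])
    return PlateGrid(
        plate_id=plate_id, n_rows=rows.shape[0], n_cols=4, sizes=rows,
        layout=layout, condition=condition,
    )
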