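"""Abstract raster grid, nested administrative partition, and raster cubes.

The study geography is an abstract unit-cell grid: cells are indexed row-major
(0-based), distances are Euclidean between cell centers in cell units. Every
cell belongs to exactly one second-administrative unit (admin2), which nests in
admin1, country, and modelling region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GridSpec", "RasterCube", "default_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry plus the nested admin partition.

    ``region_of_cell`` .. ``admin2_of_cell`` are integer arrays of length
    ``n_cells`` mapping each cell to its unit id. Nesting (admin2 within
    admin1 within country within region) is validated on construction.
    """

    n_rows: int
    n_cols: int
    years: tuple
    region_of_cell: np.ndarray
    country_of_cell: np.ndarray
    admin1_of_cell: np.ndarray
    admin2_of_cell: np.ndarray

    def __post_init__(self):
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if len(self.years) < 1:
            raise ValueError("at least one year required")
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        n = self.n_cells
        for name in ("region_of_cell", "country_of_cell", "admin1_of_cell", "admin2_of_cell"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length n_cells={n}")
        # nesting: each child unit maps to exactly one parent
        for child, parent in (
            (self.admin2_of_cell, self.admin1_of_cell),
            (self.admin1_of_cell, self.country_of_cell),
            (self.country_of_cell, self.region_of_cell),
        ):
            df = pd.DataFrame({"c": child, "p": parent})
            if (df.groupby("c")["p"].nunique() > 1).any():
                raise ValueError("admin units must nest (child unit split across parents)")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_years(self) -> int:
        return len(self.years)

    def cell_coords(self) -> np.ndarray:
        """(n_cells, 2) array of cell-center coordinates in cell units."""
        r, c = np.divmod(np.arange(self.n_cells), self.n_cols)
        return np.column_stack([r, c]).astype(float)

    def cells_of(self, level: str, unit_id: int) -> np.ndarray:
        return np.flatnonzero(self.unit_map(level) == unit_id)

    def unit_map(self, level: str) -> np.ndarray:
        try:
            return getattr(self, f"{level}_of_cell")
        except AttributeError:
            raise ValueError(f"unknown admin level {level!r}") from None

    def units(self, level: str) -> np.ndarray:
        return np.unique(self.unit_map(level))

    def membership_table(self) -> pd.DataFrame:
        """Cell-membership table (``cell_id,admin2_id,admin1_id,country_id,region_id``)."""
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "admin2_id": self.admin2_of_cell,
                "admin1_id": self.admin1_of_cell,
                "country_id": self.country_of_cell,
                "region_id": self.region_of_cell,
            }
        )


def _block_partition(n_rows, n_cols, n_countries, n_regions):
    """Band countries over rows; quarter each country into admin1; quarter each
    admin1 into admin2. Returns the four cell->unit maps."""
    cell_r, cell_c = np.divmod(np.arange(n_rows * n_cols), n_cols)
    row_bands = np.array_split(np.arange(n_rows), n_countries)
    country = np.zeros(n_rows, dtype=int)
    for i, band in enumerate(row_bands):
        country[band] = i
    country_of_cell = country[cell_r]

    admin1_of_cell = np.zeros(n_rows * n_cols, dtype=int)
    admin2_of_cell = np.zeros(n_rows * n_cols, dtype=int)
    a1 = 0
    a2 = 0
    for i, band in enumerate(row_bands):
        sub_r = np.array_split(band, 2)
        sub_c = np.array_split(np.arange(n_cols), 2)
        for rr in sub_r:
            for cc in sub_c:
                mask1 = np.isin(cell_r, rr) & np.isin(cell_c, cc)
                admin1_of_cell[mask1] = a1
                # quarter the admin1 block into admin2 units
                for rrr in np.array_split(rr, 2):
                    for ccc in np.array_split(cc, 2):
                        mask2 = np.isin(cell_r, rrr) & np.isin(cell_c, ccc)
                        admin2_of_cell[mask2] = a2
                        a2 += 1
                a1 += 1
    region_of_country = np.zeros(n_countries, dtype=int)
    for j, grp in enumerate(np.array_split(np.arange(n_countries), n_regions)):
        region_of_country[grp] = j
    region_of_cell = region_of_country[country_of_cell]
    return region_of_cell, country_of_cell, admin1_of_cell, admin2_of_cell


def default_grid(
    n_rows: int = 30,
    n_cols: int = 30,
    years=(2000, 2001, 2002, 2003, 2004, 2005),
    n_countries: int = 3,
    n_regions: int = 2,
) -> GridSpec:
    """Default synthetic geography: countries banded over rows, each split into
    4 admin1 quadrants of 4 admin2 quadrants; countries grouped into regions."""
    if n_countries < n_regions:
        raise ValueError("need at least one country per region")
    reg, cty, a1, a2 = _block_partition(n_rows, n_cols, n_countries, n_regions)
    return GridSpec(n_rows, n_cols, tuple(years), reg, cty, a1, a2)


@dataclass
class RasterCube:
    """Gridded values indexed (layer, year, cell).

    ``values`` has shape ``(n_layers, n_years, n_cells)``; layer names are
    unique strings. Probability layers live in [0, 1]; population layers are
    nonnegative (enforced by generators, not the container).
    """

    values: np.ndarray
    layers: list
    grid: GridSpec
    missing: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.layers), self.grid.n_years, self.grid.n_cells)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if len(set(self.layers)) != len(self.layers):
            raise ValueError("layer names must be unique")

    def layer(self, name: str) -> np.ndarray:
        """(n_years, n_cells) view of one layer."""
        try:
            i = self.layers.index(name)
        except ValueError:
            raise KeyError(f"no layer {name!r}; have {self.layers}") from None
        return self.values[i]

    def year_index(self, year: int) -> int:
        try:
            return self.grid.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in grid years {self.grid.years}") from None
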