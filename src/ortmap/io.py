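"""Disk formats: multi-band TIFF rasters with JSON sidecars, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import GridSpec, RasterCube
from .synthworld import OBS_COLUMNS, validate_observations

__all__ = [
    "write_raster",
    "read_raster",
    "write_observations",
    "read_observations",
    "write_membership",
    "read_grid",
]


def write_raster(path, cube: RasterCube) -> None:
    """One TIFF band per (layer, year), with a JSON sidecar naming bands and
    recording the grid geometry and admin partition."""
    path = Path(path)
    grid = cube.grid
    bands = cube.values.reshape(-1, 1).reshape(
        len(cube.layers) * grid.n_years, grid.n_rows, grid.n_cols
    )
    tifffile.imwrite(path, bands.astype(np.float32), photometric="minisblack")
    sidecar = {
        "bands": [
            {"index": i * grid.n_years + t, "layer": layer, "year": int(year)}
            for i, layer in enumerate(cube.layers)
            for t, year in enumerate(grid.years)
        ],
        "grid": {
            "n_rows": grid.n_rows,
            "n_cols": grid.n_cols,
            "years": list(grid.years),
            "region_of_cell": grid.region_of_cell.tolist(),
            "country_of_cell": grid.country_of_cell.tolist(),
            "admin1_of_cell": grid.admin1_of_cell.tolist(),
            "admin2_of_cell": grid.admin2_of_cell.tolist(),
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_grid(sidecar: dict) -> GridSpec:
    g = sidecar["grid"]
    return GridSpec(
        g["n_rows"],
        g["n_cols"],
        tuple(g["years"]),
        np.asarray(g["region_of_cell"]),
        np.asarray(g["country_of_cell"]),
        np.asarray(g["admin1_of_cell"]),
        np.asarray(g["admin2_of_cell"]),
    )


def read_raster(path) -> RasterCube:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = read_grid(sidecar)
    bands = tifffile.imread(path).astype(float)
    layers = []
    for b in sidecar["bands"]:
        if b["layer"] not in layers:
            layers.append(b["layer"])
    values = bands.reshape(len(layers), grid.n_years, grid.n_cells)
    return RasterCube(values, layers, grid)


def write_observations(path, obs: pd.DataFrame) -> None:
    validate_observations(obs)
    obs[OBS_COLUMNS].to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    obs = pd.read_csv(path)
    validate_observations(obs)
    return obs


def write_membership(path, grid: GridSpec) -> None:
    grid.membership_table().to_csv(path, index=False)
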