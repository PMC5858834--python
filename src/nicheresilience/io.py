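"""Raster and table readers/writers.

Single-band rasters are written as TIFF files carrying the standard GeoTIFF
georeference tags — ModelPixelScale (33550), ModelTiepoint (33922) and the
GDAL nodata tag (42113) — plus a JSON ImageDescription holding the CRS
label. Climate and suitability layers are float32, state grids uint8
(nodata 255), resilience maps uint16 (nodata 65535). Integer data
round-trips bit-exactly; float32 to 32-bit precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import MISSING, PREDICTORS, AlignmentError, ClimateGrid, GridTransform, StateGrid
from .classify import OCCURRENCE_COLUMNS

__all__ = [
    "read_raster",
    "write_raster",
    "write_climate_grid",
    "read_climate_grid",
    "write_state_grid",
    "read_state_grid",
    "write_occurrence_table",
    "read_occurrence_table",
    "load_yaml",
    "dump_yaml",
]

_STATE_NODATA = int(MISSING)
_RESILIENCE_NODATA = 65535


def write_raster(
    path: str | Path,
    array: np.ndarray,
    transform: GridTransform,
    crs_label: str = "EPSG:4326",
    nodata: float | int | None = None,
) -> Path:
    """Write a single-band georeferenced TIFF."""
    path = Path(path)
    array = np.asarray(array)
    desc = json.dumps({"crs": crs_label})
    extratags = [
        (33550, "d", 3, (transform.dx, transform.dy, 0.0)),  # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, transform.x0, transform.y0, 0.0)),  # ModelTiepoint
    ]
    if nodata is not None:
        extratags.append((42113, "s", 0, str(nodata)))  # GDAL_NODATA
    tifffile.imwrite(path, array, description=desc, extratags=extratags)
    return path


def read_raster(path: str | Path) -> tuple[np.ndarray, GridTransform, str, float | None]:
    """Read a single-band TIFF written by :func:`write_raster`.

    Returns (array, transform, crs_label, nodata).
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        array = page.asarray()
        tags = page.tags
        scale = tags[33550].value if 33550 in tags else (1.0, 1.0, 0.0)
        tiepoint = tags[33922].value if 33922 in tags else (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        nodata = float(tags[42113].value) if 42113 in tags else None
        crs = "unknown"
        if 270 in tags:
            try:
                crs = json.loads(tags[270].value).get("crs", "unknown")
            except (json.JSONDecodeError, AttributeError):
                pass
    transform = GridTransform(x0=tiepoint[3], y0=tiepoint[4], dx=scale[0], dy=scale[1])
    return array, transform, crs, nodata


def write_climate_grid(climate: ClimateGrid, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for p in PREDICTORS:
        layer = climate.layers[p].astype(np.float32)
        layer = np.where(climate.nodata_mask, np.float32(np.nan), layer)
        paths[p] = write_raster(outdir / f"climate_{p}.tif", layer, climate.transform, climate.crs_label)
    return paths


def read_climate_grid(outdir: str | Path) -> ClimateGrid:
    outdir = Path(outdir)
    layers, transforms, crss = {}, [], []
    for p in PREDICTORS:
        arr, t, crs, _ = read_raster(outdir / f"climate_{p}.tif")
        layers[p] = arr.astype(float)
        transforms.append(t)
        crss.append(crs)
    if len({t.to_tuple() for t in transforms}) != 1:
        raise AlignmentError("climate layers carry different georeferences")
    nodata_mask = np.isnan(layers[PREDICTORS[0]])
    return ClimateGrid(layers=layers, transform=transforms[0], crs_label=crss[0], nodata_mask=nodata_mask)


def write_state_grid(states: StateGrid, path: str | Path, crs_label: str = "EPSG:4326") -> Path:
    return write_raster(path, states.states.astype(np.uint8), states.transform, crs_label, nodata=_STATE_NODATA)


def read_state_grid(path: str | Path) -> StateGrid:
    arr, transform, _, _ = read_raster(path)
    return StateGrid(arr.astype(np.uint8), transform, provenance=[f"read from {path}"])


def write_occurrence_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, columns=list(OCCURRENCE_COLUMNS))
    return path


def read_occurrence_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(OCCURRENCE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"occurrence table is missing columns: {sorted(missing)}")
    return table


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path
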