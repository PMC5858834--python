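"""Core gridded containers: climate predictor stacks and stable-state grids.

The pipeline works on regular lon/lat grids with a half-open pixel model:
the transform origin is the outer corner of pixel (0, 0) and pixel centers
sit at ``origin + (index + 0.5) * pixel_size``. Latitude decreases with row
index, matching the usual north-up raster convention.

Stable states are encoded as small unsigned integers so they can round-trip
through uint8 rasters: 0 = grassland, 1 = savanna, 2 = forest, 255 = missing.
The integer order (grassland < savanna < forest) is also the fixed tie-break
order used everywhere a tie between states must be resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

# Predictor names, in canonical order. ACP: annual cumulative precipitation
# (mm/year); PSC: precipitation seasonality coefficient (%); AAT: average
# annual temperature (degC); ART: annual range of temperature (degC).
PREDICTORS: tuple[str, ...] = ("ACP", "PSC", "AAT", "ART")

PREDICTOR_UNITS: dict[str, str] = {
    "ACP": "mm/year",
    "PSC": "%",
    "AAT": "degC",
    "ART": "degC",
}

# Stable-state codes. Integer order doubles as the tie-break order.
GRASSLAND: int = 0
SAVANNA: int = 1
FOREST: int = 2
MISSING: int = 255

STATES: tuple[str, ...] = ("grassland", "savanna", "forest")
STATE_CODES: dict[str, int] = {"grassland": GRASSLAND, "savanna": SAVANNA, "forest": FOREST}
STATE_NAMES: dict[int, str] = {v: k for k, v in STATE_CODES.items()}


class AlignmentError(ValueError):
    """Raised when co-used grids disagree in shape or georeference."""


@dataclass(frozen=True)
class GridTransform:
    """Affine georeference for a north-up regular grid.

    ``x0, y0`` is the outer corner of pixel (0, 0); ``dx`` is pixel width in
    map units (longitude increases with column), ``dy`` is pixel height
    (latitude decreases with row).
    """

    x0: float = -80.0
    y0: float = 10.0
    dx: float = 0.05
    dy: float = 0.05

    def pixel_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.x0 + (np.asarray(col) + 0.5) * self.dx
        lat = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def to_tuple(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.dx, self.dy)

    @classmethod
    def from_tuple(cls, t) -> "GridTransform":
        return cls(*map(float, t))


@dataclass
class ClimateGrid:
    """Four co-registered bioclimatic predictor layers over one grid.

    ``layers`` maps predictor name -> 2D float array in physical units;
    ``nodata_mask`` is True where the grid carries no data (shared by all
    layers).
    """

    layers: Mapping[str, np.ndarray]
    transform: GridTransform = field(default_factory=GridTransform)
    crs_label: str = "EPSG:4326"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [p for p in PREDICTORS if p not in self.layers]
        if missing:
            raise ValueError(f"climate grid is missing predictor layer(s): {missing}")
        shapes = {p: np.asarray(self.layers[p]).shape for p in PREDICTORS}
        if len(set(shapes.values())) != 1:
            raise AlignmentError(f"predictor layers differ in shape: {shapes}")
        self.layers = {p: np.asarray(self.layers[p], dtype=float) for p in PREDICTORS}
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.shape:
                raise AlignmentError("nodata mask shape differs from layer shape")
        valid = ~self.nodata_mask
        if np.any(self.layers["ACP"][valid] < 0):
            raise ValueError("ACP (precipitation) must be non-negative on valid pixels")
        if np.any(self.layers["PSC"][valid] < 0):
            raise ValueError("PSC (seasonality) must be non-negative on valid pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.layers["ACP"]).shape

    def predictor_matrix(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Stack predictor values at (rows, cols) into an (n, 4) matrix."""
        return np.column_stack([self.layers[p][rows, cols] for p in PREDICTORS])


@dataclass
class StateGrid:
    """Per-pixel categorical stable state (grassland/savanna/forest/missing)."""

    states: np.ndarray
    transform: GridTransform = field(default_factory=GridTransform)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        allowed = {GRASSLAND, SAVANNA, FOREST, MISSING}
        found = set(np.unique(self.states).tolist())
        if not found <= allowed:
            raise ValueError(f"state grid contains codes outside {sorted(allowed)}: {sorted(found - allowed)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.states != MISSING

    def fractions(self) -> dict[str, float]:
        """Fraction of valid pixels in each state."""
        valid = self.valid_mask
        n = int(valid.sum())
        if n == 0:
            return {s: float("nan") for s in STATES}
        return {s: float(np.sum(self.states[valid] == STATE_CODES[s]) / n) for s in STATES}

    def copy(self) -> "StateGrid":
        return StateGrid(self.states.copy(), self.transform, list(self.provenance))


def check_aligned(*grids) -> None:
    """Raise AlignmentError unless all grids share shape and transform."""
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise AlignmentError(f"grids are not co-registered: shapes {shapes}")
    transforms = {getattr(g, "transform", None) for g in grids}
    transforms.discard(None)
    if len(transforms) > 1:
        raise AlignmentError(f"grids are not co-registered: transforms {transforms}")
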