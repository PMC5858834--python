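"""Climate-space exposure and adaptive-capacity metrics.

Resilience is projected out of geographic space into two-dimensional climate
planes — by default the moisture plane (ACP x PSC) and the energy plane
(AAT x ART). Presence observations are binned on the plane, each bin
carrying its occupancy count and the mean resilience sampled at those
presences. Against a user-supplied polygon of non-analog climate (the
direction observed and simulated trends point: drier, more seasonal,
hotter), two numerical metrics operationalize the vulnerability axes:

* polygon overlap — the fraction of an ecosystem's weight (occupancy, or
  occupancy weighted by resilience) whose bin centers fall inside the
  polygon; its complement is the ecosystem's exposure to non-analog
  conditions, since a climate moving into the polygon leaves behind the
  space the ecosystem occupies today;
* adaptive capacity — niche breadth: the span of bin centers keeping mean
  resilience at or above a threshold, plus the count of such bins.

These summaries, combined with the stress-resistance coefficient |b|, rank
ecosystems by vulnerability: higher |b|, higher exposure, and lower breadth
all push an ecosystem toward the vulnerable end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .classify import presence_rows
from .stress import ResilienceMap

logger = logging.getLogger(__name__)

__all__ = [
    "ClimateSpaceSurface",
    "NonAnalogPolygon",
    "MOISTURE_AXES",
    "ENERGY_AXES",
    "build_surface",
    "exposure_fraction",
    "niche_breadth",
    "compare_vulnerability",
    "default_nonanalog_polygon",
]

MOISTURE_AXES: tuple[str, str] = ("ACP", "PSC")
ENERGY_AXES: tuple[str, str] = ("AAT", "ART")


@dataclass
class ClimateSpaceSurface:
    """Binned resilience surface for one ecosystem on one climate plane."""

    ecosystem: str
    axis_x: str
    axis_y: str
    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    occupancy: np.ndarray  # (nx, ny) presence counts
    mean_resilience: np.ndarray  # (nx, ny), NaN where unoccupied

    @property
    def centers_x(self) -> np.ndarray:
        return (self.bin_edges_x[:-1] + self.bin_edges_x[1:]) / 2.0

    @property
    def centers_y(self) -> np.ndarray:
        return (self.bin_edges_y[:-1] + self.bin_edges_y[1:]) / 2.0


@dataclass(frozen=True)
class NonAnalogPolygon:
    """A simple polygon in a 2-D climate plane, in predictor units."""

    axis_x: str
    axis_y: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        if not self.shapely().is_valid:
            raise ValueError("polygon must be simple (non-self-intersecting)")

    def shapely(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)


def default_nonanalog_polygon(axes: tuple[str, str], climate_ranges: dict) -> NonAnalogPolygon:
    """An editable example polygon for the stated direction of change.

    Covers the quarter of the plane toward increased aridity/seasonality
    (moisture plane: low ACP, high PSC) or increased heat/annual range
    (energy plane: high AAT, high ART). A study would supply its own
    vertices; this default only encodes the trend direction.
    """
    (x_lo, x_hi) = climate_ranges[axes[0]]
    (y_lo, y_hi) = climate_ranges[axes[1]]
    x_mid, y_mid = (x_lo + x_hi) / 2.0, (y_lo + y_hi) / 2.0
    if axes == MOISTURE_AXES:  # arid and seasonal corner
        verts = ((x_lo, y_mid), (x_mid, y_mid), (x_mid, y_hi), (x_lo, y_hi))
    else:  # hot, wide annual range corner
        verts = ((x_mid, y_mid), (x_hi, y_mid), (x_hi, y_hi), (x_mid, y_hi))
    return NonAnalogPolygon(axes[0], axes[1], verts)


def build_surface(
    table: pd.DataFrame,
    resilience: ResilienceMap,
    ecosystem: str,
    axes: tuple[str, str] = MOISTURE_AXES,
    bins: tuple[int, int] = (50, 50),
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> ClimateSpaceSurface:
    """Bin presences on a climate plane with their mean resilience.

    ``ranges`` fixes the bin extents (useful to put several ecosystems on a
    common grid); by default the extents of this ecosystem's presences are
    used. Resilience is sampled at each presence pixel.
    """
    pres = presence_rows(table, ecosystem)
    if len(pres) == 0:
        raise ValueError(f"no presence rows for {ecosystem}")
    x = pres[axes[0]].to_numpy(dtype=float)
    y = pres[axes[1]].to_numpy(dtype=float)
    res = resilience.values[pres["row"].to_numpy(dtype=int), pres["col"].to_numpy(dtype=int)]
    if np.any(np.isnan(res)):
        raise ValueError("presence points fall on nodata resilience pixels")
    if ranges is None:
        ranges = ((x.min(), x.max()), (y.min(), y.max()))
    counts, ex, ey = np.histogram2d(x, y, bins=bins, range=ranges)
    weighted, _, _ = np.histogram2d(x, y, bins=[ex, ey], weights=res)
    mean = np.full(counts.shape, np.nan)
    occupied = counts > 0
    mean[occupied] = weighted[occupied] / counts[occupied]
    return ClimateSpaceSurface(
        ecosystem=ecosystem,
        axis_x=axes[0],
        axis_y=axes[1],
        bin_edges_x=ex,
        bin_edges_y=ey,
        occupancy=counts.astype(int),
        mean_resilience=mean,
    )


def exposure_fraction(
    surface: ClimateSpaceSurface, polygon: NonAnalogPolygon, weight: str = "occupancy"
) -> float:
    """Fraction of the surface's weight inside the non-analog polygon.

    Bins are represented by their centers; centers on the polygon edge
    count as inside. ``weight`` is "occupancy" (presence counts) or
    "resilience" (occupancy x mean resilience).
    """
    if (polygon.axis_x, polygon.axis_y) != (surface.axis_x, surface.axis_y):
        raise ValueError(
            f"polygon axes ({polygon.axis_x}, {polygon.axis_y}) do not match "
            f"surface axes ({surface.axis_x}, {surface.axis_y})"
        )
    if weight == "occupancy":
        w = surface.occupancy.astype(float)
    elif weight == "resilience":
        w = surface.occupancy * np.nan_to_num(surface.mean_resilience)
    else:
        raise ValueError("weight must be 'occupancy' or 'resilience'")
    total = w.sum()
    if total == 0:
        return 0.0
    cx, cy = np.meshgrid(surface.centers_x, surface.centers_y, indexing="ij")
    occupied = w > 0
    pts = shapely.points(cx[occupied], cy[occupied])
    inside = shapely.covers(polygon.shapely(), pts)  # covers: boundary counts as inside
    return float(w[occupied][inside].sum() / total)


def niche_breadth(surface: ClimateSpaceSurface, resilience_min: float = 500.0) -> dict:
    """Span of climate conditions holding resilience above a threshold.

    Over bins with occupancy > 0 and mean resilience >= ``resilience_min``,
    reports the span (max - min of bin centers) along each axis and the
    count of qualifying bins (an area proxy). Larger breadth means higher
    adaptive capacity. If no bin qualifies, breadth is 0 (with a warning).
    """
    ok = (surface.occupancy > 0) & (np.nan_to_num(surface.mean_resilience, nan=-1.0) >= resilience_min)
    if not np.any(ok):
        logger.warning(
            "%s: no bin reaches resilience >= %s; breadth is 0", surface.ecosystem, resilience_min
        )
        return {"span_x": 0.0, "span_y": 0.0, "n_bins": 0, "axis_x": surface.axis_x, "axis_y": surface.axis_y}
    cx, cy = np.meshgrid(surface.centers_x, surface.centers_y, indexing="ij")
    return {
        "span_x": float(cx[ok].max() - cx[ok].min()),
        "span_y": float(cy[ok].max() - cy[ok].min()),
        "n_bins": int(ok.sum()),
        "axis_x": surface.axis_x,
        "axis_y": surface.axis_y,
    }


def compare_vulnerability(
    surfaces: dict[str, ClimateSpaceSurface],
    polygon: NonAnalogPolygon,
    resilience_min: float = 500.0,
    resistance_b: dict[str, float] | None = None,
    weight: str = "occupancy",
) -> pd.DataFrame:
    """Combine the three vulnerability axes into a qualitative ranking.

    Per ecosystem: sensitivity (|b| from the stress-resistance fit),
    non-analog exposure, and adaptive capacity (niche-breadth bin count).
    The polygon marks where the climate is heading; an ecosystem whose
    occupied climate space barely overlaps it will be left behind by the
    moving climate, so its exposure to non-analog conditions is
    ``1 - exposure_fraction`` (the polygon-overlap fraction itself is also
    reported). Each axis is ranked with 1 = most vulnerable (highest |b|,
    highest non-analog exposure, lowest breadth); the vulnerability score is
    the mean of the available ranks, lower = more vulnerable. Missing
    components leave NaN gaps rather than failing.
    """
    rows = []
    for eco, surf in surfaces.items():
        breadth = niche_breadth(surf, resilience_min)
        overlap = exposure_fraction(surf, polygon, weight=weight)
        rows.append(
            {
                "ecosystem": eco,
                "abs_b": abs(resistance_b[eco]) if resistance_b and eco in resistance_b else np.nan,
                "polygon_overlap": overlap,
                "nonanalog_exposure": 1.0 - overlap,
                "breadth_bins": breadth["n_bins"],
                "breadth_span_x": breadth["span_x"],
                "breadth_span_y": breadth["span_y"],
            }
        )
    df = pd.DataFrame(rows)
    df["rank_sensitivity"] = df["abs_b"].rank(ascending=False, method="min")
    df["rank_exposure"] = df["nonanalog_exposure"].rank(ascending=False, method="min")
    df["rank_capacity"] = df["breadth_bins"].rank(ascending=True, method="min")
    df["vulnerability_score"] = df[["rank_sensitivity", "rank_exposure", "rank_capacity"]].mean(
        axis=1, skipna=True
    )
    df = df.sort_values("vulnerability_score", kind="stable").reset_index(drop=True)
    df["tied"] = df.duplicated("vulnerability_score", keep=False)
    return df
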