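"""Stable-state classification of tree-cover rasters and occurrence tables.

Tree cover (0-100%) is partitioned into three stable-state bands —
grassland [0, 5], savanna (5, 60], forest (60, 100] — following the modes of
the trimodal tree-cover frequency distribution. A one-directional consensus
rule repairs land-use corruption: a pixel classified below the forest
threshold but labeled forest by an independent consensus land-cover product
is reclassified to forest. Grids can be coarsened by block-majority
resampling, and classified grids are converted into mutually exclusive
presence-absence point tables for niche modeling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import (
    FOREST,
    GRASSLAND,
    MISSING,
    PREDICTORS,
    SAVANNA,
    STATES,
    STATE_CODES,
    ClimateGrid,
    GridTransform,
    StateGrid,
    check_aligned,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OCCURRENCE_COLUMNS",
    "classify_tree_cover",
    "reclassify_with_consensus",
    "resample_majority",
    "build_occurrence_table",
    "presence_rows",
]

#: Fixed column order of the occurrence table (also the CSV header).
OCCURRENCE_COLUMNS: tuple[str, ...] = (
    "lon",
    "lat",
    "row",
    "col",
    *PREDICTORS,
    "present_grassland",
    "present_savanna",
    "present_forest",
)


def classify_tree_cover(
    tree_cover: np.ndarray,
    transform: GridTransform | None = None,
    grassland_max: float = 5.0,
    forest_min: float = 60.0,
) -> StateGrid:
    """Partition tree cover into stable-state bands.

    Defaults follow the study bands: cover in [0, ``grassland_max``] is
    grassland, (``grassland_max``, ``forest_min``] savanna, and values
    strictly above ``forest_min`` forest (so cover exactly 60 is savanna).
    NaN encodes nodata and maps to missing. Thresholds are configurable but
    must satisfy 0 < grassland_max < forest_min < 100 so the three bands
    tile [0, 100] with no gap or overlap.
    """
    if not 0.0 < grassland_max < forest_min < 100.0:
        raise ValueError("thresholds must satisfy 0 < grassland_max < forest_min < 100")
    cover = np.asarray(tree_cover, dtype=float)
    valid = ~np.isnan(cover)
    bad = valid & ((cover < 0.0) | (cover > 100.0))
    if np.any(bad):
        raise ValueError(f"{int(bad.sum())} tree-cover pixel(s) outside [0, 100]")
    states = np.full(cover.shape, MISSING, dtype=np.uint8)
    states[valid & (cover <= grassland_max)] = GRASSLAND
    states[valid & (cover > grassland_max) & (cover <= forest_min)] = SAVANNA
    states[valid & (cover > forest_min)] = FOREST
    return StateGrid(
        states,
        transform or GridTransform(),
        provenance=[f"classified: grassland <= {grassland_max} < savanna <= {forest_min} < forest"],
    )


def reclassify_with_consensus(states: StateGrid, consensus: StateGrid) -> StateGrid:
    """Upgrade to forest where an independent consensus product says forest.

    The rule is one-directional: only non-forest pixels labeled forest in the
    consensus grid change; nothing is ever downgraded. Idempotent.
    """
    check_aligned(states, consensus)
    out = states.copy()
    upgrade = (out.states != FOREST) & (out.states != MISSING) & (consensus.states == FOREST)
    n = int(upgrade.sum())
    out.states[upgrade] = FOREST
    out.provenance.append(f"consensus reclassification: {n} pixel(s) upgraded to forest")
    logger.info("consensus reclassification upgraded %d pixel(s) to forest", n)
    return out


def resample_majority(states: StateGrid, factor: int) -> StateGrid:
    """Coarsen by taking the modal state of each ``factor`` x ``factor`` block.

    Missing pixels are excluded from the vote; all-missing blocks stay
    missing. Ties break toward the lowest state code (grassland < savanna <
    forest). Trailing partial blocks are processed with their available
    pixels. The output transform scales the pixel size by ``factor``.
    """
    if factor < 1:
        raise ValueError("resampling factor must be >= 1")
    if factor == 1:
        return states.copy()
    h, w = states.shape
    out_h, out_w = -(-h // factor), -(-w // factor)
    padded = np.full((out_h * factor, out_w * factor), MISSING, dtype=np.uint8)
    padded[:h, :w] = states.states
    blocks = padded.reshape(out_h, factor, out_w, factor)
    counts = np.stack(
        [(blocks == code).sum(axis=(1, 3)) for code in (GRASSLAND, SAVANNA, FOREST)]
    )  # (3, out_h, out_w); argmax ties -> lowest code
    modal = np.argmax(counts, axis=0).astype(np.uint8)
    modal[counts.sum(axis=0) == 0] = MISSING
    t = states.transform
    new_t = GridTransform(t.x0, t.y0, t.dx * factor, t.dy * factor)
    return StateGrid(modal, new_t, provenance=[*states.provenance, f"block-majority resampled x{factor}"])


def build_occurrence_table(
    states: StateGrid, climate: ClimateGrid, n_points: int, seed: int
) -> pd.DataFrame:
    """Sample pixels into a mutually exclusive presence-absence table.

    ``n_points`` pixels are drawn uniformly without replacement from the
    valid pixels. Each row records the pixel-center lon/lat, its row/col
    index, the four predictor values, and one-hot presence flags; because
    the stable states are geographic substitutes, recording one ecosystem
    present marks the other two absent.
    """
    check_aligned(states, climate)
    valid = states.valid_mask & ~climate.nodata_mask
    idx = np.flatnonzero(valid.ravel())
    if n_points > idx.size:
        raise ValueError(f"n_points={n_points} exceeds the {idx.size} valid pixels")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(idx, size=n_points, replace=False))
    rows, cols = np.unravel_index(chosen, states.shape)
    lon, lat = states.transform.pixel_center(rows, cols)
    data = {
        "lon": lon,
        "lat": lat,
        "row": rows.astype(np.int64),
        "col": cols.astype(np.int64),
    }
    for p in PREDICTORS:
        data[p] = climate.layers[p][rows, cols]
    codes = states.states[rows, cols]
    for s in STATES:
        data[f"present_{s}"] = (codes == STATE_CODES[s]).astype(np.int64)
    table = pd.DataFrame(data, columns=list(OCCURRENCE_COLUMNS))
    if not np.all(np.isfinite(table[list(PREDICTORS)].to_numpy())):
        raise ValueError("non-finite predictor values in sampled pixels")
    shares = {s: float(table[f"present_{s}"].mean()) for s in STATES}
    logger.info(
        "occurrence table: n=%d, class shares %s",
        n_points,
        {k: f"{100 * v:.1f}%" for k, v in shares.items()},
    )
    return table


def presence_rows(table: pd.DataFrame, ecosystem: str) -> pd.DataFrame:
    """Rows where ``ecosystem`` is present."""
    if ecosystem not in STATES:
        raise ValueError(f"unknown ecosystem {ecosystem!r}")
    return table[table[f"present_{ecosystem}"] == 1]
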