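"""Synthetic landscape generator.

Emulates the data structure of a continental tree-cover / bioclimate study:
smooth climate fields inside stated physical ranges, climate-conditioned and
mutually exclusive stable-state occupancy, a trimodal tree-cover distribution
(grassland 0-5%, savanna 5-60%, forest >60%), and land-use corruption that
pushes a fraction of forest pixels below the forest threshold while an
independent "consensus" product remembers the true labels.

Everything is a pure function of (config, seed); no global random state.

The default configuration encodes the study-system conditions: average annual
temperature from below freezing to 30 degC, annual temperature range up to
18 degC, precipitation from under 100 to over 6000 mm/year, and niche optima
placed so forests sit in the wet/hot/aseasonal corner, grasslands in the
arid/seasonal/cool corner, and savannas in between with the broadest
tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

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

__all__ = [
    "SyntheticConfig",
    "Landscape",
    "default_config",
    "forest_concentration_config",
    "generate_climate",
    "assign_states",
    "sample_tree_cover",
    "corrupt_land_use",
    "generate_landscape",
]


class ConfigurationError(ValueError):
    pass


# (optimum, tolerance) per ecosystem per predictor. Tolerances are the
# Gaussian scale of exp(-((v - opt)/tol)^2); larger tolerance = broader niche.
_DEFAULT_NICHES: dict[str, dict[str, tuple[float, float]]] = {
    "forest": {"ACP": (3800.0, 1300.0), "PSC": (40.0, 40.0), "AAT": (25.0, 6.0), "ART": (4.0, 5.0)},
    "savanna": {"ACP": (1500.0, 1100.0), "PSC": (90.0, 55.0), "AAT": (21.0, 9.0), "ART": (10.0, 8.0)},
    "grassland": {"ACP": (400.0, 800.0), "PSC": (120.0, 70.0), "AAT": (8.0, 12.0), "ART": (14.0, 9.0)},
}

# Unit-interval beta shapes per state, rescaled to the state's cover band.
_DEFAULT_COVER_MIXTURE: dict[str, tuple[float, float]] = {
    "grassland": (2.0, 5.0),
    "savanna": (2.5, 2.5),
    "forest": (5.0, 2.0),
}

_DEFAULT_CLIMATE_RANGES: dict[str, tuple[float, float]] = {
    "ACP": (50.0, 6200.0),
    "PSC": (5.0, 150.0),
    "AAT": (-5.0, 30.0),
    "ART": (1.0, 18.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic landscape generator."""

    grid_height: int = 120
    grid_width: int = 120
    seed: int = 0
    climate_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CLIMATE_RANGES)
    )
    niche_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {s: dict(v) for s, v in _DEFAULT_NICHES.items()}
    )
    state_noise: float = 0.02
    occupancy_mode: str = "argmax"
    cover_mixture: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COVER_MIXTURE)
    )
    corruption_fraction: float = 0.1
    smoothing_radius: float = 8.0
    latitude_trend_weight: float = 0.6
    trend_shape: float | tuple[float, float] = 1.0
    transform: GridTransform = field(default_factory=GridTransform)

    def __post_init__(self) -> None:
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise ConfigurationError("grid dimensions must be positive")
        if not 0.0 <= self.state_noise <= 1.0:
            raise ConfigurationError("state_noise must be in [0, 1]")
        if not 0.0 <= self.corruption_fraction <= 1.0:
            raise ConfigurationError("corruption_fraction must be in [0, 1]")
        if self.occupancy_mode not in ("argmax", "sample"):
            raise ConfigurationError("occupancy_mode must be 'argmax' or 'sample'")
        for pred in PREDICTORS:
            lo, hi = self.climate_ranges[pred]
            if not lo < hi:
                raise ConfigurationError(f"climate range for {pred} must satisfy min < max, got ({lo}, {hi})")
        for state, params in self.niche_params.items():
            for pred, (_, tol) in params.items():
                if tol <= 0:
                    raise ConfigurationError(f"tolerance for {state}/{pred} must be > 0")


def default_config(**overrides) -> SyntheticConfig:
    """The default synthetic study conditions."""
    return replace(SyntheticConfig(), **overrides) if overrides else SyntheticConfig()


def _gradient_niche(position: float, acp_tol: float, psc_tol: float) -> dict[str, tuple[float, float]]:
    """A niche anchored at a fractional position along the moisture gradient.

    ``position`` 0 is the arid/seasonal/cold end of the latitudinal
    gradient, 1 the wet/aseasonal/hot end. Moisture variables carry the
    niche (tolerances as fractions of each predictor's range); temperature
    tolerances are set very broad so the three states are differentiated by
    water availability, the axis that separates them in the study system.
    """
    broad = 1.5
    tols = {"ACP": acp_tol, "PSC": psc_tol, "AAT": broad, "ART": broad}
    out = {}
    for pred, (lo, hi) in _DEFAULT_CLIMATE_RANGES.items():
        span = hi - lo
        r = position if _TREND_SIGN[pred] > 0 else 1.0 - position
        out[pred] = (lo + r * span, tols[pred] * span)
    return out


def forest_concentration_config(**overrides) -> SyntheticConfig:
    """A landscape where forest presences concentrate at their optimum.

    The latitudinal trend is bent (``trend_shape`` < 1) so a large,
    climatically homogeneous wet/hot plateau occupies the equatorward end —
    a rainforest-core analog. Forest owns that plateau, so most forest
    presences sit at near-zero climate stress; grassland holds the arid,
    highly seasonal end; savanna is the transitional state squeezed between
    the two, occupied probabilistically (``occupancy_mode='sample'``) so its
    presences spread along its whole suitability gradient. This geometry is
    the mechanism behind the expected resistance ordering
    |b_forest| > |b_grassland| >= |b_savanna|: the steepness of each
    frequency-versus-stress curve tracks how much of the ecosystem's
    presence mass lies in its high-confidence core. State noise and
    land-use corruption are off so the mechanism is not diluted. The
    scenario is meaningful only when all three states keep a viable share
    of the landscape (grassland is the scarcest; its dry anchor zone varies
    with the noise realization).
    """
    niches = {
        "grassland": _gradient_niche(0.30, acp_tol=0.13, psc_tol=0.25),
        "savanna": _gradient_niche(0.46, acp_tol=0.12, psc_tol=0.45),
        "forest": _gradient_niche(0.76, acp_tol=0.12, psc_tol=0.30),
    }
    cfg = SyntheticConfig(
        grid_height=160,
        grid_width=160,
        niche_params=niches,
        state_noise=0.0,
        occupancy_mode="sample",
        corruption_fraction=0.0,
        latitude_trend_weight=0.85,
        trend_shape=0.55,
    )
    return replace(cfg, **overrides) if overrides else cfg


# Orientation of each predictor's latitudinal trend: precipitation and
# temperature increase toward the equatorward rows while seasonality and
# annual range increase poleward, giving every landscape a wet/hot/aseasonal
# end and an arid/seasonal/cold end like a real continental gradient.
_TREND_SIGN = {"ACP": 1.0, "PSC": -1.0, "AAT": 1.0, "ART": -1.0}


def _smooth_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    radius: float,
    trend_w: float,
    trend_sign: float,
    trend_shape: float,
) -> np.ndarray:
    """Low-pass filtered white noise plus a latitudinal (row-wise) trend.

    A scalar ``trend_shape`` is a power bend: values < 1 pile many rows at
    near-extreme values on the equatorward end — a large, climatically
    homogeneous wet/hot plateau like a rainforest core. A ``(p, q)`` pair
    selects the S-curve ``r^p / (r^p + (1-r)^q)``, which plateaus at both
    ends (a dry/cold plateau of size set by ``p`` and a wet/hot plateau set
    by ``q``) with the climatic gradient concentrated in between.
    """
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=radius, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    rows01 = np.linspace(0.0, 1.0, shape[0])[:, None]
    if isinstance(trend_shape, tuple):
        p, q = trend_shape
        shaped = rows01**p / (rows01**p + (1.0 - rows01) ** q)
    else:
        shaped = rows01**trend_shape
    rows = 2.0 * shaped - 1.0
    return (1.0 - trend_w) * smooth + trend_w * trend_sign * np.broadcast_to(rows, shape)


def _rescale(field_arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = field_arr.min(), field_arr.max()
    if fmax == fmin:
        return np.full_like(field_arr, 0.5 * (lo + hi))
    return lo + (field_arr - fmin) * (hi - lo) / (fmax - fmin)


def generate_climate(cfg: SyntheticConfig) -> ClimateGrid:
    """Generate four spatially smooth predictor fields in physical ranges.

    Deterministic for a fixed ``cfg.seed``: each predictor gets an
    independent substream so adding predictors never perturbs earlier ones.
    """
    shape = (cfg.grid_height, cfg.grid_width)
    layers: dict[str, np.ndarray] = {}
    for i, pred in enumerate(PREDICTORS):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101, i]))
        field_arr = _smooth_field(
            rng, shape, cfg.smoothing_radius, cfg.latitude_trend_weight, _TREND_SIGN[pred], cfg.trend_shape
        )
        lo, hi = cfg.climate_ranges[pred]
        layers[pred] = _rescale(field_arr, lo, hi)
    return ClimateGrid(layers=layers, transform=cfg.transform)


def suitability_fields(climate: ClimateGrid, cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Generating-model suitability: product of per-predictor Gaussians."""
    out: dict[str, np.ndarray] = {}
    for state in STATES:
        params = cfg.niche_params[state]
        suit = np.ones(climate.shape)
        for pred, (opt, tol) in params.items():
            v = climate.layers[pred]
            suit = suit * np.exp(-(((v - opt) / tol) ** 2))
        out[state] = suit
    return out


def assign_states(climate: ClimateGrid, cfg: SyntheticConfig) -> StateGrid:
    """Assign each valid pixel a stable state from its climate.

    In the default ``argmax`` mode the pixel takes the state with highest
    generating suitability, ties breaking in the fixed order grassland <
    savanna < forest. In ``sample`` mode the state is drawn with
    probability proportional to suitability — occupancy then declines
    smoothly away from each optimum, the graded structure behind the
    frequency-versus-stress response curves. Either way, with probability
    ``state_noise`` a pixel is re-assigned uniformly at random.
    """
    for state in STATES:
        if state not in cfg.niche_params:
            raise ConfigurationError(f"niche_params missing ecosystem {state!r}")
    suits = suitability_fields(climate, cfg)
    stack = np.stack([suits[s] for s in STATES])  # order = code order; argmax tie -> lowest code
    if cfg.occupancy_mode == "sample":
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 201]))
        total = stack.sum(axis=0)
        total[total == 0] = 1.0  # degenerate pixels fall back to uniform
        probs = np.where(stack.sum(axis=0, keepdims=True) == 0, 1.0 / 3.0, stack / total)
        cum = np.cumsum(probs, axis=0)
        u = rng.random(climate.shape)
        states = (u[None, :, :] > cum).sum(axis=0).astype(np.uint8)
        states = np.minimum(states, 2)
    else:
        states = np.argmax(stack, axis=0).astype(np.uint8)
    if cfg.state_noise > 0:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202]))
        flip = rng.random(states.shape) < cfg.state_noise
        states[flip] = rng.integers(0, 3, size=int(flip.sum()), dtype=np.uint8)
    states[climate.nodata_mask] = MISSING
    return StateGrid(states, climate.transform, provenance=["synthetic: argmax of Gaussian niche products"])


# Tree-cover bands per state code: (low, high], except grassland closed at 0.
_BANDS = {GRASSLAND: (0.0, 5.0), SAVANNA: (5.0, 60.0), FOREST: (60.0, 100.0)}


def sample_tree_cover(states: StateGrid, cfg: SyntheticConfig, seed: int) -> np.ndarray:
    """Draw per-pixel tree cover from the state's band-rescaled beta mixture.

    Values always lie inside the generating state's band (open at the lower
    edge for savanna and forest, so re-classification recovers the state
    exactly). Missing pixels get NaN.
    """
    for state in STATES:
        if state not in cfg.cover_mixture:
            raise ConfigurationError(f"cover_mixture missing ecosystem {state!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    cover = np.full(states.shape, np.nan)
    for state in STATES:
        code = STATE_CODES[state]
        mask = states.states == code
        n = int(mask.sum())
        if n == 0:
            continue
        a, b = cfg.cover_mixture[state]
        u = rng.beta(a, b, size=n)
        lo, hi = _BANDS[code]
        vals = lo + u * (hi - lo)
        if lo > 0.0:  # keep strictly above the band's open lower edge
            vals = np.maximum(vals, np.nextafter(lo, hi))
        cover[mask] = np.minimum(vals, hi)
    return cover


def corrupt_land_use(
    tree_cover: np.ndarray, states: StateGrid, cfg: SyntheticConfig, seed: int
) -> tuple[np.ndarray, StateGrid]:
    """Degrade a fraction of forest pixels below the forest threshold.

    Exactly ``round(corruption_fraction * n_forest)`` forest pixels (sampled
    without replacement) get cover redrawn uniformly in [10, 59], landing in
    the savanna band. The returned consensus grid preserves the original
    states, emulating an independent high-resolution land-cover census.
    """
    if tree_cover.shape != states.shape:
        raise ValueError("tree cover and state grid shapes differ")
    corrupted = np.array(tree_cover, dtype=float, copy=True)
    consensus = states.copy()
    consensus.provenance.append("synthetic consensus: pre-corruption states")
    if cfg.corruption_fraction == 0.0:
        return corrupted, consensus
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    forest_idx = np.flatnonzero(states.states.ravel() == FOREST)
    k = int(round(cfg.corruption_fraction * forest_idx.size))
    chosen = rng.choice(forest_idx, size=k, replace=False)
    flat = corrupted.ravel()
    flat[chosen] = rng.uniform(10.0, 59.0, size=k)
    return flat.reshape(corrupted.shape), consensus


@dataclass
class Landscape:
    """Bundle of all synthetic products for one (config, seed)."""

    climate: ClimateGrid
    states: StateGrid
    tree_cover: np.ndarray
    corrupted_cover: np.ndarray
    consensus: StateGrid


def generate_landscape(cfg: SyntheticConfig) -> Landscape:
    """Run the full generator: climate -> states -> cover -> corruption."""
    climate = generate_climate(cfg)
    states = assign_states(climate, cfg)
    check_aligned(climate, states)
    cover = sample_tree_cover(states, cfg, seed=cfg.seed)
    corrupted, consensus = corrupt_land_use(cover, states, cfg, seed=cfg.seed)
    return Landscape(climate, states, cover, corrupted, consensus)
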