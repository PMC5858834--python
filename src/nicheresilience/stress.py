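"""Resilience mapping, climate-stress inversion, and resistance curves.

Consensus suitability (0-1) is rescaled to an integer resilience metric on
0-1000: the climate niche is read as capacity to recover after disturbance,
maximal at the niche optimum. Climate stress is the linear inversion of that
gradient, rescaled to 0-100 stress units: pixels far from the optimum are
highly stressed. For each ecosystem the relative frequency (%) of its
presence observations is binned along the stress gradient and an exponential
resistance model

    y = a * exp(b * x)

is fit by nonlinear least squares; the rate coefficient ``b`` (per stress
unit, negative for declining frequency) indexes resistance to climatic
stress — an ecosystem whose observations collapse quickly as stress rises
has a large |b| and low resistance.

The model is sometimes written y = a * b^x, but a decay base cannot be
negative; with the exp(b*x) parameterization the reported negative ``b``
values are the decay rate per stress unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .grids import GridTransform
from .classify import presence_rows
from .ensemble import EnsembleResult

__all__ = [
    "ResilienceMap",
    "StressResponse",
    "resilience_map",
    "climate_stress",
    "stress_frequencies",
    "fit_exponential",
    "compare_resistance",
]

#: Offset added inside log() when initializing the fit from a log-linear
#: regression; keeps empty bins finite.
LOG_EPS = 1e-3


@dataclass
class ResilienceMap:
    """Per-pixel integer resilience in [0, 1000] for one ecosystem."""

    ecosystem: str
    values: np.ndarray  # float array; integers 0..1000 on valid pixels, NaN nodata
    transform: GridTransform
    source_members: list[tuple[str, int]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class StressResponse:
    """Binned stress gradient with per-ecosystem relative frequencies."""

    ecosystem: str
    bin_edges: np.ndarray  # length n_bins + 1, covering [0, 100]
    rel_freq: np.ndarray  # %, sums to 100
    n_obs: int
    fit_a: float | None = None
    fit_b: float | None = None
    fit_rss: float | None = None

    @property
    def bin_mid(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def fitted(self) -> bool:
        return self.fit_b is not None


def resilience_map(ensemble: EnsembleResult, transform: GridTransform | None = None) -> ResilienceMap:
    """Rescale consensus suitability to integer resilience on [0, 1000].

    value = round(consensus * 1000), rounding halves up; nodata propagates.
    """
    c = np.asarray(ensemble.consensus, dtype=float)
    valid = ~np.isnan(c)
    if np.any((c[valid] < 0.0) | (c[valid] > 1.0)):
        raise ValueError("consensus suitability must lie in [0, 1]")
    vals = np.full(c.shape, np.nan)
    vals[valid] = np.floor(c[valid] * 1000.0 + 0.5)  # half-up
    return ResilienceMap(
        ecosystem=ensemble.ecosystem,
        values=vals,
        transform=transform or GridTransform(),
        source_members=list(ensemble.members),
    )


def climate_stress(resilience: ResilienceMap) -> np.ndarray:
    """Invert resilience into climate stress on [0, 100].

    stress = (1000 - resilience) / 10: maximal resilience means zero
    stress and vice versa. NaN (nodata) propagates.
    """
    return (1000.0 - resilience.values) / 10.0


def stress_frequencies(
    stress: np.ndarray,
    table: pd.DataFrame,
    ecosystem: str,
    n_bins: int = 20,
) -> StressResponse:
    """Relative frequency (%) of presence observations along the gradient.

    Stress is sampled at each presence pixel of the ecosystem and binned
    into ``n_bins`` equal-width bins on [0, 100] (the last bin closed).
    """
    if n_bins < 5:
        raise ValueError("n_bins must be >= 5")
    pres = presence_rows(table, ecosystem)
    if len(pres) < n_bins:
        raise ValueError(f"{ecosystem} has {len(pres)} presences; need >= n_bins = {n_bins}")
    rows = pres["row"].to_numpy(dtype=int)
    cols = pres["col"].to_numpy(dtype=int)
    h, w = stress.shape
    outside = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if np.any(outside):
        raise ValueError(f"presence rows outside the raster extent: indices {np.flatnonzero(outside).tolist()}")
    values = stress[rows, cols]
    if np.any(np.isnan(values)):
        raise ValueError("presence points fall on nodata stress pixels")
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    rel = 100.0 * counts / counts.sum()
    return StressResponse(ecosystem=ecosystem, bin_edges=edges, rel_freq=rel, n_obs=int(counts.sum()))


def _exp_model(x: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.exp(b * x)


def fit_exponential(
    response: StressResponse, max_iter: int = 2000, tol: float = 1e-12
) -> StressResponse:
    """Fit y = a*exp(b*x) to the binned frequencies by least squares.

    ``x`` is the bin midpoint, ``y`` the relative frequency in %. The fit
    is initialized from the ordinary regression of log(y + 1e-3) on x and
    refined by Levenberg-Marquardt to gradient tolerance ``tol`` (at most
    ``max_iter`` function evaluations).
    """
    x = response.bin_mid
    y = response.rel_freq
    nonzero = int(np.sum(y > 0))
    if nonzero == 0:
        raise ValueError("all bin frequencies are zero; nothing to fit")
    if nonzero < 3:
        raise ValueError(f"need >= 3 non-empty bins to fit, got {nonzero}")
    logy = np.log(y + LOG_EPS)
    slope, intercept = np.polyfit(x, logy, 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = curve_fit(
            _exp_model, x, y, p0=p0, maxfev=max_iter, ftol=tol, xtol=tol, gtol=tol
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit did not converge from p0={p0}: {exc}") from exc
    a, b = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - _exp_model(x, a, b)) ** 2))
    return replace(response, fit_a=a, fit_b=b, fit_rss=rss)


def compare_resistance(responses: list[StressResponse]) -> pd.DataFrame:
    """Rank ecosystems by |b|, largest first (least resistant first).

    A steeper frequency decay along the stress gradient (larger |b|) means
    the ecosystem concentrates near its climatic optimum and tolerates
    little stress. Equal |b| values share a rank and are flagged as ties.
    """
    if len(responses) < 2:
        raise ValueError("need at least two fitted responses to compare")
    for r in responses:
        if not r.fitted:
            raise ValueError(f"response for {r.ecosystem} is not fitted")
    df = pd.DataFrame(
        {
            "ecosystem": [r.ecosystem for r in responses],
            "b": [r.fit_b for r in responses],
            "abs_b": [abs(r.fit_b) for r in responses],
            "n_obs": [r.n_obs for r in responses],
        }
    )
    df = df.sort_values("abs_b", ascending=False, kind="stable").reset_index(drop=True)
    df["resistance_rank"] = df["abs_b"].rank(method="min", ascending=False).astype(int)
    df["tied"] = df.duplicated("abs_b", keep=False)
    return df
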