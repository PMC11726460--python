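"""Per-tooth seasonal inference from sequential enamel series.

Drinking-water delta18O in temperate regions follows the annual temperature
cycle, so sequential enamel delta18O along a hypsodont molar crown records
roughly one sinusoidal year.  The model fitted per tooth is

    predicted(x) = A * cos(2*pi*(x - x0)/X) + M

with x the sample position (mm from the enamel-root junction, ERJ), A > 0 the
amplitude, X the crown length of one annual cycle (mm), x0 the position of the
delta18O maximum (peak summer) and M the annual mean.  The fitted curve gives
an intra-tooth season scale: positions where the predicted value drops below
M - k*A (default k = 0.5, the central cold third of each cycle) approximate
the cold season.

A crown-height time scale converts positions to ages in months: the crown is
assumed to form over 12 months, dentine at a given relative crown height
mineralizing ~6 months before the enamel at the same height:

    %crown height = position / crown height * 100            (percent at I/O)
    dentine age   = (1 - frac) * 12 + 6   months              (frac = percent/100)
    enamel age    = (1 - frac) * 12 + 12  months

Ages increase from the occlusal surface toward the ERJ because hypsodont
crowns mineralize occlusal-first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .datamodel import ToothSeries

__all__ = [
    "SeasonalModel",
    "CrownClock",
    "SeasonWindow",
    "fit_cosine",
    "fit_tooth",
    "predict_cosine",
    "cold_season_windows",
    "tooth_amplitude",
    "percent_crown_height",
    "dentine_age_months",
    "enamel_age_months",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SeasonalModel:
    """Fitted annual cosine for one tooth (positions in mm from the ERJ)."""

    tooth_id: str
    A: float    # amplitude, per-mil, > 0
    X: float    # period, mm of crown per annual cycle
    x0: float   # position of the delta18O maximum, in [0, X)
    M: float    # mean level, per-mil
    rmse: float
    n_points: int


@dataclass(frozen=True)
class CrownClock:
    """Crown-height time scale; enamel lags dentine by exactly 6 months."""

    crown_height: float
    dentine_offset_months: float = 6.0
    enamel_offset_months: float = 12.0
    cycle_months: float = 12.0

    def dentine_months(self, position_erj: float) -> float:
        frac = percent_crown_height(position_erj, self.crown_height) / 100.0
        return (1.0 - frac) * self.cycle_months + self.dentine_offset_months

    def enamel_months(self, position_erj: float) -> float:
        frac = percent_crown_height(position_erj, self.crown_height) / 100.0
        return (1.0 - frac) * self.cycle_months + self.enamel_offset_months


@dataclass(frozen=True)
class SeasonWindow:
    tooth_id: str
    start_pos: float
    end_pos: float  # start < end, mm from ERJ
    label: str      # cold | warm


def _linear_solve(x: np.ndarray, y: np.ndarray, X: float):
    """For fixed period X the model is linear in (a, b, M):
    a*cos(wx) + b*sin(wx) + M; returns coefficients and RSS."""
    w = TWO_PI / X
    design = np.column_stack([np.cos(w * x), np.sin(w * x), np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((y - design @ coef) ** 2))
    return coef, rss


def fit_cosine(
    positions: Sequence[float],
    values: Sequence[float],
    tooth_id: str = "",
    crown_height: float | None = None,
    period_bounds_factor: tuple[float, float] = (0.3, 3.0),
    n_grid: int = 241,
) -> SeasonalModel:
    """Least-squares fit of the annual cosine to one enamel series.

    The period X is the only non-linear parameter: for each candidate X the
    remaining parameters have a closed-form linear solution, so the fit scans
    a dense X grid (bounded to ``period_bounds_factor`` times the crown
    height to prevent aliasing on sparse series), refines the best candidate
    by bounded scalar minimisation, and re-parameterises to A > 0 with x0 the
    position of a maximum, reduced modulo X into [0, X).  Among equal-residual
    grid candidates the smallest X wins.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size:
        raise ValueError("positions and values differ in length")
    if x.size < 5:
        raise ValueError(f"cosine fit needs >= 5 increments, got {x.size}")
    if float(np.ptp(y)) == 0.0:
        raise ValueError("constant series: amplitude not identifiable")
    ch = crown_height if crown_height is not None else float(np.max(x))
    if ch <= 0:
        raise ValueError("crown_height must be positive")
    span = float(np.ptp(x))
    if span <= 0.4 * ch:
        raise ValueError(
            f"sampled span {span:.3g} mm covers <= 40% of crown height {ch:.3g} mm"
        )

    lo, hi = period_bounds_factor[0] * ch, period_bounds_factor[1] * ch
    grid = np.linspace(lo, hi, n_grid)
    rss_grid = np.array([_linear_solve(x, y, X)[1] for X in grid])
    best = int(np.flatnonzero(rss_grid <= rss_grid.min() + 1e-12)[0])  # ties -> smallest X

    # refine within the bracketing grid cells
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda X: _linear_solve(x, y, X)[1],
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    X_hat = float(res.x) if res.fun <= rss_grid[best] else float(grid[best])

    coef, rss = _linear_solve(x, y, X_hat)
    ca, cb, M = map(float, coef)
    A = math.hypot(ca, cb)
    if A <= 0 or not np.isfinite(rss):
        raise ValueError("cosine fit did not converge: amplitude degenerate "
                         f"(best residual {rss:.3g})")
    phi = math.atan2(cb, ca)             # y = A*cos(w*x - phi) + M
    x0 = (phi / TWO_PI * X_hat) % X_hat  # position of a maximum, in [0, X)
    rmse = math.sqrt(rss / x.size)
    return SeasonalModel(tooth_id=tooth_id, A=A, X=X_hat, x0=x0, M=M,
                         rmse=rmse, n_points=int(x.size))


def fit_tooth(tooth: ToothSeries, **kwargs) -> SeasonalModel:
    """Fit the seasonal cosine to a tooth's enamel delta18O series."""
    return fit_cosine(
        [e.position_erj for e in tooth.enamel],
        [e.d18o_bioap for e in tooth.enamel],
        tooth_id=tooth.tooth_id,
        crown_height=tooth.crown_height,
        **kwargs,
    )


def predict_cosine(model: SeasonalModel, x) -> float | np.ndarray:
    """Evaluate the fitted curve at position(s) x."""
    x = np.asarray(x, dtype=float)
    out = model.A * np.cos(TWO_PI * (x - model.x0) / model.X) + model.M
    return float(out) if out.ndim == 0 else out


def cold_season_windows(
    model: SeasonalModel,
    sampled_interval: tuple[float, float],
    k: float = 0.5,
) -> list[SeasonWindow]:
    """Tile the sampled interval into cold/warm windows from the fitted curve.

    Cold is where predicted(x) < M - k*A.  In phase terms cos(theta) < -k,
    i.e. theta in (arccos(-k), 2*pi - arccos(-k)) each cycle; for the default
    k = 0.5 this is the central third of each cycle, centred on the delta18O
    minimum at x0 + X/2.  Solved in closed form and clipped to the interval;
    the complement is labelled warm, so windows tile the interval exactly.
    """
    lo, hi = sampled_interval
    if not hi > lo:
        raise ValueError("sampled_interval must have positive length")
    if not 0.0 < k < 1.0:
        raise ValueError("cold-season multiplier k must lie in (0, 1)")
    theta1 = math.acos(-k)  # in (pi/2, pi)
    half = (math.pi - theta1) / TWO_PI * model.X  # half-width of a cold window
    centre0 = model.x0 + model.X / 2.0            # a delta18O minimum

    n_min = math.floor((lo - half - centre0) / model.X)
    n_max = math.ceil((hi + half - centre0) / model.X)
    cold: list[tuple[float, float]] = []
    for n in range(n_min, n_max + 1):
        c = centre0 + n * model.X
        a, b = max(c - half, lo), min(c + half, hi)
        if b > a:
            cold.append((a, b))
    cold.sort()

    windows: list[SeasonWindow] = []
    cursor = lo
    for a, b in cold:
        if a > cursor:
            windows.append(SeasonWindow(model.tooth_id, cursor, a, "warm"))
        windows.append(SeasonWindow(model.tooth_id, a, b, "cold"))
        cursor = b
    if cursor < hi:
        windows.append(SeasonWindow(model.tooth_id, cursor, hi, "warm"))
    return windows


def tooth_amplitude(values: Sequence[float]) -> float:
    """Intra-tooth amplitude: max - min of the raw increment values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"amplitude needs >= 2 values, got {v.size}")
    return float(v.max() - v.min())


def percent_crown_height(position_erj: float, crown_height: float) -> float:
    """Sample position as percent of crown height."""
    if crown_height <= 0:
        raise ValueError("crown_height must be positive")
    if not 0.0 <= position_erj <= crown_height:
        raise ValueError(
            f"position {position_erj} outside [0, crown_height={crown_height}]"
        )
    return position_erj / crown_height * 100.0


def _check_frac(frac: float) -> None:
    if not 0.0 <= frac <= 1.0:
        raise ValueError(f"crown-height fraction {frac} outside [0, 1]")


def dentine_age_months(frac_crown_height: float) -> float:
    """Age (months) of a dentine increment at the given crown fraction."""
    _check_frac(frac_crown_height)
    return (1.0 - frac_crown_height) * 12.0 + 6.0


def enamel_age_months(frac_crown_height: float) -> float:
    """Age (months) of an enamel increment; dentine age + 6 everywhere."""
    _check_frac(frac_crown_height)
    return (1.0 - frac_crown_height) * 12.0 + 12.0
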