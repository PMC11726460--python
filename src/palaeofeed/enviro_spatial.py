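"""Environmental enrichment, IDW isoscapes and the correlation screen.

Site records are enriched with mean forest cover (MFC) by sampling three
forest-cover reconstruction time slices (7500, 7250 and 7000 cal BP) at each
site location and averaging.  Site-median diet delta13C values are turned
into isoscape surfaces by inverse-distance-weighted (IDW) interpolation whose
power exponent is chosen per variable by leave-one-out cross-validation
(LOOCV) on root-mean-square error.  Finally, isotope summaries are screened
against the environmental covariates with Pearson/Spearman correlations and
one-way ANOVA, with Bonferroni and Benjamini-Hochberg adjustment across the
screen.

Hypothesis tests delegate to :mod:`scipy.stats`; multiple-testing adjustment
to :mod:`statsmodels`.  The spatial primitives (haversine IDW, LOOCV power
selection, grid construction) are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import Site

__all__ = [
    "ProxyGrid",
    "IDWConfig",
    "CorrelationResult",
    "haversine_km",
    "mean_forest_cover_at_site",
    "idw_predict",
    "loocv_select_power",
    "build_isoscape",
    "pearson_test",
    "spearman_test",
    "anova_oneway",
    "multiple_testing_adjust",
    "correlation_screen",
    "MFC_TIME_SLICES",
]

MFC_TIME_SLICES = ("7500", "7250", "7000")  # cal BP

EARTH_RADIUS_KM = 6371.0088


@dataclass
class ProxyGrid:
    """A gridded environmental/isotope field: unique lon/lat nodes + values."""

    variable: str
    nodes: pd.DataFrame  # columns: longitude, latitude, value
    time_slice: str = ""

    def __post_init__(self):
        dup = self.nodes.duplicated(subset=["longitude", "latitude"])
        if dup.any():
            raise ValueError(
                f"grid {self.variable!r}: {int(dup.sum())} duplicate coordinate nodes"
            )

    def nearest_value(self, longitude: float, latitude: float) -> float:
        d = haversine_km(
            self.nodes["longitude"].to_numpy(), self.nodes["latitude"].to_numpy(),
            longitude, latitude,
        )
        return float(self.nodes["value"].to_numpy()[int(np.argmin(d))])


@dataclass(frozen=True)
class IDWConfig:
    power_candidates: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)
    metric: str = "haversine_km"  # or euclidean_deg
    epsilon: float = 1e-9         # coincident-point threshold, active distance unit

    def __post_init__(self):
        if not self.power_candidates or any(p <= 0 for p in self.power_candidates):
            raise ValueError("power candidates must be non-empty and positive")
        if self.metric not in ("haversine_km", "euclidean_deg"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    method: str           # pearson | spearman
    statistic: float      # r or rho
    p_raw: float
    n: int
    s_statistic: float | None = None  # Spearman S = (n^3 - n) * (1 - rho) / 6
    p_bonferroni: float | None = None
    p_fdr: float | None = None


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


def _distances(lons, lats, lon, lat, metric: str):
    if metric == "haversine_km":
        return haversine_km(np.asarray(lons, float), np.asarray(lats, float), lon, lat)
    return np.hypot(np.asarray(lons, float) - lon, np.asarray(lats, float) - lat)


def mean_forest_cover_at_site(site: Site, grids: dict[str, ProxyGrid]) -> float:
    """Average MFC over the three reconstruction time slices at the site.

    Samples the nearest grid node of each slice (the source reconstruction
    is itself already interpolated) and takes the arithmetic mean.
    """
    missing = [s for s in MFC_TIME_SLICES if s not in grids]
    if missing:
        raise ValueError(f"missing MFC time slice(s): {', '.join(missing)}")
    vals = [grids[s].nearest_value(site.longitude, site.latitude)
            for s in MFC_TIME_SLICES]
    return float(sum(vals) / len(vals))


def idw_predict(
    lons, lats, values, target_lon: float, target_lat: float,
    power: float, config: IDWConfig = IDWConfig(),
) -> float:
    """Inverse-distance-weighted prediction at a target from all data points.

    Weights are d**-power over every point; a target within ``epsilon`` of a
    data point returns that point's value exactly (IDW is an exact
    interpolator).  Predictions are convex combinations of the data values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("idw_predict: empty point set")
    d = _distances(lons, lats, target_lon, target_lat, config.metric)
    hit = d < config.epsilon
    if hit.any():
        return float(values[np.argmax(hit)])
    w = d ** (-power)
    return float(np.sum(w * values) / np.sum(w))


def loocv_select_power(
    lons, lats, values, config: IDWConfig = IDWConfig(),
) -> tuple[float, dict[float, float]]:
    """Choose the IDW power by leave-one-out RMSE; ties -> smallest power."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError(f"LOOCV needs >= 3 points, got {n}")
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    rmse: dict[float, float] = {}
    for p in config.power_candidates:
        errs = np.empty(n)
        for i in range(n):
            keep = np.arange(n) != i
            pred = idw_predict(lons[keep], lats[keep], values[keep],
                               lons[i], lats[i], p, config)
            errs[i] = pred - values[i]
        rmse[p] = float(np.sqrt(np.mean(errs ** 2)))
    best = min(sorted(rmse), key=lambda p: rmse[p])  # stable: smallest p on ties
    return best, rmse


def build_isoscape(
    site_values: pd.DataFrame,
    lon_range: tuple[float, float],
    lat_range: tuple[float, float],
    resolution: float = 0.25,
    config: IDWConfig = IDWConfig(),
    variable: str = "d13c_diet",
) -> tuple[ProxyGrid, float, dict[float, float]]:
    """IDW isoscape of per-site median values on a regular lon/lat grid.

    ``site_values`` needs columns site_id, longitude, latitude, value (one
    row per sample; the per-site median is taken first).  Returns the grid
    plus the LOOCV-selected power and the per-candidate RMSE table.  Being a
    convex-combination interpolator, the surface is bounded by the site
    medians.
    """
    med = (
        site_values.groupby("site_id")
        .agg(longitude=("longitude", "first"), latitude=("latitude", "first"),
             value=("value", "median"))
        .reset_index()
    )
    if len(med) < 3:
        raise ValueError(f"isoscape needs >= 3 sites, got {len(med)}")
    lons = med["longitude"].to_numpy()
    lats = med["latitude"].to_numpy()
    vals = med["value"].to_numpy()
    power, rmse = loocv_select_power(lons, lats, vals, config)

    glon = np.arange(lon_range[0], lon_range[1] + resolution / 2, resolution)
    glat = np.arange(lat_range[0], lat_range[1] + resolution / 2, resolution)
    rows = []
    for la in glat:
        for lo in glon:
            rows.append({
                "longitude": lo, "latitude": la,
                "value": idw_predict(lons, lats, vals, lo, la, power, config),
            })
    grid = ProxyGrid(variable=variable, nodes=pd.DataFrame(rows))
    return grid, power, rmse


# ---------------------------------------------------------------------------
# correlation / ANOVA screen


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} paired finite values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    return x, y


def pearson_test(x, y, pair: str = "") -> CorrelationResult:
    """Two-sided Pearson correlation."""
    x, y = _check_pair(x, y)
    r = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, method="pearson",
                             statistic=float(r.statistic),
                             p_raw=float(r.pvalue), n=int(x.size))


def spearman_test(x, y, pair: str = "") -> CorrelationResult:
    """Two-sided Spearman rank correlation, average ranks for ties.

    Also reports the S statistic, S = (n^3 - n) * (1 - rho) / 6, the
    tie-corrected sum of squared rank differences printed by R's cor.test.
    """
    x, y = _check_pair(x, y)
    res = stats.spearmanr(x, y)
    n = int(x.size)
    rho = float(res.statistic)
    s = (n ** 3 - n) * (1.0 - rho) / 6.0
    return CorrelationResult(pair=pair, method="spearman", statistic=rho,
                             p_raw=float(res.pvalue), n=n, s_statistic=s)


def anova_oneway(groups: list) -> dict:
    """One-way ANOVA across >= 2 groups of >= 2 finite values each."""
    clean = [np.asarray(g, dtype=float) for g in groups]
    clean = [g[np.isfinite(g)] for g in clean]
    if len(clean) < 2 or any(g.size < 2 for g in clean):
        raise ValueError("ANOVA needs >= 2 groups of >= 2 values")
    res = stats.f_oneway(*clean)
    n = sum(g.size for g in clean)
    return {
        "F": float(res.statistic),
        "df_between": len(clean) - 1,
        "df_within": n - len(clean),
        "p": float(res.pvalue),
    }


def multiple_testing_adjust(p_values, m: int | None = None) -> dict:
    """Bonferroni and Benjamini-Hochberg adjusted p values.

    ``m`` defaults to the number of tests supplied; a larger m may be given
    when the listed p values are a subset of a wider screen (Bonferroni
    only; BH always uses the supplied family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p values must lie in [0, 1]")
    m_eff = int(m) if m is not None else p.size
    if m_eff < p.size:
        raise ValueError("m must be >= number of p values")
    bonf = np.minimum(1.0, m_eff * p)
    if p.size:
        _, fdr, _, _ = multipletests(p, method="fdr_bh")
    else:
        fdr = p.copy()
    return {"bonferroni": bonf, "fdr_bh": np.asarray(fdr)}


def correlation_screen(
    tables: dict[str, pd.DataFrame],
    manifest: list[dict],
) -> pd.DataFrame:
    """Run every manifest pair and adjust p values across the whole screen.

    Each manifest entry names a table and two of its columns, e.g.
    ``{"pair": "mfc~d13c_coll", "table": "collagen", "x": "mfc",
    "y": "d13c", "method": "pearson"}``.  Unresolvable entries are skipped
    with a warning.  Bonferroni uses the number of tests actually run.
    """
    results: list[CorrelationResult] = []
    for entry in manifest:
        table = entry.get("table")
        xcol, ycol = entry.get("x"), entry.get("y")
        method = entry.get("method", "pearson")
        label = entry.get("pair", f"{xcol}~{ycol}")
        df = tables.get(table)
        if df is None or xcol not in getattr(df, "columns", ()) or ycol not in df.columns:
            warnings.warn(f"correlation_screen: cannot resolve pair {label!r}; skipped")
            continue
        test = {"pearson": pearson_test, "spearman": spearman_test}.get(method)
        if test is None:
            warnings.warn(f"correlation_screen: unknown method {method!r}; skipped")
            continue
        try:
            results.append(test(df[xcol], df[ycol], pair=label))
        except ValueError as exc:
            warnings.warn(f"correlation_screen: pair {label!r} failed: {exc}")
    if not results:
        return pd.DataFrame(columns=["pair", "method", "statistic", "s_statistic",
                                     "p_raw", "p_bonferroni", "p_fdr", "n"])
    adj = multiple_testing_adjust([r.p_raw for r in results])
    rows = []
    for r, pb, pf in zip(results, adj["bonferroni"], adj["fdr_bh"]):
        rows.append({
            "pair": r.pair, "method": r.method, "statistic": r.statistic,
            "s_statistic": r.s_statistic, "p_raw": r.p_raw,
            "p_bonferroni": float(pb), "p_fdr": float(pf), "n": r.n,
        })
    return pd.DataFrame(rows)
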