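"""Synthetic worlds with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the early-Neolithic
cattle-husbandry problem rather than any one excavation:

* sites on a west-east gradient of reconstructed forest cover (MFC rises
  from ~60% to ~85% across the longitude range, plus noise);
* a *canopy effect*: each site's true diet delta13C is the open-vegetation
  mean plus a depression proportional to the fraction of forest-derived
  feed, here tied to forest cover;
* bulk collagen and dairy-lipid samples generated by *inverting* the
  tissue-to-diet offsets around the site's true diet mean, so all proxies
  agree on the diet scale by construction;
* deer collagen drawn around the forest-herbivore baseline (diet -27.7
  per-mil, sd 1);
* per-tooth annual delta18O cosines with known parameters, and - under the
  ``winter_woody`` foddering scenario - a cold-season depression of enamel
  delta13C below the forest reference line together with dentine Glx/Phe
  spacings drawn from the woody-plant beta distribution in cold months and
  the herbaceous one otherwise;
* forest-cover grids for three time slices and climate grids whose nearest
  node at a site returns the site's truth value (plus configurable grid
  noise).

Everything is driven by one integer seed; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import BulkSample, Dataset, DentineIncrement, EnamelIncrement, Site, ToothSeries
from .diet_inference import OffsetTable, diet_to_tissue
from .seasonal_model import CrownClock, SeasonalModel, cold_season_windows
from . import isotope_io

__all__ = [
    "ToothConfig",
    "AAConfig",
    "WorldConfig",
    "World",
    "generate_world",
    "generate_proxy_grids",
    "write_world",
    "load_world",
]


@dataclass(frozen=True)
class ToothConfig:
    n_tooth_sites: int = 7        # sites contributing molars
    teeth_per_site: int = 2
    crown_height: float = 45.0    # mm, cattle M3
    n_increments: int = 12
    amplitude: float = 2.0        # per-mil delta18O annual amplitude
    period: float = 30.0          # mm of crown per annual cycle
    mean_level: float = -6.0      # per-mil delta18O annual mean
    d18o_noise_sd: float = 0.3
    d13c_noise_sd: float = 0.3
    winter_pulse: float = 2.5     # per-mil cold-season depression of d13c_bioap
    n_dentine: int = 6            # dentine CSIA points per molar


@dataclass(frozen=True)
class AAConfig:
    phe_baseline: float = 8.0     # per-mil dentine Phe delta15N
    noise_sd: float = 0.5         # per-mil noise on the Glx-Phe spacing
    woody_beta: float = -9.3      # true plant beta for woody diets
    herbaceous_beta: float = -5.4


@dataclass(frozen=True)
class WorldConfig:
    n_sites: int = 40
    lon_range: tuple[float, float] = (2.0, 22.0)
    lat_range: tuple[float, float] = (46.0, 54.0)
    mfc_west: float = 60.0        # percent forest cover at the west edge
    mfc_east: float = 85.0        # ... and at the east edge
    mfc_noise_sd: float = 5.0
    open_diet_mean: float = -25.0  # per-mil diet d13C on open vegetation
    canopy_effect: float = -3.0    # per-mil shift at 100% forest-derived feed
    within_site_sd: float = 1.0
    samples_per_site: int = 10     # per proxy (collagen, dairy)
    dairy_spacing_mean: float = -4.3  # C18:0 - C16:0 of ruminant dairy fat
    dairy_spacing_sd: float = 0.5
    n_deer: int = 35
    deer_diet_mean: float = -27.7
    deer_diet_sd: float = 1.0
    fodder_scenario: str = "winter_woody"  # none | winter_woody
    tooth: ToothConfig = field(default_factory=ToothConfig)
    aa: AAConfig = field(default_factory=AAConfig)
    grid_noise_sd: float = 0.0
    grid_resolution: float = 1.0  # degrees, background grid spacing
    seed: int = 17

    def validate(self) -> None:
        for name in ("mfc_noise_sd", "within_site_sd", "dairy_spacing_sd",
                     "deer_diet_sd", "grid_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"WorldConfig.{name} must be >= 0")
        for name in ("d18o_noise_sd", "d13c_noise_sd"):
            if getattr(self.tooth, name) < 0:
                raise ValueError(f"ToothConfig.{name} must be >= 0")
        if self.aa.noise_sd < 0:
            raise ValueError("AAConfig.noise_sd must be >= 0")
        if self.fodder_scenario not in ("none", "winter_woody"):
            raise ValueError(f"unknown fodder_scenario {self.fodder_scenario!r}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.tooth.n_increments < 5:
            raise ValueError("ToothConfig.n_increments must be >= 5")


@dataclass
class World:
    config: WorldConfig
    dataset: Dataset
    truth: dict[str, pd.DataFrame]
    grids: dict[str, "object"]  # name -> ProxyGrid (enviro_spatial)


def _forest_use(mfc: float) -> float:
    """Fraction of forest-derived feed; proportional to forest cover."""
    return mfc / 100.0


def generate_world(config: WorldConfig = WorldConfig()) -> World:
    """Build a complete synthetic dataset + truth tables + proxy grids."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    offsets = OffsetTable()
    ds = Dataset()

    lon_lo, lon_hi = config.lon_range
    lat_lo, lat_hi = config.lat_range
    drainages = ["Rhine", "Danube", "Oder", "Vistula"]

    site_rows = []
    for i in range(config.n_sites):
        sid = f"S{i + 1:03d}"
        lon = float(rng.uniform(lon_lo, lon_hi))
        lat = float(rng.uniform(lat_lo, lat_hi))
        rel = (lon - lon_lo) / (lon_hi - lon_lo)
        mfc = float(np.clip(
            config.mfc_west + (config.mfc_east - config.mfc_west) * rel
            + rng.normal(0.0, config.mfc_noise_sd), 0.0, 100.0))
        fu = _forest_use(mfc)
        diet_mean = config.open_diet_mean + config.canopy_effect * fu
        pmw = float(150.0 + 8.0 * (lat - lat_lo) + rng.normal(0, 10))
        pms = float(220.0 + 6.0 * (lat - lat_lo) + rng.normal(0, 10))
        tmw = float(1.5 - 0.25 * (lon - lon_lo) + rng.normal(0, 0.5))
        tms = float(17.0 + 0.15 * (lon - lon_lo) + rng.normal(0, 0.5))
        site = Site(
            site_id=sid, name=f"Synthetic site {i + 1}",
            longitude=lon, latitude=lat, mfc=None,
            pmw=pmw, pms=pms, tmw=tmw, tms=tms,
            river_distance=float(rng.exponential(1.5)),
            strahler=int(rng.integers(1, 8)),
            drainage=drainages[int(rel * (len(drainages) - 1e-9))],
            culture="ALP" if rel > 0.9 else "LBK",
        )
        ds.sites[sid] = site
        site_rows.append({
            "site_id": sid, "longitude": lon, "latitude": lat,
            "mfc": mfc, "forest_use": fu, "diet_mean": diet_mean,
            "pmw": pmw, "pms": pms, "tmw": tmw, "tms": tms,
        })
    truth_sites = pd.DataFrame(site_rows)

    # --- bulk proxies: invert the diet offsets around each site's true mean
    for row in site_rows:
        sid = row["site_id"]
        for j in range(config.samples_per_site):
            diet = row["diet_mean"] + rng.normal(0.0, config.within_site_sd)
            ds.bulk.append(BulkSample(
                sample_id=f"{sid}-COL{j + 1:02d}", site_id=sid,
                tissue="collagen", taxon="cattle",
                d13c=diet_to_tissue(diet, "collagen", offsets),
            ))
        for j in range(config.samples_per_site):
            diet = row["diet_mean"] + rng.normal(0.0, config.within_site_sd)
            c16 = diet_to_tissue(diet, "dairy_c16", offsets)
            spacing = rng.normal(config.dairy_spacing_mean, config.dairy_spacing_sd)
            ds.bulk.append(BulkSample(
                sample_id=f"{sid}-DAI{j + 1:02d}", site_id=sid,
                tissue="dairy_c16", taxon="ruminant_dairy",
                d13c=c16, d13c_c18=c16 + float(spacing),
            ))

    # --- deer around the forest-herbivore baseline, spread across sites
    site_ids = [r["site_id"] for r in site_rows]
    for j in range(config.n_deer):
        diet = rng.normal(config.deer_diet_mean, config.deer_diet_sd)
        ds.bulk.append(BulkSample(
            sample_id=f"DEER{j + 1:03d}", site_id=site_ids[j % len(site_ids)],
            tissue="collagen", taxon="deer",
            d13c=diet_to_tissue(float(diet), "collagen", offsets),
        ))

    # --- intra-tooth series with known cosine truth and diet seasons
    tc, aa = config.tooth, config.aa
    tooth_rows, window_rows, inc_rows = [], [], []
    n_tooth_sites = min(tc.n_tooth_sites, config.n_sites)
    for si in range(n_tooth_sites):
        row = site_rows[si]
        for tj in range(tc.teeth_per_site):
            tid = f"{row['site_id']}-T{tj + 1}"
            ch = tc.crown_height
            x0 = float(rng.uniform(0.0, tc.period))
            true_model = SeasonalModel(tooth_id=tid, A=tc.amplitude, X=tc.period,
                                       x0=x0, M=tc.mean_level, rmse=0.0,
                                       n_points=tc.n_increments)
            positions = np.linspace(0.98 * ch, 0.10 * ch, tc.n_increments)
            windows = cold_season_windows(true_model,
                                          (float(positions.min()), float(positions.max())))
            cold_pos = [(w.start_pos, w.end_pos) for w in windows if w.label == "cold"]
            clock = CrownClock(crown_height=ch)
            cold_months = [
                tuple(sorted((clock.enamel_months(a), clock.enamel_months(b))))
                for a, b in cold_pos
            ]
            tooth = ToothSeries(tooth_id=tid, site_id=row["site_id"], crown_height=ch)
            bioap_base = diet_to_tissue(row["diet_mean"], "bioapatite", OffsetTable())
            for pos in positions:
                pos = float(pos)
                in_cold = any(a <= pos <= b for a, b in cold_pos)
                d18o = (tc.amplitude * np.cos(2 * np.pi * (pos - x0) / tc.period)
                        + tc.mean_level + rng.normal(0.0, tc.d18o_noise_sd))
                d13c = bioap_base + rng.normal(0.0, tc.d13c_noise_sd)
                if config.fodder_scenario == "winter_woody" and in_cold:
                    d13c -= tc.winter_pulse
                tooth.enamel.append(EnamelIncrement(tid, pos, float(d13c), float(d18o)))
                inc_rows.append({
                    "tooth_id": tid, "kind": "enamel", "position_erj": pos,
                    "months": clock.enamel_months(pos), "is_cold": in_cold,
                    "diet_class": ("woody" if config.fodder_scenario == "winter_woody"
                                   and in_cold else "herbaceous"),
                })
            dpositions = np.linspace(0.90 * ch, 0.15 * ch, tc.n_dentine)
            for pos in dpositions:
                pos = float(pos)
                months = clock.dentine_months(pos)
                in_cold = any(a <= months <= b for a, b in cold_months)
                woody = config.fodder_scenario == "winter_woody" and in_cold
                beta_true = aa.woody_beta if woody else aa.herbaceous_beta
                phe = aa.phe_baseline + rng.normal(0.0, 0.2)
                # consumer spacing = beta - trophic offset (offset is -4.0)
                glx = phe + (beta_true + 4.0) + rng.normal(0.0, aa.noise_sd)
                tooth.dentine.append(DentineIncrement(tid, pos, float(glx), float(phe)))
                inc_rows.append({
                    "tooth_id": tid, "kind": "dentine", "position_erj": pos,
                    "months": months, "is_cold": in_cold,
                    "diet_class": "woody" if woody else "herbaceous",
                })
            ds.teeth.append(tooth)
            tooth_rows.append({
                "tooth_id": tid, "site_id": row["site_id"], "crown_height": ch,
                "A": tc.amplitude, "X": tc.period, "x0": x0, "M": tc.mean_level,
            })
            for a, b in cold_pos:
                window_rows.append({"tooth_id": tid, "start_pos": a, "end_pos": b})

    truth = {
        "sites": truth_sites,
        "teeth": pd.DataFrame(tooth_rows),
        "cold_windows": pd.DataFrame(window_rows),
        "increments": pd.DataFrame(inc_rows),
    }
    grids = generate_proxy_grids(config, truth_sites,
                                 rng=np.random.default_rng(config.seed + 1))
    return World(config=config, dataset=ds, truth=truth, grids=grids)


def generate_proxy_grids(
    config: WorldConfig,
    truth_sites: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict:
    """Forest-cover grids (three time slices) + climate grids.

    Each grid holds a regular background lattice from the same linear models
    used for the truth plus one node at every site's exact coordinates with
    the site's truth value (plus ``grid_noise_sd`` noise per slice), so the
    nearest node of a site is its own node.
    """
    from .enviro_spatial import MFC_TIME_SLICES, ProxyGrid

    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    lon_lo, lon_hi = config.lon_range
    lat_lo, lat_hi = config.lat_range
    res = config.grid_resolution
    glon = np.arange(lon_lo, lon_hi + res / 2, res)
    glat = np.arange(lat_lo, lat_hi + res / 2, res)
    bg_rows = []
    for la in glat:
        for lo in glon:
            rel = (lo - lon_lo) / (lon_hi - lon_lo)
            bg_rows.append({
                "longitude": float(lo), "latitude": float(la),
                "mfc": config.mfc_west + (config.mfc_east - config.mfc_west) * rel,
                "pmw": 150.0 + 8.0 * (la - lat_lo),
                "pms": 220.0 + 6.0 * (la - lat_lo),
                "tmw": 1.5 - 0.25 * (lo - lon_lo),
                "tms": 17.0 + 0.15 * (lo - lon_lo),
            })
    bg = pd.DataFrame(bg_rows)

    grids: dict = {}
    for ts in MFC_TIME_SLICES:
        site_nodes = pd.DataFrame({
            "longitude": truth_sites["longitude"],
            "latitude": truth_sites["latitude"],
            "value": np.clip(
                truth_sites["mfc"].to_numpy()
                + rng.normal(0.0, config.grid_noise_sd, len(truth_sites)),
                0.0, 100.0),
        })
        nodes = pd.concat(
            [bg[["longitude", "latitude", "mfc"]].rename(columns={"mfc": "value"}),
             site_nodes],
            ignore_index=True,
        ).drop_duplicates(subset=["longitude", "latitude"])
        grids[f"mfc_{ts}"] = ProxyGrid(variable="mfc", nodes=nodes, time_slice=ts)
    for var in ("pmw", "pms", "tmw", "tms"):
        site_nodes = pd.DataFrame({
            "longitude": truth_sites["longitude"],
            "latitude": truth_sites["latitude"],
            "value": truth_sites[var],
        })
        nodes = pd.concat(
            [bg[["longitude", "latitude", var]].rename(columns={var: "value"}),
             site_nodes],
            ignore_index=True,
        ).drop_duplicates(subset=["longitude", "latitude"])
        grids[var] = ProxyGrid(variable=var, nodes=nodes, time_slice="7100")
    return grids


def write_world(world: World, outdir) -> dict[str, Path]:
    """Write the world through the public I/O path (the formats readers consume)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "grids").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    ds = world.dataset
    paths = {
        "sites": outdir / "sites.csv",
        "collagen": outdir / "collagen.csv",
        "dairy": outdir / "dairy.csv",
        "deer": outdir / "deer.csv",
        "enamel": outdir / "enamel.csv",
        "dentine": outdir / "dentine.csv",
    }
    isotope_io.write_sites(ds.sites.values(), paths["sites"])
    isotope_io.write_bulk_samples(ds.bulk_by_tissue("collagen", "cattle"),
                                  paths["collagen"])
    isotope_io.write_bulk_samples(ds.bulk_by_tissue("dairy_c16"), paths["dairy"])
    isotope_io.write_bulk_samples(ds.bulk_by_tissue("collagen", "deer"),
                                  paths["deer"])
    isotope_io.write_tooth_series(ds.teeth, paths["enamel"], paths["dentine"])
    for name, grid in world.grids.items():
        p = outdir / "grids" / f"{name}.csv"
        grid.nodes.to_csv(p, index=False, float_format="%.12g")
        paths[f"grid:{name}"] = p
    for name, df in world.truth.items():
        p = outdir / "truth" / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.12g")
        paths[f"truth:{name}"] = p
    cfg = dataclasses.asdict(world.config)
    (outdir / "world.yml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths["config"] = outdir / "world.yml"
    return paths


def load_world(indir) -> Dataset:
    """Read a written world back through the public readers."""
    indir = Path(indir)
    ds = Dataset()
    for s in isotope_io.read_sites(indir / "sites.csv").records:
        ds.sites[s.site_id] = s
    ds.bulk.extend(isotope_io.read_bulk_samples(indir / "collagen.csv",
                                                "collagen", "cattle").records)
    ds.bulk.extend(isotope_io.read_bulk_samples(indir / "dairy.csv",
                                                "dairy_c16", "ruminant_dairy").records)
    ds.bulk.extend(isotope_io.read_bulk_samples(indir / "deer.csv",
                                                "collagen", "deer").records)
    ds.teeth.extend(isotope_io.read_tooth_series(indir / "enamel.csv",
                                                 indir / "dentine.csv").records)
    return ds
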