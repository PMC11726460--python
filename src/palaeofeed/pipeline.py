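"""Stage orchestration: ingest -> diet -> seasonal -> csia -> spatial -> report.

Each stage reads the previous stage's tidy outputs from the run directory,
writes its own, and contributes to a JSON run report.  Every output file is
SHA-256 hashed into the report so reruns can be compared bit-for-bit; all
thresholds (dairy spacing -3.1, woody beta -7.7 via the plant reference,
baseline band k = 1, cold-season multiplier 0.5) surface in :class:`RunConfig`
and a frozen copy of the resolved configuration is written with every run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aa_csia, diet_inference, enviro_spatial, isotope_io, seasonal_model
from .datamodel import Dataset
from .diet_inference import Baseline, OffsetTable
from .enviro_spatial import IDWConfig
from .synthetic_data import load_world

__all__ = ["RunConfig", "run_pipeline", "STAGES", "default_manifest"]

log = logging.getLogger("palaeofeed")

STAGES = ("ingest", "diet", "seasonal", "csia", "spatial", "report")


def default_manifest() -> list[dict]:
    """Correlation pairs shipped as defaults.

    Bulk-sample pairs are per-sample (each measurement paired with its
    site's environmental value); amplitude and beta pairs are per-tooth.
    """
    return [
        {"pair": "mfc~d13c_coll", "table": "collagen", "x": "mfc", "y": "d13c",
         "method": "pearson"},
        {"pair": "mfc~d13c_dairy", "table": "dairy", "x": "mfc", "y": "d13c",
         "method": "pearson"},
        {"pair": "mfc~d13c_diet", "table": "combined", "x": "mfc", "y": "d13c_diet",
         "method": "pearson"},
        {"pair": "longitude~d13c_diet", "table": "combined", "x": "longitude",
         "y": "d13c_diet", "method": "pearson"},
        {"pair": "pmw~d13c_diet", "table": "combined", "x": "pmw", "y": "d13c_diet",
         "method": "pearson"},
        {"pair": "tmw~d13c_diet", "table": "combined", "x": "tmw", "y": "d13c_diet",
         "method": "pearson"},
        {"pair": "mfc~amplitude_d13c", "table": "teeth", "x": "mfc",
         "y": "amplitude_d13c", "method": "pearson"},
        {"pair": "mfc~beta_mean", "table": "teeth", "x": "mfc", "y": "beta_mean",
         "method": "spearman"},
    ]


@dataclass
class RunConfig:
    indir: str                      # directory of input tables (sites.csv, ...)
    outdir: str
    stages: tuple[str, ...] = STAGES
    grids_dir: str | None = None    # defaults to indir/grids
    offsets: OffsetTable = field(default_factory=OffsetTable)
    dairy_threshold: float = diet_inference.DAIRY_SPACING_THRESHOLD
    baseline_k: float = 1.0
    cold_k: float = 0.5
    trophic_offset: float = aa_csia.TROPHIC_OFFSET
    min_points: int = 5
    idw: IDWConfig = field(default_factory=IDWConfig)
    grid_resolution: float = 1.0
    manifest: list[dict] = field(default_factory=default_manifest)
    seed: int = 0

    def __post_init__(self):
        if tuple(self.stages) != STAGES[: len(self.stages)] or not self.stages:
            raise ValueError(
                f"stages must be a non-empty prefix of {STAGES}, got {self.stages}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "offsets" in raw:
            raw["offsets"] = OffsetTable(**raw["offsets"])
        if "idw" in raw:
            raw["idw"] = IDWConfig(**raw["idw"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return the run report.

    A stage failure halts the run with the stage name; outputs of completed
    stages are preserved on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "files": {}, "warnings": []}
    cfg_path = outdir / "run_config.yml"
    cfg_path.write_text(yaml.safe_dump(_config_dict(config), sort_keys=True))
    report["files"]["run_config.yml"] = _sha256(cfg_path)

    state: dict = {}
    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _STAGE_FUNCS[stage](config, state, report, outdir)
            for w in caught:
                report["warnings"].append(f"{stage}: {w.message}")
        except Exception as exc:
            report["failed_stage"] = stage
            report["error"] = str(exc)
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    report["files"]["report.json"] = "(self)"
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stages"] = list(config.stages)
    d["idw"]["power_candidates"] = list(config.idw.power_candidates)
    return d


def _stage_ingest(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    ds = load_world(config.indir)
    validation = isotope_io.validate_dataset(ds)
    vpath = outdir / "validation.json"
    vpath.write_text(json.dumps(validation, indent=2))
    report["files"]["validation.json"] = _sha256(vpath)
    report["stages"]["ingest"] = {
        k: validation[k] for k in
        ("n_sites", "n_bulk", "n_teeth", "n_enamel_increments",
         "n_dentine_increments", "n_measurements", "n_failures")
    }
    state["dataset"] = ds


def _stage_diet(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    ds: Dataset = state["dataset"]
    cattle_bulk = [s for s in ds.bulk if s.taxon != "deer"]
    estimates = diet_inference.estimate_diets(cattle_bulk, config.offsets)
    deer = ds.bulk_by_tissue("collagen", "deer")
    baseline = diet_inference.build_forest_baseline(deer, config.offsets)
    calls = [
        diet_inference.classify_dairy_extract(s.sample_id, s.d13c, s.d13c_c18,
                                              config.dairy_threshold)
        for s in ds.bulk_by_tissue("dairy_c16")
    ]
    est_df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])
    est_df["vs_baseline"] = [
        diet_inference.classify_vs_baseline(e.d13c_diet, baseline, config.baseline_k)
        for e in estimates
    ]
    summary = diet_inference.summarize_by_dataset(estimates, cattle_bulk)
    report["files"]["diet_estimates.csv"] = _sha256(
        _write_csv(est_df, outdir / "diet_estimates.csv"))
    report["files"]["diet_summary.csv"] = _sha256(
        _write_csv(summary, outdir / "diet_summary.csv"))
    report["files"]["dairy_calls.csv"] = _sha256(_write_csv(
        pd.DataFrame([dataclasses.asdict(c) for c in calls]),
        outdir / "dairy_calls.csv"))
    bpath = outdir / "baseline.json"
    bpath.write_text(json.dumps(dataclasses.asdict(baseline), indent=2))
    report["files"]["baseline.json"] = _sha256(bpath)
    report["stages"]["diet"] = {
        "n_estimates": len(estimates),
        "baseline": dataclasses.asdict(baseline),
        "n_dairy_calls": sum(1 for c in calls if c.call == "dairy"),
        "summary": summary.to_dict(orient="records"),
    }
    state.update(estimates=estimates, baseline=baseline, summary=summary)


def _stage_seasonal(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    ds: Dataset = state["dataset"]
    models, mrows, arows, wrows = {}, [], [], []
    for tooth in ds.teeth:
        if len(tooth.enamel) >= 2:
            arows.append({
                "tooth_id": tooth.tooth_id, "site_id": tooth.site_id,
                "amplitude_d13c": seasonal_model.tooth_amplitude(
                    [e.d13c_bioap for e in tooth.enamel]),
            })
        if len(tooth.enamel) < config.min_points:
            warnings.warn(f"tooth {tooth.tooth_id}: too few enamel points; no fit")
            continue
        try:
            model = seasonal_model.fit_tooth(tooth)
        except ValueError as exc:
            warnings.warn(f"tooth {tooth.tooth_id}: cosine fit failed: {exc}")
            continue
        models[tooth.tooth_id] = model
        mrows.append(dataclasses.asdict(model))
        pos = [e.position_erj for e in tooth.enamel]
        for w in seasonal_model.cold_season_windows(
                model, (min(pos), max(pos)), k=config.cold_k):
            wrows.append(dataclasses.asdict(w))
    report["files"]["seasonal_models.csv"] = _sha256(
        _write_csv(pd.DataFrame(mrows), outdir / "seasonal_models.csv"))
    report["files"]["amplitudes.csv"] = _sha256(
        _write_csv(pd.DataFrame(arows), outdir / "amplitudes.csv"))
    report["files"]["season_windows.csv"] = _sha256(
        _write_csv(pd.DataFrame(wrows), outdir / "season_windows.csv"))
    report["stages"]["seasonal"] = {"n_models": len(models), "n_amplitudes": len(arows)}
    state.update(models=models, amplitudes=pd.DataFrame(arows))


def _stage_csia(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    ds: Dataset = state["dataset"]
    models = state.get("models", {})
    betas, aligned_rows = {}, []
    for tooth in ds.teeth:
        if not tooth.dentine:
            continue
        betas[tooth.tooth_id] = aa_csia.beta_values_for_tooth(
            tooth, config.trophic_offset)
        profile = aa_csia.align_profiles(
            tooth, model=models.get(tooth.tooth_id),
            trophic_offset=config.trophic_offset, cold_k=config.cold_k)
        rows = profile.rows.copy()
        rows.insert(0, "tooth_id", tooth.tooth_id)
        aligned_rows.append(rows)
    beta_df = pd.DataFrame([
        dataclasses.asdict(b) for bs in betas.values() for b in bs
    ])
    aligned = (pd.concat(aligned_rows, ignore_index=True)
               if aligned_rows else pd.DataFrame())
    summary = aa_csia.tooth_beta_summary(betas)
    report["files"]["beta_values.csv"] = _sha256(
        _write_csv(beta_df, outdir / "beta_values.csv"))
    report["files"]["aligned_profiles.csv"] = _sha256(
        _write_csv(aligned, outdir / "aligned_profiles.csv"))
    report["files"]["beta_summary.csv"] = _sha256(
        _write_csv(summary, outdir / "beta_summary.csv"))
    report["stages"]["csia"] = {
        "n_teeth_with_beta": len(betas),
        "n_woody_calls": int((beta_df["call"] == "woody").sum()) if len(beta_df) else 0,
    }
    state.update(beta_summary=summary, aligned=aligned)


def _load_grids(config: RunConfig) -> dict:
    from .enviro_spatial import ProxyGrid

    gdir = Path(config.grids_dir) if config.grids_dir else Path(config.indir) / "grids"
    grids = {}
    if gdir.is_dir():
        for p in sorted(gdir.glob("*.csv")):
            nodes = pd.read_csv(p)
            name = p.stem
            grids[name] = ProxyGrid(variable=name.split("_")[0], nodes=nodes,
                                    time_slice=name.split("_")[-1])
    return grids


def _stage_spatial(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    ds: Dataset = state["dataset"]
    grids = _load_grids(config)
    mfc_grids = {name.split("_")[1]: g for name, g in grids.items()
                 if name.startswith("mfc_")}
    if mfc_grids:
        for site in ds.sites.values():
            site.mfc = enviro_spatial.mean_forest_cover_at_site(site, mfc_grids)

    site_df = pd.DataFrame([
        {k: v for k, v in dataclasses.asdict(s).items() if k != "extra"}
        for s in ds.sites.values()
    ])
    report["files"]["sites_enriched.csv"] = _sha256(
        _write_csv(site_df, outdir / "sites_enriched.csv"))

    env = site_df.set_index("site_id")
    estimates = state.get("estimates", [])
    est_df = pd.DataFrame([dataclasses.asdict(e) for e in estimates])

    def with_env(df: pd.DataFrame) -> pd.DataFrame:
        return df.join(env[["longitude", "latitude", "mfc", "pmw", "pms",
                            "tmw", "tms"]], on="site_id")

    tables: dict[str, pd.DataFrame] = {}
    raw = {s.sample_id: s.d13c for s in ds.bulk}
    if len(est_df):
        est_df["d13c"] = est_df["sample_id"].map(raw)
        tables["collagen"] = with_env(est_df[est_df.tissue == "collagen"])
        tables["dairy"] = with_env(est_df[est_df.tissue == "dairy_c16"])
        # combined diet dataset: collagen + dairy per sample, plus per-tooth
        # bioapatite max and min converted to the diet scale (two records per
        # tooth, matching the per-tooth extremes convention)
        bio_rows = []
        for tooth in ds.teeth:
            if not tooth.enamel:
                continue
            vals = [e.d13c_bioap for e in tooth.enamel]
            for stat, v in (("max", max(vals)), ("min", min(vals))):
                bio_rows.append({
                    "sample_id": f"{tooth.tooth_id}:{stat}",
                    "site_id": tooth.site_id, "tissue": "bioapatite",
                    "d13c": v,
                    "d13c_diet": diet_inference.tissue_to_diet(
                        v, "bioapatite", config.offsets),
                })
        combined = pd.concat(
            [est_df[["sample_id", "site_id", "tissue", "d13c", "d13c_diet"]],
             pd.DataFrame(bio_rows)],
            ignore_index=True)
        tables["combined"] = with_env(combined)

    teeth_tbl = state.get("amplitudes", pd.DataFrame())
    beta_sum = state.get("beta_summary", pd.DataFrame())
    if len(teeth_tbl):
        if len(beta_sum):
            teeth_tbl = teeth_tbl.merge(beta_sum, on="tooth_id", how="left")
        tables["teeth"] = with_env(teeth_tbl)

    corr = enviro_spatial.correlation_screen(tables, config.manifest)
    report["files"]["correlations.csv"] = _sha256(
        _write_csv(corr, outdir / "correlations.csv"))

    anova = None
    if "combined" in tables:
        groups = [g["d13c_diet"].to_numpy()
                  for _, g in tables["combined"].groupby("tissue")]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            anova = enviro_spatial.anova_oneway(groups)

    isoscape = None
    if "collagen" in tables and tables["collagen"]["site_id"].nunique() >= 3:
        sv = tables["collagen"].rename(columns={"d13c_diet": "value"})[
            ["site_id", "longitude", "latitude", "value"]]
        lon_r = (sv.longitude.min() - 0.5, sv.longitude.max() + 0.5)
        lat_r = (sv.latitude.min() - 0.5, sv.latitude.max() + 0.5)
        grid, power, rmse = enviro_spatial.build_isoscape(
            sv, lon_r, lat_r, resolution=config.grid_resolution, config=config.idw)
        report["files"]["isoscape_collagen.csv"] = _sha256(
            _write_csv(grid.nodes, outdir / "isoscape_collagen.csv"))
        isoscape = {"power": power, "rmse": rmse}

    report["stages"]["spatial"] = {
        "n_correlations": len(corr),
        "correlations": corr.to_dict(orient="records"),
        "anova_diet_datasets": anova,
        "isoscape": isoscape,
    }
    state.update(correlations=corr, tables=tables, anova=anova)


def _stage_report(config: RunConfig, state: dict, report: dict, outdir: Path) -> None:
    baseline: Baseline | None = state.get("baseline")
    report["stages"]["report"] = {
        "seed": config.seed,
        "baseline": dataclasses.asdict(baseline) if baseline else None,
        "n_files": len(report["files"]),
    }


_STAGE_FUNCS = {
    "ingest": _stage_ingest,
    "diet": _stage_diet,
    "seasonal": _stage_seasonal,
    "csia": _stage_csia,
    "spatial": _stage_spatial,
    "report": _stage_report,
}
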