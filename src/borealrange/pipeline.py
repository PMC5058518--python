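"""Run configuration and stage orchestration for reproducible pipeline runs.

Each stage reads its inputs from the run directory, writes its outputs
there, and records a manifest (stage name, SHA-256 of the canonical config,
seed, package version, output file list) so any artifact is traceable to a
config hash.  Deterministic stages are bit-identical under the same config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import attribute, summarize_attribution
from .climate import WinterSpec, annual_index_table, annual_series, fit_trend
from .forecast import ForecastScenario, forecast_decade, range_change
from .io import (
    read_climate_table,
    read_events,
    read_raster,
    write_climate_table,
    write_events,
    write_raster,
)
from .landscape import DecadalLandscape, GridSpec, assemble_landscape
from .sdm import SDMCoefficients, classify, predict_probability, PredictionGrid
from .synthetic import (
    LanduseGrowth,
    SnowProcess,
    SyntheticConfig,
    generate_climate,
    generate_landcover,
    generate_landuse_history,
    sample_observations,
)
from .validation import ValidationSet, validate

logger = logging.getLogger("borealrange")

__all__ = ["RunConfig", "run", "STAGES"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to/from YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    decades: list[int] = field(default_factory=lambda: [1970, 1980, 1990, 2000])
    wsi_base_year: int = 1961
    gs_base_year: int = 1950
    threshold: float = 0.73
    coefficients: list[float] = field(
        default_factory=lambda: SDMCoefficients().as_array().tolist()
    )
    winter: dict = field(default_factory=dict)  # WinterSpec overrides
    include_undated_cuts: bool = True
    cutblock_age_limit: int = 30
    n_validation_sites: int = 60
    validation_decade: int | None = None
    forecast_base_decade: int | None = None
    forecast_decades: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def grid(self) -> GridSpec:
        return self.synthetic.grid

    @property
    def coef(self) -> SDMCoefficients:
        return SDMCoefficients.from_array(self.coefficients)

    @property
    def winter_spec(self) -> WinterSpec:
        return WinterSpec(**self.winter)

    def to_dict(self) -> dict:
        d = asdict(self)
        trend = d["synthetic"]["climate_trend_wsi"]
        if isinstance(trend, np.ndarray):
            d["synthetic"]["climate_trend_wsi"] = trend.tolist()
        trend = d["synthetic"]["climate_trend_gs"]
        if isinstance(trend, np.ndarray):
            d["synthetic"]["climate_trend_gs"] = trend.tolist()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        syn = dict(data.pop("synthetic", {}))
        if "snow_process" in syn:
            syn["snow_process"] = SnowProcess(**syn["snow_process"])
        if "landuse_growth" in syn:
            lg = dict(syn["landuse_growth"])
            if "ag_epochs" in lg:
                lg["ag_epochs"] = {int(k): float(v) for k, v in lg["ag_epochs"].items()}
            syn["landuse_growth"] = LanduseGrowth(**lg)
        data["synthetic"] = SyntheticConfig(**syn)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        return cls.from_dict(yaml.safe_load(path.read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def demo(cls, seed: int = 0) -> "RunConfig":
        """Small fast configuration exercising every stage end to end."""
        syn = SyntheticConfig(
            grid_rows=8,
            grid_cols=5,
            start_year=1995,
            end_year=2014,
            seed=seed,
            landuse_growth=LanduseGrowth(
                wells_per_year=4.0, cuts_per_year=3.0, ag_epochs={1996: 0.2, 2006: 0.3}
            ),
        )
        return cls(
            synthetic=syn,
            decades=[2000, 2010],
            wsi_base_year=1995,
            gs_base_year=1995,
            validation_decade=2010,
            forecast_base_decade=2010,
            forecast_decades=[2020, 2030],
        )


def _manifest(cfg: RunConfig, outdir: Path, stage: str, outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "config_sha256": cfg.config_hash(),
        "seed": cfg.synthetic.seed,
        "version": __version__,
        "outputs": sorted(outputs),
    }
    (outdir / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _require(outdir: Path, name: str, stage: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"{stage}: missing input {path}; run the producing stage first"
        )
    return path


def run_simulate(cfg: RunConfig, outdir: Path) -> list[str]:
    climate = generate_climate(cfg.synthetic)
    write_climate_table(outdir / "climate.csv", climate)
    events = generate_landuse_history(cfg.synthetic)
    names = ["climate.csv", "landcover.csv", *write_events(outdir, events)]
    generate_landcover(cfg.synthetic).to_csv(outdir / "landcover.csv", index=False)
    return names


def run_indices(cfg: RunConfig, outdir: Path) -> list[str]:
    climate = read_climate_table(_require(outdir, "climate.csv", "indices"))
    syn = cfg.synthetic
    table = annual_index_table(
        climate,
        winters=range(syn.start_year, syn.end_year),
        gs_years=range(syn.start_year, syn.end_year + 1),
        spec=cfg.winter_spec,
    )
    table.to_csv(outdir / "annual_indices.csv", index=False)
    return ["annual_indices.csv"]


def _load_landscape(cfg: RunConfig, outdir: Path, decade: int) -> DecadalLandscape:
    path = _require(outdir, f"landscape_{decade}.csv", "hindcast")
    frame = pd.read_csv(path).set_index("cell_id")
    return DecadalLandscape(decade, frame)


def run_landscape(cfg: RunConfig, outdir: Path) -> list[str]:
    events = read_events(outdir)
    landcover = pd.read_csv(_require(outdir, "landcover.csv", "landscape"))
    indices = pd.read_csv(_require(outdir, "annual_indices.csv", "landscape"))
    names = []
    for decade in cfg.decades:
        landscape = assemble_landscape(
            cfg.grid,
            events,
            landcover,
            indices,
            decade,
            wsi_base_year=cfg.wsi_base_year,
            gs_base_year=cfg.gs_base_year,
            include_undated_cuts=cfg.include_undated_cuts,
            cutblock_age_limit=cfg.cutblock_age_limit,
        )
        name = f"landscape_{decade}.csv"
        landscape.frame.to_csv(outdir / name, index_label="cell_id")
        names.append(name)
    return names


def run_hindcast(cfg: RunConfig, outdir: Path) -> list[str]:
    names = []
    for decade in cfg.decades:
        landscape = _load_landscape(cfg, outdir, decade)
        grid = predict_probability(landscape, cfg.coef)
        presence = classify(grid, cfg.threshold)
        write_raster(outdir / f"probability_{decade}.txt", grid.probability, cfg.grid, "probability")
        write_raster(
            outdir / f"presence_{decade}.txt", presence.astype(float), cfg.grid, "presence"
        )
        names += [f"probability_{decade}.txt", f"presence_{decade}.txt"]
    return names


def run_attribute(cfg: RunConfig, outdir: Path) -> list[str]:
    names = []
    for prev_d, curr_d in zip(cfg.decades[:-1], cfg.decades[1:]):
        prev = _load_landscape(cfg, outdir, prev_d)
        curr = _load_landscape(cfg, outdir, curr_d)
        attr = attribute(prev, curr, cfg.coef, cfg.threshold)
        name = f"attribution_{prev_d}_{curr_d}"
        attr.frame.to_csv(outdir / f"{name}.csv", index_label="cell_id")
        summary = summarize_attribution(attr)
        summary["decade_pair"] = list(summary["decade_pair"])

        def _jsonable(obj):
            if isinstance(obj, dict):
                return {k: _jsonable(v) for k, v in obj.items()}
            if isinstance(obj, float) and not np.isfinite(obj):
                return None
            return obj

        (outdir / f"{name}_summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
        )
        names += [f"{name}.csv", f"{name}_summary.json"]
    return names


def run_validate(cfg: RunConfig, outdir: Path) -> list[str]:
    decade = cfg.validation_decade or cfg.decades[-1]
    prob, _ = read_raster(_require(outdir, f"probability_{decade}.txt", "validate"))
    pred = PredictionGrid(decade, pd.DataFrame({"probability": prob}))
    obs = sample_observations(
        pred,
        n_sites=min(cfg.n_validation_sites, cfg.grid.n_cells),
        detection_prob=cfg.synthetic.detection_prob,
        seed=cfg.synthetic.seed + 101,
    )
    vs = ValidationSet(
        pd.DataFrame(
            {
                "cell_id": obs["cell_id"],
                "observed": obs["presence"],
                "probability": prob.loc[obs["cell_id"]].to_numpy(),
            }
        )
    )
    stats = validate(vs, cfg.threshold, seed=cfg.synthetic.seed + 202)
    stats.to_frame().to_csv(outdir / f"validation_{decade}.csv", index=False)
    return [f"validation_{decade}.csv"]


def run_forecast(cfg: RunConfig, outdir: Path) -> list[str]:
    base = cfg.forecast_base_decade or cfg.decades[-1]
    targets = cfg.forecast_decades or [base + 10]
    indices = pd.read_csv(_require(outdir, "annual_indices.csv", "forecast"))
    base_landscape = _load_landscape(cfg, outdir, base)
    wsi = indices.dropna(subset=["wsi"])
    gs = indices.dropna(subset=["gs"])
    wsi_trends = {
        c: fit_trend(annual_series(wsi, c, "wsi")) for c in cfg.grid.cell_ids
    }
    gs_trends = {c: fit_trend(annual_series(gs, c, "gs")) for c in cfg.grid.cell_ids}
    scenario = ForecastScenario(
        base_decade=base,
        base_landscape=base_landscape,
        wsi_annual=wsi,
        gs_annual=gs,
        wsi_trends=wsi_trends,
        gs_trends=gs_trends,
        wsi_base_year=cfg.wsi_base_year,
        gs_base_year=cfg.gs_base_year,
    )
    base_grid, base_presence = forecast_decade(scenario, base, cfg.coef, cfg.threshold)
    names = []
    changes = {}
    for decade in targets:
        grid, presence = forecast_decade(scenario, decade, cfg.coef, cfg.threshold)
        write_raster(
            outdir / f"forecast_probability_{decade}.txt", grid.probability, cfg.grid, "probability"
        )
        write_raster(
            outdir / f"forecast_presence_{decade}.txt", presence.astype(float), cfg.grid, "presence"
        )
        rc = range_change(base_presence, presence, cfg.grid.cell_area_km2)
        changes[str(decade)] = {
            "gained_km2": rc.gained_km2,
            "lost_km2": rc.lost_km2,
            "net_km2": rc.net_km2,
        }
        names += [f"forecast_probability_{decade}.txt", f"forecast_presence_{decade}.txt"]
    (outdir / "forecast_range_change.json").write_text(
        json.dumps({"base_decade": base, "changes": changes}, indent=2, sort_keys=True) + "\n"
    )
    return names + ["forecast_range_change.json"]


STAGES = {
    "simulate": run_simulate,
    "indices": run_indices,
    "landscape": run_landscape,
    "hindcast": run_hindcast,
    "attribute": run_attribute,
    "validate": run_validate,
    "forecast": run_forecast,
}


def run(cfg: RunConfig, stage: str, outdir) -> list[str]:
    """Execute one pipeline stage, writing outputs and a manifest."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage %s -> %s (config %s)", stage, outdir, cfg.config_hash()[:12])
    outputs = STAGES[stage](cfg, outdir)
    _manifest(cfg, outdir, stage, outputs)
    logger.info("stage %s wrote %d artifacts", stage, len(outputs))
    return outputs
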