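"""End-to-end orchestration: simulate/read -> residence -> events -> panel -> model.

A run is described by one declarative config (YAML-friendly nested dict).
Every artifact is written as headered CSV (or JSON for the fit) with a
provenance header recording the package version, the config hash and the
seed, so a rerun with the same config and seed reproduces identical panels
and -- for a fixed lambda policy -- identical fits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, events, gamm, panel, residence, synthesize
from .synthesize import CorpusValidationError, GdpModel, HazardSpec, SimConfig

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_config", "default_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration.

    When ``simulate`` is set, the corpus is generated synthetically;
    otherwise ``input_dir`` must hold ``publications.csv`` and
    ``covariates.csv``.
    """

    out_dir: str = "run_out"
    input_dir: str | None = None
    simulate: SimConfig | None = field(default_factory=SimConfig)
    top_n: int = 100
    min_population: float = 500_000.0
    family: str = "poisson"
    k: int = 10
    lambdas: dict[str, float] | str = "auto"
    grid_points: int = 400
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file with nested simulate/hazard sections."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    sim = raw.pop("simulate", "default")
    if sim is None:
        sim_cfg = None
    elif sim == "default":
        sim_cfg = SimConfig()
    else:
        sim = dict(sim)
        hazard = HazardSpec(**sim.pop("hazard")) if "hazard" in sim else HazardSpec()
        gdp = GdpModel(**sim.pop("gdp")) if "gdp" in sim else GdpModel()
        sim_cfg = SimConfig(hazard=hazard, gdp=gdp, **sim)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(simulate=sim_cfg, **raw)


def _provenance(config: RunConfig) -> dict:
    return {
        "generator": f"scholarmigrate {__version__}",
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def _write_csv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("".join(f"# {k}: {v}\n" for k, v in header.items()))
        df.to_csv(fh, index=False)


def validate_inputs(input_dir) -> dict:
    """Schema/code/range checks on an input corpus directory.

    Returns ``{"errors": {...per-file lists...}, "ok": bool}`` without
    raising, so callers can render a report and pick an exit code.
    """
    input_dir = Path(input_dir)
    report: dict = {"errors": {}, "ok": True}
    for name in ("publications.csv", "covariates.csv"):
        if not (input_dir / name).exists():
            report["errors"].setdefault(name, []).append("file not found")
    if report["errors"]:
        report["ok"] = False
        return report
    try:
        pubs = synthesize._read_table(input_dir / "publications.csv", synthesize.PUBLICATIONS_COLUMNS)
        cov = synthesize._read_table(input_dir / "covariates.csv", synthesize.COVARIATES_COLUMNS)
    except CorpusValidationError as exc:
        report["errors"]["parse"] = exc.errors
        report["ok"] = False
        return report
    errors = synthesize.validate_corpus(pubs, cov)
    if errors:
        report["errors"]["corpus"] = errors
        report["ok"] = False
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> residence -> events -> panel -> fit -> turning point.

    Returns the run report (also written as ``report.json``): panel summary,
    fit summary, turning point and the file manifest. With zero detected
    events the model stage is skipped with an explanatory message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    manifest: list[str] = []
    report: dict = {"provenance": prov, "stages": {}}
    t_start = time.perf_counter()

    def _stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t_start)

    try:
        if config.simulate is not None:
            _stage("simulate")
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            pubs, cov, truth = synthesize.generate_corpus(sim)
            synthesize.write_corpus(pubs, cov, out, truth_events=truth, header=prov)
            manifest += ["publications.csv", "covariates.csv", "truth_events.csv"]
        else:
            _stage("load")
            if config.input_dir is None:
                raise ValueError("config needs either a simulate section or input_dir")
            pubs, cov, truth = synthesize.read_corpus(config.input_dir)
        report["stages"]["corpus"] = {
            "publications": int(len(pubs)),
            "scholars": int(pubs["scholar_id"].nunique()),
            "countries": int(cov["country"].nunique()),
        }

        _stage("residence")
        timelines = residence.assign_residence_all(pubs)
        _stage("events")
        ev = events.detect_events_all(timelines)
        _write_csv(ev, out / "events.csv", prov)
        manifest.append("events.csv")
        report["stages"]["events"] = {"n_events": int(len(ev))}

        _stage("panel")
        pan = panel.build_panel(timelines, ev, cov)
        pan = panel.filter_countries(pan, top_n=config.top_n, min_population=config.min_population)
        _write_csv(pan, out / "panel.csv", prov)
        manifest.append("panel.csv")
        report["stages"]["panel"] = {
            "rows": int(len(pan)),
            "countries": int(pan["country"].nunique()),
            "mean_rate_per_1000": float(pan["rate_per_1000"].mean()),
        }

        if len(ev) == 0:
            report["turning_point"] = None
            report["stages"]["model"] = {
                "skipped": "no migration events detected; nothing to model"
            }
        else:
            _stage("fit")
            frame = panel.to_model_frame(pan)
            design = gamm.build_design(frame, k=config.k)
            fit = gamm.fit(design, family=config.family, lambdas=config.lambdas)
            (out / "fit.json").write_text(gamm.fit_to_json(fit))
            manifest.append("fit.json")
            _stage("marginal")
            curve = gamm.predict_marginal(
                fit, gamm.default_gdp_grid(fit, config.grid_points)
            )
            _write_csv(curve, out / "curve.csv", prov)
            manifest.append("curve.csv")
            tp = gamm.find_turning_point(curve)
            report["turning_point"] = tp
            report["stages"]["model"] = {
                "deviance": fit.deviance,
                "edf": fit.edf,
                "n_obs": int(design.n),
                "lambdas": fit.lambdas,
            }
    except Exception as exc:
        stage = list(report["stages"])[-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    report["manifest"] = manifest
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
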