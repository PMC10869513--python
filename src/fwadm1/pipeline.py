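"""End-to-end runs from one layered YAML config, with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets
from .balance import platform_balance
from .calibration import MethaneCalibration, sensitivity_scan
from .feed import FeedSpec, fractionate
from .io import (file_sha256, load_characterization, load_timeseries,
                 save_timeseries)
from .params import default_params
from .reactor import ReactorConfig, daily_series, run_bmp, run_cstr, smp
from .synth import gen_observed_campaign

log = logging.getLogger("fwadm1")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunManifest:
    """Everything needed to re-run: inputs, hashes, seed, outcomes."""

    config: dict
    seed: int | None
    version: str = __version__
    input_hashes: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages: dict[str, str] = field(default_factory=dict)
    results: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=float))


def _resolve_char(spec: dict, manifest: RunManifest):
    src = spec.get("characterization", "pretreated_solid_residue")
    if isinstance(src, str) and Path(src).exists():
        manifest.input_hashes[src] = file_sha256(src)
        return load_characterization(src, stream=spec.get("stream"))
    return datasets.characterization(src)


def _build_feed(spec: dict, manifest: RunManifest) -> FeedSpec:
    char = _resolve_char(spec, manifest)
    ratio = spec.get("cod_vs_ratio") or char.cod_tot / char.vs
    return fractionate(char, ratio, spec.get("f_xi", 0.12),
                       f_si=spec.get("f_si", 0.0))


def _reactor_config(spec: dict) -> ReactorConfig:
    known = {k: v for k, v in (spec or {}).items()
             if k in ReactorConfig.__dataclass_fields__}
    if "calendar" in known:
        known["calendar"] = tuple(known["calendar"])
    return ReactorConfig(**known)


def run_pipeline(config: dict | str | Path,
                 outdir: str | Path | None = None) -> RunManifest:
    """Execute the configured stage chain and write outputs + manifest.

    Modes: `simulate`, `bmp`, `calibrate`, `sensitivity`, `balance`,
    `synth`, `synth_calibrate` (generate a campaign, then recover its
    parameters).  Any stage error aborts with the stage name; the partial
    manifest is still written.
    """
    if not isinstance(config, dict):
        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(f"config file {path} does not exist")
        raw = yaml.safe_load(path.read_text())
    else:
        raw = dict(config)
    mode = raw.get("mode", "simulate")
    seed = raw.get("seed")
    out = Path(outdir or raw.get("outdir", "fwadm1_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=raw, seed=seed)

    def emit(name: str, writer) -> Path:
        p = out / name
        writer(p)
        manifest.outputs[name] = file_sha256(p)
        return p

    try:
        if mode in ("simulate", "bmp", "sensitivity", "calibrate",
                    "synth", "synth_calibrate"):
            cfg = _reactor_config(raw.get("reactor", {}))
            feed = _build_feed(raw.get("feed", {}), manifest)
            params = default_params(cfg.temperature)
            for k, v in (raw.get("params") or {}).items():
                params = params.replace(**{k: v})

        if mode == "simulate":
            res = run_cstr(cfg, feed, params)
            daily = daily_series(res)
            emit("daily_methane.csv", lambda p: pd.DataFrame(
                {"day": np.arange(daily.size), "methane_nl": daily}
            ).to_csv(p, index=False))
            emit("trajectory.csv",
                 lambda p: res.to_frame().iloc[::10].to_csv(p, index=False))
            manifest.results["smp"] = smp(res)
            manifest.results["cod_closure"] = res.cod_balance()["closure"]
            manifest.stages["simulate"] = "ok"

        elif mode == "bmp":
            bmp = run_bmp(feed, si_ratio=raw.get("si_ratio", 0.5),
                          horizon=raw.get("horizon", 80.0), params=params)
            emit("bmp_net_methane.csv", lambda p: pd.DataFrame(
                {"time_d": bmp.test.t,
                 "net_methane_nl": bmp.net_methane_nl()}
            ).to_csv(p, index=False))
            manifest.results["net_smp"] = bmp.net_smp()
            manifest.stages["bmp"] = "ok"

        elif mode == "sensitivity":
            ranges = {k: tuple(v) for k, v in raw["ranges"].items()}
            df = sensitivity_scan(params, ranges, cfg, feed,
                                  window=tuple(raw["window"])
                                  if raw.get("window") else None)
            emit("sensitivity.csv", lambda p: df.to_csv(p, index=False))
            manifest.results["ranking"] = list(df.parameter)
            manifest.stages["sensitivity"] = "ok"

        elif mode in ("calibrate", "synth_calibrate"):
            if mode == "synth_calibrate":
                truth = raw.get("truth", {"k_dis": 1.0, "f_xi": 0.2})
                camp = gen_observed_campaign(
                    (truth["k_dis"], truth["f_xi"]), cfg,
                    _resolve_char(raw.get("feed", {}), manifest),
                    noise_cv=raw.get("noise_cv", 0.05),
                    stock_cv=raw.get("stock_cv", 0.05),
                    seed=seed or 0, params=params)
                obs = camp.observed
                emit("synthetic_series.csv",
                     lambda p: save_timeseries(obs, p))
                emit("synthetic_spec.json", lambda p: Path(p).write_text(
                    json.dumps(camp.spec(), indent=2)))
                manifest.results["truth"] = camp.truth
            else:
                obs_path = raw["observed"]
                manifest.input_hashes[obs_path] = file_sha256(obs_path)
                obs = load_timeseries(obs_path)
            if raw.get("window"):
                obs = obs.window(*raw["window"])
            grid = raw.get("grid", {})
            model = MethaneCalibration(
                obs, cfg, feed, params=params,
                k_dis_grid=np.asarray(grid["k_dis"])
                if "k_dis" in grid else None,
                f_xi_grid=np.asarray(grid["f_xi"])
                if "f_xi" in grid else None)
            fit = model.fit()
            emit("calibration_scores.csv",
                 lambda p: fit.scores.to_csv(p, index=False))
            emit("calibration_summary.json", lambda p: Path(p).write_text(
                json.dumps({"k_dis": fit.k_dis, "f_xi": fit.f_xi,
                            "best": fit.best}, indent=2, default=float)))
            manifest.results["k_dis"] = fit.k_dis
            manifest.results["f_xi"] = fit.f_xi
            manifest.stages[mode] = "ok"

        elif mode == "synth":
            truth = raw.get("truth", {"k_dis": 1.0, "f_xi": 0.2})
            camp = gen_observed_campaign(
                (truth["k_dis"], truth["f_xi"]), cfg,
                _resolve_char(raw.get("feed", {}), manifest),
                noise_cv=raw.get("noise_cv", 0.05),
                stock_cv=raw.get("stock_cv", 0.05), seed=seed or 0,
                params=params)
            emit("synthetic_series.csv",
                 lambda p: save_timeseries(camp.observed, p))
            emit("synthetic_spec.json", lambda p: Path(p).write_text(
                json.dumps(camp.spec(), indent=2)))
            manifest.stages["synth"] = "ok"

        elif mode == "balance":
            chars = datasets.characterizations()
            bspec = raw.get("balance", {})
            sheets = platform_balance(
                chars["raw_fw"],
                (chars["raw_solid_residue"], chars["raw_liquid_extract"]),
                (chars["pretreated_solid_residue"],
                 chars["pretreated_liquid_extract"]),
                bspec.get("yields", {}),
                bspec.get("smp", {"raw": 0.33, "pretreated": 0.33}))
            for name, sheet in sheets.items():
                emit(f"balance_{name}.csv",
                     lambda p, s=sheet: s.to_csv(p))
                manifest.results[f"{name}_residuals"] = sheet.residuals
                manifest.results[f"{name}_products"] = \
                    sheet.total_products()
            manifest.stages["balance"] = "ok"

        else:
            raise ValueError(f"unknown pipeline mode {mode!r}")

    except Exception as err:  # noqa: BLE001 - re-raised with stage context
        stage = mode
        manifest.stages[stage] = f"failed: {err}"
        manifest.write(out / "manifest.json")
        if isinstance(err, StageError):
            raise
        raise StageError(stage, err) from err

    manifest.write(out / "manifest.json")
    return manifest
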