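"""Workbench IO, pipeline orchestration and the command line."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import fwadm1 as fw
from fwadm1 import datasets
from fwadm1.cli import main
from fwadm1.io import (SchemaError, load_characterization, load_timeseries,
                       save_characterization, save_timeseries)
from fwadm1.objectives import ObservedSeries
from fwadm1.pipeline import StageError, run_pipeline


def test_shipped_characterizations_match_assays():
    chars = datasets.characterizations()
    pre = chars["pretreated_solid_residue"]
    assert pre.cod_tot == 151.0
    assert pre.cod_sol == 40.0
    assert chars["raw_fw"].cod_tot == 249.0
    assert chars["raw_solid_residue"].cod_tot == 212.0
    assert pre.uncertainties["cod_tot"] == 14.0


def test_characterization_round_trip(tmp_path, raw_char):
    path = tmp_path / "chars.csv"
    save_characterization(raw_char, path)
    loaded = load_characterization(path, stream=raw_char.name)
    assert loaded.as_dict() == raw_char.as_dict()
    assert loaded.uncertainties == raw_char.uncertainties


def test_characterization_schema_errors(tmp_path):
    empty = tmp_path / "empty.csv"
    empty.write_text("")
    with pytest.raises(SchemaError, match="empty"):
        load_characterization(empty)
    bad = tmp_path / "bad.csv"
    bad.write_text("stream,ts,vs\nx,1,2\n")
    with pytest.raises(SchemaError, match="missing columns"):
        load_characterization(bad)
    neg = tmp_path / "neg.csv"
    neg.write_text(
        "stream,ts,vs,cod_tot,cod_sol,carb_tot,carb_sol,prot_tot,prot_sol,"
        "lipids,starch,lignocellulosics\nx,10,9,5,6,1,0,1,0,0,0,0\n")
    with pytest.raises(SchemaError, match="row 0"):
        load_characterization(neg)


def test_timeseries_round_trip_and_errors(tmp_path):
    obs = ObservedSeries(np.arange(3), np.array([1.0, 2.5, 2.0]))
    path = tmp_path / "series.csv"
    save_timeseries(obs, path)
    loaded = load_timeseries(path)
    assert np.array_equal(loaded.days, obs.days)
    assert np.array_equal(loaded.methane_nl, obs.methane_nl)

    dup = tmp_path / "dup.csv"
    dup.write_text("day,methane_nl\n1,2.0\n1,3.0\n")
    with pytest.raises(SchemaError, match="duplicated day 1"):
        load_timeseries(dup)
    txt = tmp_path / "txt.csv"
    txt.write_text("day,methane_nl\n1,abc\n")
    with pytest.raises(SchemaError, match="non-numeric"):
        load_timeseries(txt)


def test_balance_pipeline_writes_sheets_and_manifest(tmp_path):
    manifest = run_pipeline({"mode": "balance", "seed": 1,
                             "balance": {"smp": {"raw": 0.29,
                                                 "pretreated": 0.33}}},
                            outdir=tmp_path)
    assert manifest.stages["balance"] == "ok"
    assert (tmp_path / "balance_raw.csv").exists()
    assert (tmp_path / "balance_pretreated.csv").exists()
    man = json.loads((tmp_path / "manifest.json").read_text())
    assert man["version"] == fw.__version__
    for name, digest in man["outputs"].items():
        assert len(digest) == 64


def test_missing_input_aborts_with_stage_name(tmp_path):
    with pytest.raises(StageError, match="calibrate"):
        run_pipeline({"mode": "calibrate",
                      "observed": str(tmp_path / "nope.csv"),
                      "reactor": {"horizon": 5.0, "spinup": 0.0}},
                     outdir=tmp_path)
    # partial manifest still records the failure
    man = json.loads((tmp_path / "manifest.json").read_text())
    assert "failed" in man["stages"]["calibrate"]


def test_synth_pipeline_embeds_spec_sidecar(tmp_path):
    cfg = {"mode": "synth", "seed": 11,
           "reactor": {"hrt": 20.0, "olr": 1.6, "horizon": 7.0,
                       "spinup": 0.0, "rtol": 1e-6, "atol": 1e-10},
           "feed": {"characterization": "raw_solid_residue", "f_xi": 0.2},
           "truth": {"k_dis": 1.0, "f_xi": 0.2}}
    m1 = run_pipeline(cfg, outdir=tmp_path / "a")
    m2 = run_pipeline(cfg, outdir=tmp_path / "b")
    spec = json.loads((tmp_path / "a" / "synthetic_spec.json").read_text())
    assert spec["truth"]["k_dis"] == 1.0
    assert spec["seed"] == 11
    # identical config + seed -> byte-identical numeric outputs
    assert (m1.outputs["synthetic_series.csv"]
            == m2.outputs["synthetic_series.csv"])


def test_cli_balance_roundtrip(tmp_path):
    runner = CliRunner()
    result = runner.invoke(main, ["--quiet", "balance", "--outdir",
                                  str(tmp_path)])
    assert result.exit_code == 0, result.output
    assert (tmp_path / "balance_raw.csv").exists()


def test_cli_reports_missing_config_error(tmp_path):
    runner = CliRunner()
    result = runner.invoke(
        main, ["calibrate", "--config", str(tmp_path / "none.yaml")])
    assert result.exit_code != 0
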