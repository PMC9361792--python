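"""End-to-end pipelines, config round trips and the CLI surface."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from modvar.cli import main
from modvar.synthetic_data import gen_condition_table
from modvar.workbench import RunConfig, run_experiment_analysis, run_model_reproduction


def _table(seed=0, sd=2.0):
    means = {"a": {"ctrl": 10.3, "Proc": 14.9, "ProcCCAP": 15.6, "wash": 11.8}}
    sds = {"a": {c: sd for c in means["a"]}}
    table, _ = gen_condition_table(means, sds, n_rows=16, seed=seed)
    return table


def test_experiment_analysis_zero_sd_table():
    means = {"a": {c: 12.0 for c in ("ctrl", "Proc", "ProcCCAP", "wash")}}
    sds = {"a": {c: 0.0 for c in means["a"]}}
    table, _ = gen_condition_table(means, sds, n_rows=16, seed=0)
    report, comparisons = run_experiment_analysis(table)
    assert (report.table["cv"] == 0.0).all()
    # no variance anywhere: null comparison
    assert all(c["p"] > 0.9 for c in comparisons)


def test_experiment_analysis_detects_modulator_effect():
    report, comparisons = run_experiment_analysis(_table(seed=3))
    comp = comparisons[0]
    assert comp["parameter"] == "a"
    assert comp["p"] < 0.001
    df = report.table
    cv_ctrl = df[(df.parameter == "a") & (df.condition == "ctrl")].cv.iloc[0]
    cv_proc = df[(df.parameter == "a") & (df.condition == "Proc")].cv.iloc[0]
    assert cv_proc < cv_ctrl  # equal SD, higher mean -> lower CV


def test_experiment_analysis_outputs_are_reproducible(tmp_path):
    cfg = RunConfig(seed=5)
    table = _table(seed=5)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    run_experiment_analysis(table, cfg, d1)
    run_experiment_analysis(table, cfg, d2)
    for name in ("variability_report.csv", "comparisons.json", "config.yaml"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_run_config_yaml_round_trip(tmp_path):
    cfg = RunConfig(seed=9, levels=(0.0, 0.1), lif_n=50)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    again = RunConfig.from_yaml(path)
    assert again == cfg
    assert again.hash() == cfg.hash()
    (tmp_path / "bad.yaml").write_text("nonsense_key: 1\n")
    with pytest.raises(ValueError):
        RunConfig.from_yaml(tmp_path / "bad.yaml")


def test_lif_reproduction_small_scale(tmp_path):
    cfg = RunConfig(seed=2, lif_n=40)
    out = run_model_reproduction("lif_sweep", cfg, tmp_path / "lif")
    per_level = out["per_level"]
    assert list(per_level["g_mi_l"]) == [0.0, 0.2, 0.36]
    assert per_level["i0_mean"].is_monotonic_decreasing
    assert (tmp_path / "lif" / "per_level.csv").exists()
    assert (tmp_path / "lif" / "config_hash.txt").read_text().strip() == cfg.hash()


def test_unknown_reproduction_kind():
    with pytest.raises(ValueError):
        run_model_reproduction("nope")


def test_cli_synth_analyze_round_trip(tmp_path):
    runner = CliRunner()
    spec = {
        "means": {"a": {"ctrl": 10.0, "Proc": 15.0, "ProcCCAP": 15.5, "wash": 11.0}},
        "sds": {"a": {"ctrl": 2.0, "Proc": 2.0, "ProcCCAP": 2.0, "wash": 2.0}},
        "n_rows": 16,
        "seed": 3,
    }
    spec_path = tmp_path / "spec.json"
    spec_path.write_text(json.dumps(spec))
    table_path = tmp_path / "table.csv"
    r = runner.invoke(main, ["synth", "--spec", str(spec_path), "--out", str(table_path)])
    assert r.exit_code == 0, r.output
    out_dir = tmp_path / "analysis"
    r2 = runner.invoke(
        main, ["analyze-table", "--table", str(table_path), "--out", str(out_dir)]
    )
    assert r2.exit_code == 0, r2.output
    report = pd.read_csv(out_dir / "variability_report.csv")
    assert set(report["condition"]) == {"ctrl", "Proc", "ProcCCAP", "wash"}
    comps = json.loads((out_dir / "comparisons.json").read_text())
    assert comps and comps[0]["parameter"] == "a"


def test_cli_fit_power(tmp_path):
    runner = CliRunner()
    grid = np.arange(0.0, 5.01, 0.5)
    df = pd.DataFrame({"i": grid, "f": 12.0 * np.maximum(grid - 0.5, 0) ** 0.4})
    path = tmp_path / "pts.csv"
    df.to_csv(path, index=False)
    r = runner.invoke(main, ["fit", "--kind", "power", "--data", str(path)])
    assert r.exit_code == 0, r.output
    rec = json.loads(r.output)
    assert rec["a"] == pytest.approx(12.0, rel=1e-3)


def test_cli_vclamp_features(tmp_path):
    runner = CliRunner()
    out = tmp_path / "features.json"
    r = runner.invoke(main, ["vclamp-features", "--seed", "1", "--out", str(out)])
    assert r.exit_code == 0, r.output
    feats = json.loads(out.read_text())
    assert feats["ihtk_transient_na"] == pytest.approx(80.0, rel=0.05)
    assert feats["imi_peak_na"] < 0


def test_cli_simulate_lp_writes_trace(tmp_path):
    runner = CliRunner()
    out = tmp_path / "trace.csv"
    r = runner.invoke(
        main,
        ["simulate-lp", "--protocol", "rebound_dc", "--dt", "0.05",
         "--stride", "40", "--out", str(out)],
    )
    assert r.exit_code == 0, r.output
    df = pd.read_csv(out)
    assert {"time_ms", "v_soma_mv", "v_axon_mv", "ca_mm", "i_inj_na"} <= set(df.columns)
    meta = json.loads((tmp_path / "trace.csv.json").read_text())
    assert meta["protocol"] == "rebound_dc"
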