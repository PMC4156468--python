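"""Experiment runners and the command-line interface (smoke-level)."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from fofr.cli import main
from fofr.experiments import (EXPERIMENTS, ExperimentConfig,
                              run_experiment)


def test_unknown_experiment_rejected():
    with pytest.raises(ValueError, match="unknown experiment"):
        run_experiment(ExperimentConfig("fig99"))


def test_fig2_step_bundle_reports_trafficking_metrics(tmp_path):
    cfg = ExperimentConfig("fig2_step", overrides=dict(
        vip_steps_nM=[1000.0], washout_s=3600.0),
        out_dir=str(tmp_path / "fig2"))
    res = run_experiment(cfg)
    m = res.metrics
    assert m["defined"]
    assert m["half_time_min"] > 0
    assert 0 < m["max_internalization_pct"] < 100
    assert (tmp_path / "fig2" / "metrics.json").exists()
    saved = json.loads((tmp_path / "fig2" / "metrics.json").read_text())
    assert saved["seed"] == 0 and saved["experiment"] == "fig2_step"


def test_fig2_dose_deterministic():
    cfg = ExperimentConfig("fig2_dose", overrides=dict(
        test_concs_nM=[0.1, 10.0, 1000.0]))
    a = run_experiment(cfg).tables["dose_response"]
    b = run_experiment(cfg).tables["dose_response"]
    np.testing.assert_array_equal(a.values, b.values)


def test_fig2_dose_desensitization_reduces_maximum():
    cfg = ExperimentConfig("fig2_dose", overrides=dict(
        test_concs_nM=list(np.geomspace(0.05, 2000.0, 7))))
    res = run_experiment(cfg)
    tab = res.tables["dose_response"]
    assert tab.ac_desensitized_pct.max() < tab.ac_naive_pct.max()
    assert res.metrics["max_fold_reduction"] > 1.3
    assert np.all(tab.ac_naive_pct.between(0, 100))


def test_cli_simulate_cell(tmp_path):
    runner = CliRunner()
    out = tmp_path / "traj.csv"
    proto = tmp_path / "proto.yaml"
    proto.write_text(
        "segments:\n- {duration: 600, vip_clamp: 10.0, secretion_on: false}\n")
    r = runner.invoke(main, ["simulate-cell", "--protocol", str(proto),
                             "--out", str(out), "--dt-out", "30"])
    assert r.exit_code == 0, r.output
    import pandas as pd
    df = pd.read_csv(out)
    assert "firing_rate_hz" in df.columns and len(df) > 10
    assert (df["L"] == 10.0).all()


def test_cli_run_experiment(tmp_path):
    runner = CliRunner()
    r = runner.invoke(main, [
        "run", "fig2_step", "--seed", "3",
        "--override", "vip_steps_nM=[1000.0]",
        "--override", "washout_s=600.0",
        "--out", str(tmp_path / "bundle")])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "bundle" / "metrics.json").exists()


def test_all_experiment_ids_have_runners():
    expected = {"fig2_step", "fig2_dose", "fig3_nullclines",
                "fig4_bifurcation", "fig4_sensitivity", "fig5_sync50",
                "fig6_induction", "fig7_circadian"}
    assert expected == set(EXPERIMENTS)


def test_shipped_parameter_files_match_code_defaults():
    """The versioned YAML parameter files mirror the in-code defaults."""
    from importlib.resources import files
    import yaml
    from fofr import CellParameters
    from fofr.clock import ClockParameters
    from fofr.model import DEFAULT_TOTALS
    data = files("fofr") / "data"
    p = yaml.safe_load((data / "default_parameters.yaml").read_text())
    assert p == pytest.approx(
        {k: getattr(CellParameters(), k) for k in p})
    c = yaml.safe_load((data / "clock_parameters.yaml").read_text())
    assert c == pytest.approx(
        {k: getattr(ClockParameters(), k) for k in c})
    init = yaml.safe_load((data / "initial_concentrations.yaml").read_text())
    assert init == pytest.approx(DEFAULT_TOTALS)


def test_fig7_series2_decoupling_raises_firing_phase_spread():
    """Clock-jittered coupled network (reduced size): removing VIP
    exchange after a coupled epoch increases the firing phase spread in
    the FOFR-coupled variant."""
    cfg = ExperimentConfig(
        "fig7_circadian", seed=5,
        overrides=dict(variant="vip_cng_with_fofr", series=2, n_cells=4,
                       coupling_on_s=12 * 3600.0,
                       coupling_off_s=60 * 3600.0,
                       post_off_s=24 * 3600.0, dt_out=180.0))
    m = run_experiment(cfg).metrics
    assert m["series"] == 2
    assert np.isfinite(m["firing_phase_sd_coupled_h"])
    assert (m["firing_phase_sd_post_decoupling_h"]
            > m["firing_phase_sd_coupled_h"])
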