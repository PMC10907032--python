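"""Configuration, fixtures, determinism, and CLI surface."""
import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from cardiopes import cli, scenarios
from cardiopes.scenarios import ConfigError, ScenarioConfig


def test_config_validation_names_offending_key():
    with pytest.raises(ConfigError, match="scenario"):
        ScenarioConfig(scenario="bogus")
    with pytest.raises(ConfigError, match="variants"):
        ScenarioConfig(scenario="pes_cell", variants=["amX"])
    with pytest.raises(ConfigError, match="bcl"):
        ScenarioConfig(scenario="pes_cell", bcl=-5.0)
    with pytest.raises(ConfigError, match="stability"):
        ScenarioConfig(scenario="reduced", dt=0.05, dx=0.01, diffusion=0.001)


def test_config_yaml_round_trip(tmp_path):
    cfg = ScenarioConfig(scenario="pes_cell", variants=["control", "hf"],
                         bcl=500.0)
    path = tmp_path / "cfg.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    cfg2 = ScenarioConfig.from_yaml(path)
    assert cfg2 == cfg
    assert cfg2.digest() == cfg.digest()


def test_config_rejects_unknown_keys(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("scenario: pes_cell\nwibble: 3\n")
    with pytest.raises(ConfigError, match="wibble"):
        ScenarioConfig.from_yaml(path)


def test_fixture_kinds():
    for kind in ("uniform_sheet", "gradient_sheet_small",
                 "spiral_synthetic", "cable_short"):
        cfg, manifest = scenarios.make_fixture(kind)
        assert cfg and manifest
    with pytest.raises(ConfigError):
        scenarios.make_fixture("bogus")


def test_spiral_fixture_manifest_is_self_consistent():
    from cardiopes import classify
    cfg, manifest = scenarios.make_fixture("spiral_synthetic")
    frames, times = scenarios.synthetic_spiral(cfg)
    ph, _ = classify.phase_maps(frames, times, vstar=cfg["vstar"])
    counts = classify.singularities_per_frame(ph)
    assert np.all(counts == manifest["n_singularities"])


def test_pipeline_determinism_byte_identical(tmp_path, registry):
    """The pipeline has no randomness: identical configs give
    byte-identical summary CSVs."""
    outs = []
    for sub in ("a", "b"):
        cfg = ScenarioConfig(scenario="pes_cell", variants=["control"],
                             out_dir=str(tmp_path / sub))
        summary = scenarios.run_scenario(cfg, registry=registry)
        outs.append((tmp_path / sub / f"pes_cell-{cfg.digest()}" /
                     "pes.csv").read_bytes())
    assert outs[0] == outs[1]


def test_cli_fixtures_smoke():
    runner = CliRunner()
    result = runner.invoke(cli.main, ["fixtures", "spiral_synthetic"])
    assert result.exit_code == 0
    assert "n_singularities" in result.output


def test_cli_bad_scenario_exit_code(tmp_path):
    runner = CliRunner()
    result = runner.invoke(cli.main, ["pes", "--variant", "nope",
                                      "--out", str(tmp_path)])
    assert result.exit_code == 2
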