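"""Table file format round-trip, config handling and the CLI surface."""

import numpy as np
import pytest
from click.testing import CliRunner

from protrack.cli import main
from protrack.engine_io import (RunConfig, read_xs_tables,
                                write_xs_tables)


def _tables_equal(a, b):
    if set(a.tcs) != set(b.tcs):
        return False
    for k in a.tcs:
        if not np.array_equal(a.tcs[k], b.tcs[k]):
            return False
    for name in ("e_grid", "ek_grid", "ek_cdf", "binding_mean",
                 "cos_nodes", "theta_cdf", "exc_weights", "elastic_x",
                 "elastic_theta"):
        if not np.array_equal(getattr(a, name), getattr(b, name)):
            return False
    return True


def test_roundtrip_bit_exact(toy, tmp_path):
    _, tab = toy
    p = tmp_path / "toy.xs"
    write_xs_tables(tab, str(p))
    back = read_xs_tables(str(p))
    assert _tables_equal(tab, back)
    assert back.medium == "toy"
    assert back.meta["sigma_cm2"] == tab.meta["sigma_cm2"]
    # write(read(x)) is byte-identical
    p2 = tmp_path / "toy2.xs"
    write_xs_tables(back, str(p2))
    assert p.read_text() == p2.read_text()


def test_truncated_file_raises(toy, tmp_path):
    _, tab = toy
    p = tmp_path / "toy.xs"
    write_xs_tables(tab, str(p))
    text = p.read_text()
    (tmp_path / "bad.xs").write_text(text[: len(text) // 2])
    with pytest.raises(ValueError, match="truncat"):
        read_xs_tables(str(tmp_path / "bad.xs"))
    (tmp_path / "junk.xs").write_text("not a table\n")
    with pytest.raises(ValueError, match="not an XsTables"):
        read_xs_tables(str(tmp_path / "junk.xs"))


def test_header_echoes_generating_config(toy, tmp_path):
    _, tab = toy
    tab.meta["h0_screening"] = [0.35, 2.0]
    p = tmp_path / "toy.xs"
    write_xs_tables(tab, str(p))
    back = read_xs_tables(str(p))
    assert back.meta["h0_screening"] == [0.35, 2.0]


def test_run_config_yaml_roundtrip(tmp_path):
    cfg = RunConfig(mode="range", medium="dna", histories=500, seed=7)
    import yaml
    p = tmp_path / "run.yaml"
    p.write_text(yaml.safe_dump(cfg.to_dict()))
    back = RunConfig.from_yaml(str(p))
    assert back.to_dict() == cfg.to_dict()
    # defaults reproduce the reference configuration
    d = RunConfig()
    assert d.range_correction_um == pytest.approx(0.322)
    assert d.theta_cut_lab_mrad == pytest.approx(0.1)


def test_cli_imfp_and_sp_with_tables(toy, tmp_path):
    _, tab = toy
    p = tmp_path / "toy.xs"
    write_xs_tables(tab, str(p))
    runner = CliRunner()
    res = runner.invoke(main, ["imfp", "--tables", str(p),
                               "--energy", "100"])
    assert res.exit_code == 0, res.output
    val = float(res.output.strip().splitlines()[-1].split("\t")[1])
    assert val == pytest.approx(2.99, abs=0.01)

    res = runner.invoke(main, ["sp", "--tables", str(p), "--energy",
                               "100", "--histories", "5000",
                               "--seed", "3"])
    assert res.exit_code == 0, res.output
    val = float(res.output.strip().splitlines()[-1].split("\t")[1])
    assert val == pytest.approx(6.686, rel=0.05)

    res = runner.invoke(main, ["range", "--tables", str(p), "--energy",
                               "50", "--histories", "300", "--seed",
                               "3"])
    assert res.exit_code == 0, res.output
    val = float(res.output.strip().splitlines()[-1].split("\t")[1])
    assert val == pytest.approx((50.0 - 10.0) / 6.686 + 0.322, rel=0.05)
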