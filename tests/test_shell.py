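"""File-format round-trips, pipeline orchestration, and CLI behaviour."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import fepbench.io as fio
from fepbench.cli import main as cli_main
from fepbench.exceptions import InputError
from fepbench.pipeline import RunConfig, StageError, run_pipeline, subseed
from fepbench.synthgen import (
    GaussianWorkSpec,
    HarmonicAlchemySpec,
    sample_gaussian_work,
    sample_harmonic_alchemy,
)

from conftest import UNIT_KT


class TestWindowFileRoundTrip:
    def test_write_read_identical(self, tmp_path):
        window, _ = sample_gaussian_work(GaussianWorkSpec(seed=1))
        path = tmp_path / "windows.tsv"
        fio.write_window_file(path, [window])
        (back,) = fio.read_window_file(path)
        assert np.array_equal(back.dU_forward, window.dU_forward)
        assert np.array_equal(back.dU_backward, window.dU_backward)

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(InputError):
            fio.read_window_file(path)

    def test_header_only_is_an_error(self, tmp_path):
        path = tmp_path / "header.tsv"
        path.write_text("lambda_low\tlambda_high\tdirection\tdU\n")
        with pytest.raises(InputError, match="no data rows"):
            fio.read_window_file(path)

    def test_nan_cell_names_the_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "lambda_low\tlambda_high\tdirection\tdU\n"
            "0.0\t1.0\tfwd\t1.0\n"
            "0.0\t1.0\tfwd\tnan\n"
        )
        with pytest.raises(InputError, match=":3"):
            fio.read_window_file(path)

    def test_bad_direction_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "lambda_low\tlambda_high\tdirection\tdU\n0.0\t1.0\tsideways\t1.0\n"
        )
        with pytest.raises(InputError, match="direction"):
            fio.read_window_file(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("lambda_low\tdirection\tdU\n0.0\tfwd\t1.0\n")
        with pytest.raises(InputError, match="lambda_high"):
            fio.read_window_file(path)


class TestUknRoundTrip:
    def test_write_read_identical(self, tmp_path):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(n_per_state=10, temperature=UNIT_KT, seed=2)
        )
        path = tmp_path / "ukn.csv"
        fio.write_ukn_file(path, res.rps)
        back = fio.read_ukn_file(path)
        assert np.array_equal(back.u, res.rps.u)
        assert np.array_equal(back.origin, res.rps.origin)
        assert back.temperature == res.rps.temperature
        assert np.array_equal(back.lambdas, res.rps.lambdas)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "ukn.csv"
        path.write_text("origin,u0,u1\n0,0.0,1.0\n1,0.0,1.0\n")
        with pytest.raises(InputError, match="header"):
            fio.read_ukn_file(path)


class TestPipeline:
    def _write_synthetic_inputs(self, tmp_path, seed=11):
        res = sample_harmonic_alchemy(
            HarmonicAlchemySpec(n_per_state=50, temperature=UNIT_KT, seed=seed)
        )
        ukn = tmp_path / "ukn.csv"
        fio.write_ukn_file(ukn, res.rps)
        window, _ = sample_gaussian_work(
            GaussianWorkSpec(mu_f=1.0, sigma=1.0, temperature=UNIT_KT,
                             seed=seed)
        )
        wfile = tmp_path / "windows.tsv"
        fio.write_window_file(wfile, [window])
        return res, ukn, wfile

    def test_end_to_end_recovers_planted_free_energy(self, tmp_path):
        res, ukn, wfile = self._write_synthetic_inputs(tmp_path)
        cfg = RunConfig(
            out_dir=str(tmp_path / "out"), temperature=UNIT_KT, seed=1,
            ukn_file=str(ukn), window_file=str(wfile), mbar_bootstrap=20,
        )
        summary = run_pipeline(cfg)
        est = summary["estimate"]
        tol = 3 * max(est["se_asymptotic"], est["se_bootstrap"])
        assert est["value"] == pytest.approx(res.exact_dg, abs=tol)
        assert (tmp_path / "out" / "summary.json").exists()
        assert summary["diagnose"][0]["refine"] is False

    def test_reruns_with_same_seed_are_byte_identical(self, tmp_path):
        _, ukn, wfile = self._write_synthetic_inputs(tmp_path)
        texts = []
        for run_dir in ("a", "b"):
            cfg = RunConfig(
                out_dir=str(tmp_path / run_dir), temperature=UNIT_KT, seed=7,
                ukn_file=str(ukn), window_file=str(wfile), mbar_bootstrap=10,
            )
            run_pipeline(cfg)
            text = (tmp_path / run_dir / "summary.json").read_text()
            texts.append(text.replace(f'"{tmp_path}/{run_dir}', '"X'))
        # timings differ between runs; strip them before comparing
        a, b = (json.loads(t) for t in texts)
        a.pop("timings_s"), b.pop("timings_s")
        assert a == b

    def test_stage_failure_is_tagged(self, tmp_path):
        cfg = RunConfig(out_dir=str(tmp_path / "out"),
                        ukn_file=str(tmp_path / "missing.csv"))
        with pytest.raises(StageError, match="estimate"):
            run_pipeline(cfg)

    def test_fixture_pairs_through_pipeline(self, tmp_path, fixtures):
        labels, calc, se, exp = fixtures.set2_pairs("nowat_3ft5")
        pfile = tmp_path / "pairs.csv"
        pfile.write_text(
            "label,calc,calc_se,exp\n"
            + "\n".join(f"{l},{c},{s},{e}"
                        for l, c, s, e in zip(labels, calc, se, exp))
            + "\n"
        )
        cfg = RunConfig(out_dir=str(tmp_path / "out"), seed=5,
                        pairs_file=str(pfile), metric_bootstrap=100,
                        antisymmetrize=True)
        summary = run_pipeline(cfg)
        point = summary["evaluate"]["point"]
        assert point["mad"] == pytest.approx(5.3, abs=0.05)
        assert point["r"] == pytest.approx(0.59, abs=0.01)

    def test_config_validation(self, tmp_path):
        with pytest.raises(InputError):
            RunConfig(temperature=-1.0)
        bad = tmp_path / "cfg.yaml"
        bad.write_text(yaml.safe_dump({"not_a_key": 1}))
        with pytest.raises(InputError, match="not_a_key"):
            RunConfig.from_yaml(bad)

    def test_subseed_is_stable_and_bounded(self):
        assert subseed(3, 1) == subseed(3, 1)
        assert subseed(3, 1) != subseed(3, 2)
        assert 0 <= subseed(12345, 9) < 2**31
        assert subseed(None, 1) is None


class TestCli:
    def test_simulate_estimate_diagnose_chain(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(cli_main, [
            "simulate", "--model", "harmonic", "--seed", "4",
            "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        truth = json.loads((out / "truth.json").read_text())

        report = tmp_path / "est.json"
        r = runner.invoke(cli_main, [
            "estimate", "--method", "mbar", "--input", str(out / "ukn.csv"),
            "--out", str(report),
        ])
        assert r.exit_code == 0, r.output
        est = json.loads(report.read_text())
        assert est["value"] == pytest.approx(truth["exact_dg"],
                                             abs=3 * est["se"])

        r = runner.invoke(cli_main, [
            "simulate", "--model", "gaussian-work", "--seed", "4",
            "--out", str(out),
        ])
        assert r.exit_code == 0
        diag = tmp_path / "diag.json"
        r = runner.invoke(cli_main, [
            "diagnose", "--input", str(out / "windows.tsv"),
            "--temperature", "300", "--out", str(diag),
        ])
        assert r.exit_code == 0, r.output
        rows = json.loads(diag.read_text())
        assert {"omega", "kab", "pi", "wmax", "refine"} <= set(rows[0])

    def test_network_and_score_commands(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "net"
        r = runner.invoke(cli_main, [
            "simulate", "--model", "network", "--seed", "2", "--out", str(out),
        ])
        assert r.exit_code == 0, r.output
        table = tmp_path / "pairs.csv"
        r = runner.invoke(cli_main, [
            "network", "--edges", str(out / "edges.csv"),
            "--ligands", str(out / "ligands.csv"),
            "--scheme", "all_pairs", "--out", str(table),
        ])
        assert r.exit_code == 0, r.output
        assert table.read_text().count("\n") == 11  # header + C(5,2) rows

    def test_validation_failure_exits_nonzero(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.tsv"
        bad.write_text("lambda_low\tlambda_high\tdirection\tdU\n")
        r = runner.invoke(cli_main, [
            "estimate", "--method", "ea", "--input", str(bad),
            "--out", str(tmp_path / "x.json"),
        ])
        assert r.exit_code != 0
        assert "error" in r.output
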