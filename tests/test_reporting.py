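"""TSV schema round trips, pipeline end-to-end behaviour, CLI smoke tests."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from methanofrac.cli import main
from methanofrac.kinetics import BatchBottleSeries, CellCountSeries, ChemostatState
from methanofrac.reporting import (
    condition_isotopes,
    epsilon_for_condition,
    packaged_isotope_table,
    read_batch_series,
    read_cell_counts,
    read_chemostat_states,
    read_isotope_table,
    read_metadata_sidecar,
    run_condition,
    simulate,
    write_batch_series,
    write_cell_counts,
    write_chemostat_states,
    write_isotope_table,
    write_metadata_sidecar,
)
from methanofrac.synthetic import SimConfig, gen_coculture


class TestSchemaRoundTrips:
    def test_cell_counts(self, tmp_path):
        series = CellCountSeries(
            np.array([0.0, 1.0, 2.0]), np.array([1e6, 2e6, 4e6]), "methanogen"
        )
        path = tmp_path / "counts.tsv"
        write_cell_counts(series, path)
        back = read_cell_counts(path)
        np.testing.assert_allclose(back.count_per_ml, series.count_per_ml, rtol=1e-10)
        assert back.organism_label == "methanogen"

    def test_batch_series(self, tmp_path):
        series = gen_coculture(0.16, 9e-14, 9.1e12, SimConfig(seed=5))
        path = tmp_path / "bottle.tsv"
        write_batch_series(series, path)
        back = read_batch_series(path)
        np.testing.assert_allclose(back.ch4_mol_total, series.ch4_mol_total, rtol=1e-10)
        np.testing.assert_allclose(
            back.heterotroph_cells_total, series.heterotroph_cells_total, rtol=1e-10
        )

    def test_chemostat_states(self, tmp_path):
        states = [
            ChemostatState(0.6, 1e7, 1.5, 9.15, 8e-4, 1e-6),
            ChemostatState(0.21, 2e7, 1.5, 9.18, 3e-4, 5e-7),
        ]
        path = tmp_path / "chemostat.tsv"
        write_chemostat_states(states, path)
        back = read_chemostat_states(path)
        assert back[0].dilution_rate_per_h == pytest.approx(0.6)
        assert back[1].headspace_ch4_mol_per_l == pytest.approx(3e-4, rel=1e-10)

    def test_isotope_table(self, tmp_path):
        df = packaged_isotope_table()
        path = tmp_path / "iso.tsv"
        write_isotope_table(df, path)
        back = read_isotope_table(path)
        pd.testing.assert_frame_equal(back, df)

    def test_metadata_sidecar(self, tmp_path):
        path = tmp_path / "x.meta.txt"
        write_metadata_sidecar(path, {"seed": 7, "k_per_h": 0.16})
        meta = read_metadata_sidecar(path)
        assert meta["seed"] == "7"
        assert float(meta["k_per_h"]) == 0.16

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"hours": [1, 2]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError):
            read_cell_counts(path)
        with pytest.raises(ValueError):
            read_batch_series(path)


class TestIsotopeSummaries:
    def test_condition_lookup_prefers_co2_over_dic(self):
        vals = condition_isotopes(packaged_isotope_table(), "B1")
        assert vals["delta_co2_tf"] == pytest.approx(18.9)
        assert vals["delta_co2_to"] == pytest.approx(-26.1)
        assert vals["delta_ch4_tf"] == pytest.approx(-32.9)

    @pytest.mark.parametrize(
        "condition, expected",
        [("R1", 28.5), ("R2", 29.3), ("R3", 29.0), ("R4", 45.9), ("R5", 45.8),
         ("R6", 43.7), ("B3", 85.1), ("B4", 84.8), ("B5", 73.5)],
    )
    def test_direct_epsilon_matches_published_table(self, condition, expected):
        eps = epsilon_for_condition(packaged_isotope_table(), condition, mode="direct")
        assert eps == pytest.approx(expected, abs=0.1)

    def test_rayleigh_mode_for_drawdown_bottles(self):
        df = packaged_isotope_table()
        eps_b1 = epsilon_for_condition(df, "B1", mode="rayleigh")
        eps_b2 = epsilon_for_condition(df, "B2", mode="rayleigh")
        assert eps_b1 == pytest.approx(22.1, abs=1.3)
        assert eps_b2 == pytest.approx(23.0, abs=1.3)


class TestPipeline:
    def test_simulate_then_run_condition_round_trip(self, tmp_path):
        """End-to-end at zero noise: the pipeline returns generator truth."""
        parser_dir = tmp_path / "sim"
        config = tmp_path / "sim.ini"
        config.write_text(
            "[simulate]\nseed = 3\nnoise_cv_counts = 0\nsigma_delta_permil = 0\n\n"
            "[chemostat:high]\nreplicates = 3\ndilution_rate_per_h = 0.6\n"
            "cell_conc_per_ml = 1e7\nq_fmol_per_cell_h = 496\n"
            "gas_flow_l_per_h = 9.15\nliquid_volume_l = 1.5\n\n"
            "[coculture:maltose]\nreplicates = 2\nk_het_per_h = 0.16\n"
            "h2_per_cell_fmol_h = 85\ny_ch4_cells_per_mol = 9.1e12\n"
            "acetate_per_cell_fmol_h = 1050\nt_max_h = 12\nn_points = 9\n"
        )
        simulate(config, out_dir=parser_dir)
        summaries = {
            s.condition_label: s for s in run_condition(parser_dir / "analysis.ini")
        }
        chem = summaries["high"]
        assert chem.q_fmol_per_cell_h == pytest.approx(496.0, rel=1e-9)
        assert chem.q_se == pytest.approx(0.0, abs=1e-9)
        assert chem.yield_cells_per_mol == pytest.approx(0.6 / 496e-15, rel=1e-9)
        cocx = summaries["maltose"]
        assert cocx.k_per_h == pytest.approx(0.16, rel=1e-9)
        assert cocx.yield_cells_per_mol == pytest.approx(9.1e12, rel=1e-9)

    def test_simulate_determinism_byte_identical(self, tmp_path):
        simulate(out_dir=tmp_path / "a", seed=9)
        simulate(out_dir=tmp_path / "b", seed=9)
        for name in ("high_H2_chemostat.tsv", "maltose_rep1.tsv", "analysis.ini"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_simulate_seed_changes_data_not_schema(self, tmp_path):
        simulate(out_dir=tmp_path / "a", seed=1)
        simulate(out_dir=tmp_path / "b", seed=2)
        a = pd.read_csv(tmp_path / "a" / "maltose_rep1.tsv", sep="\t")
        b = pd.read_csv(tmp_path / "b" / "maltose_rep1.tsv", sep="\t")
        assert list(a.columns) == list(b.columns)
        assert not np.array_equal(a["methanogen_cells_total"], b["methanogen_cells_total"])

    def test_sidecars_record_seed(self, tmp_path):
        simulate(out_dir=tmp_path, seed=4)
        meta = read_metadata_sidecar(tmp_path / "maltose_rep1.tsv.meta.txt")
        assert "seed" in meta and "k_het_per_h" in meta

    def test_run_condition_writes_summary_and_log(self, tmp_path):
        simulate(out_dir=tmp_path / "sim", seed=2)
        out = tmp_path / "out"
        run_condition(tmp_path / "sim" / "analysis.ini", out_dir=out)
        assert (out / "summary.tsv").exists()
        log = (out / "run.log").read_text()
        assert "methanofrac_version=" in log and "config_sha256=" in log


class TestCli:
    def test_isotope_subcommand(self):
        result = CliRunner().invoke(main, ["isotope", "--dco2", "-29.0", "--dch4", "-55.9"])
        assert result.exit_code == 0
        assert "epsilon = 28.5 permil" in result.output

    def test_rayleigh_invert_subcommand(self):
        result = CliRunner().invoke(
            main,
            ["rayleigh-invert", "--delta0", "-26.1", "--residual", "18.9",
             "--product", "-32.9"],
        )
        assert result.exit_code == 0
        assert "epsilon = 22.8 permil" in result.output

    def test_simulate_and_fit_growth(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            main, ["simulate", "--seed", "5", "--out-dir", str(tmp_path)]
        )
        assert result.exit_code == 0
        result = runner.invoke(
            main, ["fit-growth", str(tmp_path / "high_H2_batch_counts.tsv")]
        )
        assert result.exit_code == 0
        assert "k = 1.0" in result.output

    def test_run_condition_subcommand(self, tmp_path):
        runner = CliRunner()
        runner.invoke(main, ["simulate", "--seed", "5", "--out-dir", str(tmp_path)])
        result = runner.invoke(
            main, ["run-condition", "--config", str(tmp_path / "analysis.ini")]
        )
        assert result.exit_code == 0
        assert "high_H2" in result.output
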