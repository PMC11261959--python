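"""Study drivers, text I/O, and the command-line interface."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

import mixdoc as mx
from mixdoc.cli import main as cli_main
from mixdoc.io import (
    read_fit_result,
    read_pairs,
    read_scenario,
    write_fit_result,
    write_pairs,
)
from mixdoc.study import STUDY_DEFAULTS, _cell_scenario, run_entropy_grid


@pytest.fixture(scope="module")
def small_report():
    scenario = mx.mixture_comparison_scenario(n_per_zygosity=150)
    return mx.run_model_comparison(
        scenario, n_reps=2, seed=3, n_starts=2, max_iter=200,
        families=("mix4", "doc_xy", "cholesky"),
    )


class TestModelComparison:

    def test_win_frequencies_form_a_distribution(self, small_report):
        assert sum(small_report["win_freq"].values()) == pytest.approx(1.0)
        assert small_report["n_reps"] == 2

    def test_table_arithmetic_holds_rowwise(self, small_report):
        t = small_report["per_rep"].dropna(subset=["aic"])
        np.testing.assert_allclose(t["aic"], t["minus2ll"] + 2 * t["k"])
        assert set(t["rep"]) == {0, 1}

    def test_identical_seed_reproduces_the_report(self):
        scenario = mx.mixture_comparison_scenario(n_per_zygosity=100)
        kw = dict(n_reps=1, seed=9, n_starts=2, families=("doc_xy", "doc_yx"))
        a = mx.run_model_comparison(scenario, **kw)
        b = mx.run_model_comparison(scenario, **kw)
        assert a["per_rep"].equals(b["per_rep"])
        assert a["win_freq"] == b["win_freq"]


class TestEntropyGrid:
    def test_malformed_cells_are_named(self):
        with pytest.raises(ValueError, match="unknown section"):
            _cell_scenario({"section": "nope", "x": 1}, 100, 0)
        with pytest.raises(ValueError, match="unexpected key"):
            _cell_scenario({"section": "causal", "b_xy": 0.5, "b_yx": 0.5,
                            "r_a": 0.1}, 100, 0)
        with pytest.raises(ValueError, match="a2_y"):
            _cell_scenario({"section": "heritability", "a2_y": 0.9}, 100, 0)

    def test_mean_separation_increases_entropy(self):
        grid = [
            {"section": "mean_diff", "mean_diff_x": d, "mean_diff_y": d}
            for d in (0.1, 0.5, 1.5)
        ]
        out = run_entropy_grid(grid, n_reps=2, seed=5, n_pairs_total=2000,
                               entropy_mode="oracle")
        ents = out["mean_entropy"].to_numpy()
        assert np.all(np.diff(ents) > 0)
        assert out["mean_entropy"].between(0, 1).all()

    def test_causal_effect_size_increases_entropy(self):
        grid = [
            {"section": "causal", "b_xy": b, "b_yx": b} for b in (0.1, 0.5, 0.8)
        ]
        out = run_entropy_grid(grid, n_reps=2, seed=5, n_pairs_total=2000,
                               entropy_mode="oracle")
        assert np.all(np.diff(out["mean_entropy"].to_numpy()) > 0)

    def test_genetic_confounding_reduces_fitted_entropy(self):
        # the base mixture fixes r_a = 0, so confounded data blur the classes
        ents = []
        for ra in (0.0, 0.4):
            vals = []
            for rep in range(2):
                sc = _cell_scenario({"section": "confounding", "r_a": ra},
                                    1500, 50 + rep)
                data = mx.simulate_dataset(sc)
                fr = mx.fit(data, "mix4", n_starts=2, seed=50 + rep)
                vals.append(mx.relative_entropy(mx.posterior_probabilities(data, fr)))
            ents.append(np.mean(vals))
        assert ents[1] < ents[0]

    def test_default_grid_covers_the_four_sections(self):
        grid = mx.default_entropy_grid()
        assert {c["section"] for c in grid} == {
            "mean_diff", "causal", "heritability", "confounding"
        }
        assert len(grid) == 20


class TestIO:
    def test_pair_csv_round_trip(self, tmp_path, mix_data):
        path = tmp_path / "pairs.csv"
        write_pairs(mix_data, path)
        back = read_pairs(path)
        np.testing.assert_array_equal(back.values, mix_data.values)
        assert np.array_equal(back.zygosity, mix_data.zygosity)

    def test_unknown_zygosity_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("zygosity,x1,y1,x2,y2\nMZ,0,0,0,0\nXX,1,1,1,1\n")
        with pytest.raises(ValueError, match=r":3: unknown zygosity"):
            read_pairs(path)

    def test_non_numeric_value_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("zygosity,x1,y1,x2,y2\nMZ,0,oops,0,0\n")
        with pytest.raises(ValueError, match=r":2: non-numeric"):
            read_pairs(path)

    def test_empty_file_with_header_gives_empty_dataset(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("zygosity,x1,y1,x2,y2\n")
        assert len(read_pairs(path)) == 0

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("zygosity,x1,y1\nMZ,0,0\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_pairs(path)

    @pytest.mark.parametrize("fmt", ["json", "yaml"])
    def test_scenario_config_formats(self, tmp_path, fmt):
        cfg = {
            "n_mz": 40, "n_dz": 60, "family": "mix4", "seed": 5,
            "fixed_quota": True,
            "design": {"b_xy": 0.4, "b_yx": 0.2, "mean_diff_x": 1.0,
                       "mean_diff_y": 0.5, "base_mean": [0.5, 0.5]},
            "weights": {"MZ": [0.4, 0.2, 0.2, 0.2], "DZ": [0.25, 0.25, 0.25, 0.25]},
        }
        path = tmp_path / f"scn.{fmt}"
        if fmt == "json":
            path.write_text(json.dumps(cfg))
        else:
            path.write_text(yaml.safe_dump(cfg))
        scn = read_scenario(path)
        assert (scn.n_mz, scn.n_dz, scn.family, scn.seed) == (40, 60, "mix4", 5)
        assert scn.params.b_xy == 0.4
        assert scn.weights.omega_mz[0] == 0.4
        data = mx.simulate_dataset(scn)
        assert len(data) == 100

    def test_fit_result_json_round_trip(self, tmp_path, mix_data, mix4_fit):
        path = tmp_path / "fit.json"
        write_fit_result(mix4_fit, path)
        back = read_fit_result(path)
        assert back.spec == mix4_fit.spec
        assert back.minus2ll == pytest.approx(mix4_fit.minus2ll)
        # posterior computation works from the rebuilt result
        post = mx.posterior_probabilities(mix_data, back)
        np.testing.assert_allclose(
            post.p, mx.posterior_probabilities(mix_data, mix4_fit).p, atol=1e-12
        )


class TestCli:
    @pytest.fixture()
    def workspace(self, tmp_path, mix_data):
        scn = {
            "n_mz": 80, "n_dz": 80, "seed": 2, "fixed_quota": True,
            "design": {"mean_diff_x": 1.0, "mean_diff_y": 1.0},
        }
        scn_path = tmp_path / "scenario.json"
        scn_path.write_text(json.dumps(scn))
        data_path = tmp_path / "pairs.csv"
        write_pairs(mix_data, data_path)
        return tmp_path, scn_path, data_path

    def test_simulate_then_fit_then_posteriors(self, workspace):
        tmp, scn_path, _ = workspace
        runner = CliRunner()
        out_csv = tmp / "sim.csv"
        r = runner.invoke(cli_main, ["simulate", "--config", str(scn_path),
                                     "--out", str(out_csv)])
        assert r.exit_code == 0, r.output
        assert len(read_pairs(out_csv)) == 160

        fit_json = tmp / "fit.json"
        r = runner.invoke(cli_main, ["fit", str(out_csv), "--family", "mix4",
                                     "--starts", "2", "--out", str(fit_json)])
        assert r.exit_code == 0, r.output
        assert json.loads(fit_json.read_text())["family"] == "mix4"

        post_csv = tmp / "post.csv"
        r = runner.invoke(cli_main, ["posteriors", str(out_csv),
                                     "--fit-json", str(fit_json),
                                     "--out", str(post_csv)])
        assert r.exit_code == 0, r.output
        assert "relative entropy" in r.output
        assert post_csv.exists()

    def test_compare_prints_six_model_table(self, workspace):
        _, _, data_path = workspace
        r = CliRunner().invoke(cli_main, ["compare", str(data_path), "--starts", "1"])
        assert r.exit_code == 0, r.output
        for family in ("mix4", "mix2", "doc_xy", "doc_yx", "doc_bidir", "cholesky"):
            assert family in r.output
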