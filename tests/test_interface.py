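"""Pipeline orchestration and the command-line interface."""

import json

import pytest
import yaml
from click.testing import CliRunner

from pancbn.cli import main
from pancbn.errors import ConfigurationError, SchemaError
from pancbn.interface import RunConfig, run_pipeline
from pancbn.network import CompiledNetwork
from pancbn.prediction import write_cohort
from pancbn.synthetic import CohortSimConfig, reference_study_table, simulate_cohort


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory, default_networks_cached):
    """Study table + small cohort CSVs written once for CLI runs."""
    root = tmp_path_factory.mktemp("pipeline")
    reference_study_table().to_csv(root / "studies.csv")
    pre, post = default_networks_cached
    cohort = simulate_cohort(post, CohortSimConfig(n_patients=40, missingness=0.2, seed=17))
    variables = [v.name for v in post.spec.variables]
    write_cohort(cohort, root / "cohort.csv", variables)
    post.save(root / "network_post.json")
    pre.save(root / "network_pre.json")
    return root


class TestRunPipeline:
    def test_full_run_emits_all_artifacts(self, fixture_dir, tmp_path):
        config = RunConfig(
            study_table=str(fixture_dir / "studies.csv"),
            cohort=str(fixture_dir / "cohort.csv"),
            out_dir=str(tmp_path / "out"),
        )
        artifacts = run_pipeline(config)
        assert set(artifacts) == {
            "evidence",
            "network_pre",
            "network_post",
            "predictions",
            "validation",
        }
        for path in artifacts.values():
            assert path.exists()
        # every artifact carries the provenance header
        for name in ("evidence", "predictions", "validation"):
            first = artifacts[name].read_text().splitlines()[0]
            assert first.startswith("# pancbn 0.") and "config_hash=" in first
        meta = json.loads(artifacts["network_post"].read_text())["_meta"]
        assert "config_hash" in meta

    def test_rerun_is_byte_identical(self, fixture_dir, tmp_path):
        config = dict(
            study_table=str(fixture_dir / "studies.csv"),
            cohort=str(fixture_dir / "cohort.csv"),
        )
        out1 = run_pipeline(RunConfig(out_dir=str(tmp_path / "a"), **config))
        out2 = run_pipeline(RunConfig(out_dir=str(tmp_path / "b"), **config))
        for name in out1:
            assert out1[name].read_bytes() == out2[name].read_bytes()

    def test_missing_cohort_column_fails_fast(self, fixture_dir, tmp_path):
        bad = tmp_path / "bad_cohort.csv"
        lines = (fixture_dir / "cohort.csv").read_text().splitlines()
        header = lines[0].split(",")
        drop = header.index("survival_months")
        bad.write_text(
            "\n".join(
                ",".join(c for i, c in enumerate(line.split(",")) if i != drop)
                for line in lines
            )
        )
        out_dir = tmp_path / "out"
        config = RunConfig(
            study_table=str(fixture_dir / "studies.csv"),
            cohort=str(bad),
            out_dir=str(out_dir),
        )
        with pytest.raises(SchemaError):
            run_pipeline(config)
        assert not (out_dir / "predictions.csv").exists()

    def test_nonexistent_input_rejected_before_compute(self, tmp_path):
        with pytest.raises(ConfigurationError):
            run_pipeline(RunConfig(study_table=str(tmp_path / "nope.csv")))

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump({"study_table": "s.csv", "top_k": 10}))
        config = RunConfig.from_yaml(path)
        assert config.top_k == 10
        assert len(config.hash()) == 12


class TestCli:
    def setup_method(self):
        self.runner = CliRunner()

    def test_synthesize_writes_ranked_csv(self, fixture_dir, tmp_path):
        out = tmp_path / "evidence.csv"
        result = self.runner.invoke(
            main,
            ["synthesize", "--studies", str(fixture_dir / "studies.csv"), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert out.exists()
        header = out.read_text().splitlines()[0]
        assert header.split(",") == [
            "variable",
            "n_included",
            "n_significant",
            "reporting_population",
            "original_weight",
            "normalized_weight",
            "rank",
        ]

    def test_build_and_predict_single_evidence(self, fixture_dir, tmp_path):
        net_path = tmp_path / "net.json"
        result = self.runner.invoke(
            main,
            [
                "build",
                "--studies",
                str(fixture_dir / "studies.csv"),
                "--phase",
                "pre_operative",
                "--out",
                str(net_path),
            ],
        )
        assert result.exit_code == 0, result.output
        net = CompiledNetwork.load(net_path)
        assert net.phase == "pre_operative"

        evidence_path = tmp_path / "evidence.json"
        evidence_path.write_text(json.dumps({"Albumin": "Low", "mGPS": "2"}))
        result = self.runner.invoke(
            main,
            [
                "predict",
                "--network",
                str(net_path),
                "--evidence",
                str(evidence_path),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "P(Poor Prognosis = yes)" in result.output

    def test_predict_cohort_csv(self, fixture_dir, tmp_path):
        out = tmp_path / "pred.csv"
        result = self.runner.invoke(
            main,
            [
                "predict",
                "--network",
                str(fixture_dir / "network_post.json"),
                "--cohort",
                str(fixture_dir / "cohort.csv"),
                "--out",
                str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert out.exists()

    def test_update_command(self, fixture_dir, tmp_path):
        out = tmp_path / "update.csv"
        result = self.runner.invoke(
            main,
            [
                "update",
                "--pre-network",
                str(fixture_dir / "network_pre.json"),
                "--post-network",
                str(fixture_dir / "network_post.json"),
                "--cohort",
                str(fixture_dir / "cohort.csv"),
                "--out",
                str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert "probability_poor_post" in out.read_text().splitlines()[0]

    def test_validate_command(self, fixture_dir, tmp_path):
        out = tmp_path / "val.csv"
        result = self.runner.invoke(
            main,
            [
                "validate",
                "--network",
                str(fixture_dir / "network_pre.json"),
                "--cohort",
                str(fixture_dir / "cohort.csv"),
                "--out",
                str(out),
            ],
        )
        assert result.exit_code == 0, result.output
        assert out.read_text().splitlines()[0].split(",") == [
            "stratum",
            "n",
            "auc",
            "se",
            "p_value",
            "ci_low",
            "ci_high",
        ]

    def test_simulate_studies_and_cohort(self, fixture_dir, tmp_path):
        config_path = tmp_path / "sim.yaml"
        config_path.write_text(
            yaml.safe_dump(
                {
                    "n_studies": 8,
                    "variables": [
                        {"name": "A", "p_include": 1.0, "p_significant": 0.7},
                        {"name": "B", "p_include": 0.5, "p_significant": 0.3},
                    ],
                }
            )
        )
        out = tmp_path / "studies.csv"
        result = self.runner.invoke(
            main,
            ["simulate", "studies", "--config", str(config_path), "--out", str(out)],
        )
        assert result.exit_code == 0, result.output

        cohort_out = tmp_path / "cohort.csv"
        result = self.runner.invoke(
            main,
            [
                "simulate",
                "cohort",
                "--network",
                str(fixture_dir / "network_post.json"),
                "--n-patients",
                "10",
                "--out",
                str(cohort_out),
            ],
        )
        assert result.exit_code == 0, result.output

    def test_bad_input_exits_nonzero(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("not,a,study\ntable,at,all\n")
        result = self.runner.invoke(
            main, ["synthesize", "--studies", str(bad), "--out", str(tmp_path / "o.csv")]
        )
        assert result.exit_code != 0
        assert "error" in result.output.lower()
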