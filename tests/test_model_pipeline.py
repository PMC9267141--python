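"""ReactivityStudy model, end-to-end pipeline orchestration, file outputs
and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from hrbp import (
    AnalysisConfig,
    ArtifactSpec,
    CohortEntry,
    CouplingSpec,
    PipelineConfig,
    ReactivityStudy,
    generate_cohort,
    run_pipeline,
    write_reports,
)
from hrbp.cli import main as cli_main
from hrbp.io import read_beats_csv, write_beats_csv


def small_plan(n_subjects=5, duration=150.0):
    regimes = ["central", "cyclic", "peripheral", "independent", "central"]
    plan = []
    for i in range(n_subjects):
        for task in ("math", "rumination"):
            plan.append(
                CohortEntry(
                    f"s{i:02d}",
                    task,
                    CouplingSpec(regimes[i % len(regimes)], duration_s=duration),
                )
            )
    return plan


@pytest.fixture
def small_cohort():
    beats, truth = generate_cohort(small_plan(), master_seed=5)
    return beats


class TestReactivityStudy:
    def test_fit_produces_tables(self, small_cohort):
        results = ReactivityStudy(small_cohort).fit()
        assert len(results.analyses) == 10
        assert set(results.max_cc_table["pair"]) == {"sbp", "dbp", "mbp"}
        assert len(results.max_cc_table) == 30
        assert results.contingency.grand_total == 5
        assert len(results.meta_profiles) == 5
        assert "math" in results.profile_chisq

    def test_from_dataframe_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "beats.csv"
        write_beats_csv(small_cohort, path)
        results = ReactivityStudy.from_dataframe(pd.read_csv(path)).fit()
        assert len(results.analyses) == 10

    def test_duplicate_records_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="duplicate"):
            ReactivityStudy(small_cohort + [small_cohort[0]])

    def test_summary_mentions_counts(self, small_cohort):
        text = ReactivityStudy(small_cohort).fit().summary()
        assert "math" in text and "rumination" in text
        assert "Wilks" in text or "Lambda" in text

    def test_empty_cohort(self):
        results = ReactivityStudy([]).fit()
        assert results.max_cc_table.empty
        assert results.manifest["tasks"]["math"]["input"] == 0

    def test_single_subject_cohort(self):
        beats, _ = generate_cohort(small_plan(n_subjects=1), master_seed=1)
        results = ReactivityStudy(beats).fit()
        assert len(results.meta_profiles) == 1

    def test_bp_channels_agree_on_strong_coupling(self):
        # SBP, DBP and MBP correlograms carry the same shape per record
        beats, _ = generate_cohort(
            [
                CohortEntry(
                    "s1", "math",
                    CouplingSpec("central", strength=5.0, ar_coef=0.95, duration_s=600.0),
                ),
                CohortEntry(
                    "s1", "rumination",
                    CouplingSpec("cyclic", strength=5.0, duration_s=600.0),
                ),
            ],
            master_seed=2,
        )
        results = ReactivityStudy(beats).fit()
        for analysis in results.analyses.values():
            labels = {lab.type for lab in analysis.labels.values()}
            assert len(labels) == 1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnalysisConfig(window=10).validate()
        with pytest.raises(ValueError):
            AnalysisConfig(primary_pair="xyz").validate()
        with pytest.raises(ValueError):
            AnalysisConfig(majority=0.4).validate()


class TestRunPipeline:
    def _config(self, out_dir, seed=7, **kw):
        return PipelineConfig(
            out_dir=str(out_dir),
            simulation={
                "math": {"central": 3, "cyclic": 2},
                "rumination": {"cyclic": 3, "central": 2},
            },
            seed=seed,
            **kw,
        )

    def test_outputs_written(self, tmp_path):
        results, manifest = run_pipeline(self._config(tmp_path / "run"))
        out = tmp_path / "run"
        for name in (
            "beats.csv", "ground_truth.csv", "uniform.csv", "rejections.csv",
            "cc.csv", "max_cc.csv", "labels.csv", "meta_profiles.csv",
            "contingency.csv", "stats.json", "manifest.json", "summary.txt",
        ):
            assert (out / name).exists(), name

    def test_deterministic_under_fixed_seed(self, tmp_path):
        run_pipeline(self._config(tmp_path / "a", seed=11))
        run_pipeline(self._config(tmp_path / "b", seed=11))
        for name in ("beats.csv", "cc.csv", "labels.csv", "stats.json", "contingency.csv"):
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text()
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        ma.pop("timestamp"), mb.pop("timestamp")
        assert ma == mb

    def test_seed_changes_outputs(self, tmp_path):
        run_pipeline(self._config(tmp_path / "a", seed=1))
        run_pipeline(self._config(tmp_path / "b", seed=2))
        assert (tmp_path / "a" / "cc.csv").read_text() != (tmp_path / "b" / "cc.csv").read_text()

    def test_count_conservation(self, tmp_path):
        _, manifest = run_pipeline(self._config(tmp_path / "run"))
        for task, c in manifest.counts.items():
            assert c["analyzed"] == c["input"] - c["rejected"]

    def test_refuses_to_overwrite_without_force(self, tmp_path):
        cfg = self._config(tmp_path / "run")
        run_pipeline(cfg)
        with pytest.raises(FileExistsError):
            run_pipeline(self._config(tmp_path / "run"))
        run_pipeline(self._config(tmp_path / "run", force=True))

    def test_forced_artifact_runs_are_rejected_and_counted(self, tmp_path):
        plan = small_plan(n_subjects=4)
        # corrupt two math records with 2-beat runs
        plan = [
            CohortEntry(
                e.subject_id,
                e.task,
                e.coupling,
                ArtifactSpec(p_single=0.0, p_consecutive=0.0, runs=((20, 2),))
                if e.task == "math" and e.subject_id in ("s00", "s01")
                else None,
            )
            for e in plan
        ]
        beats, _ = generate_cohort(plan, master_seed=3)
        results = ReactivityStudy(beats).fit()
        counts = results.manifest["tasks"]
        assert counts["math"]["rejected"] == 2
        assert counts["math"]["analyzed"] == 2
        assert counts["rumination"]["rejected"] == 0
        # rejected-in-one-task subjects keep their other task but leave paired set
        assert results.manifest["n_both_tasks_valid"] == 2

    def test_input_csv_mode(self, tmp_path):
        beats, _ = generate_cohort(small_plan(n_subjects=3), master_seed=9)
        path = tmp_path / "beats.csv"
        write_beats_csv(beats, path)
        cfg = PipelineConfig(out_dir=str(tmp_path / "run"), input_csv=str(path))
        results, manifest = run_pipeline(cfg)
        assert sum(c["input"] for c in manifest.counts.values()) == 6

    def test_exactly_one_input_mode_required(self, tmp_path):
        with pytest.raises(ValueError):
            PipelineConfig(out_dir=str(tmp_path)).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump(
                {
                    "out_dir": str(tmp_path / "run"),
                    "simulation": {"math": {"central": 2}, "rumination": {"cyclic": 2}},
                    "seed": 3,
                    "analysis": {"s_min": 4, "tasks": ["math", "rumination"]},
                }
            )
        )
        cfg = PipelineConfig.from_yaml(cfg_path)
        assert cfg.analysis.s_min == 4
        results, _ = run_pipeline(cfg)
        assert len(results.analyses) > 0

    def test_write_reports_empty_results(self, tmp_path):
        results = ReactivityStudy([]).fit()
        write_reports(results, tmp_path / "empty")
        assert (tmp_path / "empty" / "labels.csv").exists()


class TestCLI:
    def test_stage_chain(self, tmp_path):
        runner = CliRunner()
        out = str(tmp_path)
        r = runner.invoke(
            cli_main,
            ["simulate", "--n-subjects", "3", "--regimes", "central,cyclic",
             "--duration", "90", "--seed", "4", "--p-consecutive", "0",
             "--out-dir", out],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["preprocess", f"{out}/beats.csv", "--out-dir", out])
        assert r.exit_code == 0, r.output
        r = runner.invoke(cli_main, ["cc", f"{out}/uniform.csv", "--out-dir", out])
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            cli_main, ["classify", f"{out}/cc.csv", "--out", f"{out}/labels.csv"]
        )
        assert r.exit_code == 0, r.output
        labels = pd.read_csv(f"{out}/labels.csv")
        assert len(labels) == 6
        r = runner.invoke(cli_main, ["stats", f"{out}/beats.csv", "--out", f"{out}/stats.json"])
        assert r.exit_code == 0, r.output
        assert json.loads((tmp_path / "stats.json").read_text())["manifest"]

    def test_run_all_default_cohort(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main, ["run-all", "--seed", "2", "--out-dir", str(tmp_path / "run")]
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "run" / "stats.json").exists()


class TestPlotting:
    def test_record_figure_builds(self, small_cohort):
        import matplotlib

        matplotlib.use("Agg")
        from hrbp.plotting import plot_record

        results = ReactivityStudy(small_cohort).fit()
        analysis = next(iter(results.analyses.values()))
        fig = plot_record(analysis.uniform, analysis.ccfs)
        assert len(fig.axes) == 2
        import matplotlib.pyplot as plt

        plt.close(fig)
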