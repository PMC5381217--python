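import math

import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from micquant.cli import main as cli_main
from micquant.decontamination import REASON_BELOW_NEC, REASON_NOT_REPRODUCIBLE
from micquant.io_tables import read_count_table
from micquant.model import AbsoluteAbundanceModel
from micquant.pipeline import (
    ConfigError,
    RunConfig,
    accuracy_report_from_reference,
    benchmark_reports,
    run_benchmark,
    run_quantify,
)
from micquant.simulator import DEFAULT_TAXA, SimulationConfig, simulate_experiment


@pytest.fixture(scope="module")
def micelle_experiment():
    return simulate_experiment(
        [2500.0, 250.0, 25.0, 2.5], SimulationConfig(method="micelle"), seed=7
    )


@pytest.fixture(scope="module")
def fitted(micelle_experiment):
    model = AbsoluteAbundanceModel.from_simulation(micelle_experiment)
    return model.fit(seed=7, expected_otus=DEFAULT_TAXA)


class TestModelFit:
    def test_every_otu_accounted_for(self, micelle_experiment, fitted):
        """Each observed OTU of a group appears exactly once: either retained
        in the corrected output or listed in the removal ledger."""
        for group in micelle_experiment.groups:
            if group.role != "specimen":
                continue
            observed = set()
            for p in group.profiles:
                observed |= {o for o, n in p.otu_reads.items() if n > 0 and o != p.ic_otu_id}
            corrected = fitted.corrected[group.group_id]
            retained = set(corrected.otu_copies)
            removed = set(corrected.removed_otus)
            assert retained & removed == set()
            # every OTU actually observed in the group is in exactly one partition
            assert observed <= retained | removed
            # and the partition covers the whole (dense) input table minus the calibrator
            table_otus = set(micelle_experiment.count_table().otu_ids)
            ic = group.profiles[0].ic_otu_id
            assert retained | removed == table_otus - {ic}

    def test_reagent_contaminants_end_in_removal_ledger(self, micelle_experiment, fitted):
        reagent = {otu for otu, _ in micelle_experiment.config.reagent_contaminants}
        ledger = fitted.removal_ledger()
        listed = set(zip(ledger["group_id"], ledger["otu_id"]))
        for group_id, prof in fitted.corrected.items():
            for otu in reagent:
                if otu in prof.otu_copies:
                    pytest.fail(f"reagent contaminant {otu} survived in {group_id}")
                if otu in prof.removed_otus:
                    assert (group_id, otu) in listed

    def test_summary_mentions_key_sections(self, fitted):
        text = fitted.summary()
        assert "correction factors" in text
        assert "NEC thresholds" in text
        assert "LOD" in text

    def test_missing_nec_is_a_hard_error(self, micelle_experiment):
        counts = micelle_experiment.count_table()
        metadata = [m for m in micelle_experiment.metadata() if m.role != "nec"]
        with pytest.raises(ValueError, match="NEC"):
            AbsoluteAbundanceModel(counts, metadata)

    def test_group_with_failed_calibration_is_skipped(self, micelle_experiment):
        """Zeroing the calibrator reads of one replicate makes its whole group
        unusable; it is skipped with a logged reason, not silently patched."""
        counts = micelle_experiment.count_table()
        df = counts.counts.copy()
        victim_group = next(g for g in micelle_experiment.groups if g.role == "specimen")
        victim = victim_group.profiles[0]
        df.loc[victim.ic_otu_id, victim.sample_id] = 0
        model = AbsoluteAbundanceModel(type(counts)(df), micelle_experiment.metadata())
        result = model.fit(seed=0)
        assert victim_group.group_id in result.skipped_groups
        assert victim_group.group_id not in result.corrected

    def test_rarefaction_depth_applied_before_calibration(self, micelle_experiment):
        model = AbsoluteAbundanceModel.from_simulation(
            micelle_experiment, rarefaction_depth=500
        )
        result = model.fit(seed=1)
        # copies stay on the absolute scale despite halving the depth
        top = result.corrected[f"SMC2500_micelle"]
        for taxon in DEFAULT_TAXA:
            assert top.otu_copies.get(taxon, 0.0) > 500


class TestRunConfig:
    def test_both_input_and_simulate_rejected(self):
        with pytest.raises(ConfigError, match="not both"):
            RunConfig(counts_path="a.tsv", metadata_path="b.tsv", simulate={"method": "micelle"})

    def test_neither_rejected(self):
        with pytest.raises(ConfigError):
            RunConfig()

    def test_yaml_roundtrip(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(
            yaml.safe_dump(
                {"simulate": {"method": "micelle", "levels": [250.0], "seed": 5}, "seed": 5}
            )
        )
        cfg = RunConfig.from_yaml(path)
        assert cfg.simulate["method"] == "micelle"

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "run.yaml"
        path.write_text(yaml.safe_dump({"simulate": {}, "bogus": 1}))
        with pytest.raises(ConfigError, match="bogus"):
            RunConfig.from_yaml(path)


class TestRunQuantify:
    def test_simulated_run_writes_all_outputs(self, tmp_path):
        cfg = RunConfig(
            simulate={"method": "micelle", "levels": [250.0, 25.0], "seed": 3},
            expected_otus=DEFAULT_TAXA,
            out_dir=str(tmp_path / "out"),
            seed=3,
        )
        result = run_quantify(cfg)
        out = tmp_path / "out"
        for name in (
            "corrected_profiles.tsv",
            "removal_ledger.tsv",
            "correction_factors.tsv",
            "accuracy_report.tsv",
            "manifest.yaml",
        ):
            assert (out / name).exists(), name
        assert not result.skipped_groups

    def test_rerun_is_byte_identical(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            cfg = RunConfig(
                simulate={"method": "micelle", "levels": [250.0], "seed": 9},
                out_dir=str(tmp_path / run),
                seed=9,
            )
            run_quantify(cfg)
            outputs.append(
                {
                    p.name: p.read_bytes()
                    for p in sorted((tmp_path / run).iterdir())
                    if p.name != "manifest.yaml"  # manifest embeds out_dir
                }
            )
        assert outputs[0] == outputs[1]

    def test_file_based_run(self, tmp_path, micelle_experiment):
        from micquant.io_tables import write_count_table, write_metadata

        write_count_table(micelle_experiment.count_table(), tmp_path / "counts.tsv")
        write_metadata(micelle_experiment.metadata(), tmp_path / "metadata.tsv")
        cfg = RunConfig(
            counts_path=str(tmp_path / "counts.tsv"),
            metadata_path=str(tmp_path / "metadata.tsv"),
            expected_otus=DEFAULT_TAXA,
        )
        result = run_quantify(cfg)
        assert result.accuracy is not None
        assert set(result.corrected) == {
            g.group_id for g in micelle_experiment.groups if g.role == "specimen"
        }


class TestBenchmark:
    def test_reference_arms_significant(self):
        mic = accuracy_report_from_reference("micPCR")
        trad = accuracy_report_from_reference("traditional")
        comparison = benchmark_reports(mic, trad, labels=("mic", "trad"))
        assert comparison["wilcoxon_p"] < 0.01

    def test_identical_arms_degenerate(self):
        mic = accuracy_report_from_reference("micPCR")
        with pytest.warns(UserWarning, match="degenerate"):
            comparison = benchmark_reports(mic, mic)
        assert comparison["wilcoxon_p"] == 1.0

    def test_mismatched_cells_rejected(self):
        mic = accuracy_report_from_reference("micPCR")
        trad = accuracy_report_from_reference("traditional")
        trad.rows = trad.rows[:-1]
        with pytest.raises(ValueError, match="different"):
            benchmark_reports(mic, trad)

    def test_directory_benchmark(self, tmp_path):
        from micquant.io_tables import write_count_table, write_metadata

        for method, arm in (("micelle", "a"), ("traditional", "b")):
            exp = simulate_experiment(
                [2500.0, 250.0], SimulationConfig(method=method), seed=21
            )
            arm_dir = tmp_path / arm
            arm_dir.mkdir()
            write_count_table(exp.count_table(), arm_dir / "counts.tsv")
            write_metadata(exp.metadata(), arm_dir / "metadata.tsv")
        comparison = run_benchmark(tmp_path / "a", tmp_path / "b", tmp_path / "out", seed=21)
        assert (tmp_path / "out" / "benchmark_summary.yaml").exists()
        assert 0.0 <= comparison["wilcoxon_p"] <= 1.0


class TestCli:
    def test_fixture_subcommand_dumps_reference(self):
        runner = CliRunner()
        result = runner.invoke(cli_main, ["fixture"])
        assert result.exit_code == 0
        assert "Clostridium\t2500.0\tmicPCR\t6735" in result.output

    def test_simulate_then_quantify(self, tmp_path):
        runner = CliRunner()
        sim_cfg = tmp_path / "sim.yaml"
        sim_cfg.write_text(
            yaml.safe_dump({"simulate": {"method": "micelle", "levels": [250.0], "seed": 4}})
        )
        sim_out = tmp_path / "sim"
        result = runner.invoke(cli_main, ["simulate", "--config", str(sim_cfg), "--out", str(sim_out)])
        assert result.exit_code == 0, result.output
        assert (sim_out / "counts.tsv").exists()

        q_out = tmp_path / "quant"
        result = runner.invoke(
            cli_main,
            [
                "quantify",
                "--counts", str(sim_out / "counts.tsv"),
                "--metadata", str(sim_out / "metadata.tsv"),
                "--out", str(q_out),
                "--seed", "4",
            ],
        )
        assert result.exit_code == 0, result.output
        assert (q_out / "corrected_profiles.tsv").exists()
        assert "Absolute 16S quantification" in result.output

    def test_quantify_rejects_conflicting_config(self, tmp_path):
        runner = CliRunner()
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            yaml.safe_dump(
                {"counts_path": "x.tsv", "metadata_path": "y.tsv", "simulate": {"method": "micelle"}}
            )
        )
        result = runner.invoke(cli_main, ["quantify", "--config", str(bad), "--out", str(tmp_path / "o")])
        assert result.exit_code != 0
        assert "not both" in result.output
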