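"""Model/Results surface, end-to-end pipeline behavior, and the CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from pcafe.cli import main as cli_main
from pcafe.model import PCAFeatureExtraction
from pcafe.pipeline import PipelineConfig, make_report, run_pipeline


@pytest.fixture(scope="module")
def fitted(default_dataset_module):
    cfg, matrix, truth, annotation = default_dataset_module
    results = PCAFeatureExtraction(matrix, annotation).fit()
    return cfg, matrix, truth, annotation, results


@pytest.fixture(scope="module")
def default_dataset_module():
    from pcafe.synthetic import SimulationConfig, generate_dataset, generate_probe_annotation

    config = SimulationConfig(seed=1)
    matrix, truth = generate_dataset(config)
    return config, matrix, truth, generate_probe_annotation(config)


class TestModel:
    def test_recovers_planted_component_and_probes(self, fitted):
        cfg, _, truth, _, results = fitted
        assert results.association.selected_component == cfg.signal_pc_index
        s, t = set(results.selected_probes), truth.spiked_probe_ids
        assert len(s & t) / len(s | t) >= 0.8

    def test_gene_symbols_fewer_than_probes(self, fitted):
        *_, results = fitted
        assert 0 < len(results.gene_symbols) < results.n_selected

    def test_classification_quality(self, fitted):
        *_, results = fitted
        c = results.classification
        assert c.accuracy >= 0.8
        assert c.auc >= 0.85
        assert c.confusion.sum() == 60

    def test_summary_contains_metric_suite(self, fitted):
        *_, results = fitted
        text = results.summary()
        for needle in ("sensitivity", "precision", "accuracy", "AUC",
                       "odds ratio", "Fisher exact", "selected probes"):
            assert needle in text

    def test_forced_component_matches_auto_scan(self, fitted):
        cfg, matrix, _, annotation, results = fitted
        forced = PCAFeatureExtraction(matrix, annotation).fit(
            forced_component=cfg.signal_pc_index
        )
        assert forced.selected_probes == results.selected_probes

    def test_missing_labels_rejected(self, fitted):
        from pcafe.containers import ExpressionMatrix

        _, matrix, *_ = fitted
        with pytest.raises(ValueError, match="labels"):
            PCAFeatureExtraction(ExpressionMatrix(matrix.values))

    def test_from_dataframe_constructor(self, small_matrix):
        model = PCAFeatureExtraction.from_dataframe(
            small_matrix.values, small_matrix.labels
        )
        results = model.fit(alpha=0.5, n_components_scan=3)
        assert results.decomposition.n_components == 3

    def test_log2_transform(self, small_matrix):
        values = np.exp(small_matrix.values)  # strictly positive
        model = PCAFeatureExtraction.from_dataframe(
            values, small_matrix.labels, log2_transform=True
        )
        expected = np.log2(values + 1.0)
        assert np.allclose(model.matrix.values.to_numpy(), expected.to_numpy())


class TestPipeline:
    def test_simulation_run_is_deterministic(self, tmp_path):
        kwargs = dict(seed=3, simulation={"n_probes": 800, "n_control": 12,
                                          "n_case": 10, "n_spiked_probes": 60},
                      n_genesets=10)
        b1 = run_pipeline(PipelineConfig(output_dir=str(tmp_path / "a"), **kwargs))
        b2 = run_pipeline(PipelineConfig(output_dir=str(tmp_path / "b"), **kwargs))
        m1, m2 = b1.manifest.copy(), b2.manifest.copy()
        m1["config"].pop("output_dir"), m2["config"].pop("output_dir")
        assert m1 == m2

    def test_bundle_files_written(self, tmp_path):
        out = tmp_path / "out"
        config = PipelineConfig(output_dir=str(out), seed=1, simulation={})
        bundle = run_pipeline(config)
        for name in ("selection.tsv", "association.tsv", "classification.json",
                     "manifest.json", "report.txt", "gene_symbols.txt",
                     "enrichment_synthetic.tsv"):
            assert (out / name).exists(), name
        manifest = json.loads((out / "manifest.json").read_text())
        counts = manifest["stage_counts"]
        # funnel is internally consistent
        assert counts["n_selected_probes"] >= counts["n_gene_symbols"]
        assert counts["n_gene_symbols"] >= counts["coverage"]["synthetic"]
        report = make_report(bundle)
        assert f"selected probes (BH-adjusted p <= 0.01): {counts['n_selected_probes']}" in report

    def test_null_run_completes_with_empty_selection(self, tmp_path):
        config = PipelineConfig(
            output_dir=str(tmp_path / "null"),
            seed=0,
            simulation={"effect_size": 0.0, "n_probes": 1000,
                        "n_control": 12, "n_case": 10, "n_spiked_probes": 50},
            n_genesets=5,
        )
        with pytest.warns(UserWarning, match="probe"):
            bundle = run_pipeline(config)
        assert bundle.manifest["stage_counts"]["n_selected_probes"] <= 20
        assert bundle.manifest["classification"] is None
        assert "enrichment" in make_report(bundle)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            PipelineConfig(simulation={}, expression="x.tsv", labels="l.tsv")
        with pytest.raises(ValueError, match="exactly one"):
            PipelineConfig()
        with pytest.raises(ValueError, match="alpha"):
            PipelineConfig(simulation={}, alpha_selection=2.0)

    def test_file_mode_matches_simulation_mode(self, tmp_path):
        """Writing the simulated dataset to disk and reading it back must
        give the same selection as the in-memory run."""
        from pcafe import io as pio
        from pcafe.synthetic import (SimulationConfig, generate_dataset,
                                     generate_probe_annotation)

        sim = dict(n_probes=800, n_control=12, n_case=10, n_spiked_probes=60)
        b_sim = run_pipeline(PipelineConfig(
            output_dir=str(tmp_path / "sim"), seed=5, simulation=sim, n_genesets=0,
        ))
        cfg = SimulationConfig(seed=5, **sim)
        matrix, _ = generate_dataset(cfg)
        ann = generate_probe_annotation(cfg)
        pio.write_expression_table(matrix, tmp_path / "expr.tsv")
        pio.write_labels(matrix.labels, tmp_path / "labels.tsv")
        pio.write_probe_annotation(ann, tmp_path / "ann.tsv")
        b_file = run_pipeline(PipelineConfig(
            output_dir=str(tmp_path / "file"), seed=5,
            expression=str(tmp_path / "expr.tsv"),
            labels=str(tmp_path / "labels.tsv"),
            annotation=str(tmp_path / "ann.tsv"),
        ))
        assert (b_file.manifest["stage_counts"]["n_selected_probes"]
                == b_sim.manifest["stage_counts"]["n_selected_probes"])
        assert b_file.results.selected_probes == b_sim.results.selected_probes


class TestCLI:
    def test_simulate_run_report_cycle(self, tmp_path):
        runner = CliRunner()
        data_dir = tmp_path / "data"
        r = runner.invoke(cli_main, [
            "simulate", "-o", str(data_dir), "--seed", "4",
            "--n-probes", "800", "--n-control", "12", "--n-case", "10",
        ])
        assert r.exit_code == 0, r.output
        for name in ("expression.tsv", "labels.tsv", "annotation.tsv",
                     "library.gmt", "truth.json"):
            assert (data_dir / name).exists()

        config = {
            "expression": str(data_dir / "expression.tsv"),
            "labels": str(data_dir / "labels.tsv"),
            "annotation": str(data_dir / "annotation.tsv"),
            "libraries": {"lib": str(data_dir / "library.gmt")},
            "output_dir": str(tmp_path / "out"),
            "seed": 4,
        }
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        r = runner.invoke(cli_main, ["run", "-c", str(cfg_path)])
        assert r.exit_code == 0, r.output
        assert "selected probes" in r.output

        r = runner.invoke(cli_main, ["report", "-d", str(tmp_path / "out")])
        assert r.exit_code == 0
        assert "stage counts" in r.output

    def test_enrich_subcommand(self, tmp_path):
        runner = CliRunner()
        (tmp_path / "query.txt").write_text("A\nB\nC\n")
        (tmp_path / "lib.gmt").write_text("T1\td\tA\tB\nT2\td\tX\tY\n")
        r = runner.invoke(cli_main, [
            "enrich", "-q", str(tmp_path / "query.txt"),
            "-g", str(tmp_path / "lib.gmt"), "-N", "1000",
        ])
        assert r.exit_code == 0, r.output
        assert "T1" in r.output and "2/2" in r.output

    def test_run_fails_nonzero_on_bad_config(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "bad.yaml"
        cfg_path.write_text(yaml.safe_dump({"seed": 1}))
        r = runner.invoke(cli_main, ["run", "-c", str(cfg_path)])
        assert r.exit_code != 0
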