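"""End-to-end orchestration: config file in, report bundle out.

The pipeline either reads an expression matrix (plus labels, annotation
and GMT libraries) from disk or simulates one, runs the two-pass
feature-extraction / classification analysis, enriches the selected gene
symbols against every library, and writes a fixed-name report bundle:

* ``selection.tsv`` — per-probe raw/adjusted p and selected flag
* ``association.tsv`` / ``association_pass2.tsv`` — per-component class p
* ``classification.json`` — scores, predictions, confusion, metric suite
* ``enrichment_<library>.tsv`` — Enrichr-style per-term results
* ``manifest.json`` — config, seed, stage counts, package version
* ``report.txt`` — human-readable summary

Every stage logs its counts; a failure in any stage removes the partial
bundle and re-raises with the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as _io
from .containers import CASE, CONTROL, ExpressionMatrix, GeneSetLibrary, ProbeAnnotation
from .enrich import DEFAULT_BACKGROUND_N, records_to_frame, summarize_mirna_coverage
from .model import PCAFeatureExtraction, PCAFEResults
from .synthetic import (
    SimulationConfig,
    generate_dataset,
    generate_genesets,
    generate_probe_annotation,
)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline", "make_report"]

logger = logging.getLogger("pcafe.pipeline")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Pipeline parameters; exactly one of input paths / simulation block.

    ``simulation`` holds :class:`SimulationConfig` keyword arguments. In
    file mode, ``expression`` and ``labels`` are required; ``annotation``
    and ``libraries`` (mapping name -> GMT path) are optional.
    """

    output_dir: str = "pcafe_out"
    seed: int = 0
    alpha_selection: float = 0.01
    alpha_enrichment: float = 0.05
    forced_component: int | None = None
    n_components_scan: int = 10
    log2_transform: bool = False
    background_N: int = DEFAULT_BACKGROUND_N
    # file mode
    expression: str | None = None
    labels: str | None = None
    annotation: str | None = None
    libraries: dict[str, str] = field(default_factory=dict)
    # simulation mode
    simulation: dict | None = None
    n_genesets: int = 50
    enriched_fraction: float = 0.2

    def __post_init__(self) -> None:
        file_mode = self.expression is not None
        sim_mode = self.simulation is not None
        if file_mode == sim_mode:
            raise ValueError(
                "config must set exactly one of 'expression' (file mode) "
                "or 'simulation' (simulation block)"
            )
        if file_mode and self.labels is None:
            raise ValueError("file mode requires a 'labels' path")
        for name, a in (("alpha_selection", self.alpha_selection),
                        ("alpha_enrichment", self.alpha_enrichment)):
            if not 0 < a < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class ReportBundle:
    """In-memory results plus the paths written."""

    results: PCAFEResults
    enrichments: dict[str, list]
    coverage: dict[str, dict]
    manifest: dict
    output_dir: Path


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation | None, dict[str, GeneSetLibrary], dict]:
    truth_payload: dict = {}
    if config.simulation is not None:
        sim = SimulationConfig(**{"seed": config.seed, **config.simulation})
        matrix, truth = generate_dataset(sim)
        annotation = generate_probe_annotation(sim)
        library = generate_genesets(
            truth,
            annotation,
            n_sets=config.n_genesets,
            enriched_fraction=config.enriched_fraction,
            seed=sim.seed,
        )
        libraries = {"synthetic": library} if len(library) else {}
        truth_payload = {
            "n_spiked_probes": len(truth.spiked_probe_ids),
            "n_spiked_symbols": len(truth.spiked_gene_symbols),
            "signal_pc_index": truth.signal_pc_index,
        }
        return matrix, annotation, libraries, truth_payload
    matrix = _io.read_expression_table(config.expression, config.labels)
    annotation = (
        _io.read_probe_annotation(config.annotation) if config.annotation else None
    )
    libraries = {name: _io.read_gmt(path) for name, path in config.libraries.items()}
    return matrix, annotation, libraries, truth_payload


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle to ``output_dir``."""
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except PipelineError:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
    except Exception as exc:  # pragma: no cover - safety net
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise PipelineError("unknown", exc) from exc


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(name, exc) from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def _run(config: PipelineConfig, out: Path) -> ReportBundle:
    with _stage("load"):
        matrix, annotation, libraries, truth_payload = _load_inputs(config)
        logger.info(
            "loaded %d probes x %d samples (%d control / %d case)",
            matrix.n_probes,
            matrix.n_samples,
            int((matrix.labels == CONTROL).sum()),
            int((matrix.labels == CASE).sum()),
        )

    with _stage("fit"):
        model = PCAFeatureExtraction(
            matrix, annotation, log2_transform=config.log2_transform
        )
        results = model.fit(
            alpha=config.alpha_selection,
            forced_component=config.forced_component,
            n_components_scan=config.n_components_scan,
        )
        logger.info(
            "selected %d probes on PC%d; %s gene symbols",
            results.n_selected,
            results.component_used,
            "n/a" if results.gene_symbols is None else len(results.gene_symbols),
        )

    enrichments: dict[str, list] = {}
    coverage: dict[str, dict] = {}
    with _stage("enrich"):
        if results.gene_symbols:
            # with an annotation the gene universe of the platform is known
            # and is the coherent hypergeometric background; the configured
            # background_N is the fallback for bare gene lists
            background = annotation.all_symbols if annotation is not None else None
            for name, library in libraries.items():
                records = results.enrich(
                    library, background_N=config.background_N, background=background
                )
                significant, covered, count = summarize_mirna_coverage(
                    results.gene_symbols, records, config.alpha_enrichment
                )
                enrichments[name] = records
                coverage[name] = {
                    "n_significant_terms": len(significant),
                    "significant_terms": [r.term for r in significant],
                    "coverage_count": count,
                    "covered_symbols": sorted(covered),
                }
                logger.info(
                    "library %s: %d terms, %d significant, coverage %d",
                    name, len(records), len(significant), count,
                )
        elif libraries:
            logger.warning("empty selection: enrichment skipped")

    with _stage("write"):
        manifest = _build_manifest(config, results, enrichments, coverage, truth_payload)
        _write_bundle(out, config, results, enrichments, manifest)
    return ReportBundle(results, enrichments, coverage, manifest, out)


def _build_manifest(config, results: PCAFEResults, enrichments, coverage, truth_payload):
    c = results.classification
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "stage_counts": {
            "n_probes": results.model.matrix.n_probes,
            "n_samples": results.model.matrix.n_samples,
            "n_control": int((results.model.matrix.labels == CONTROL).sum()),
            "n_case": int((results.model.matrix.labels == CASE).sum()),
            "component_used": results.component_used,
            "n_selected_probes": results.n_selected,
            "n_gene_symbols": (
                None if results.gene_symbols is None else len(results.gene_symbols)
            ),
            "n_libraries": len(enrichments),
            "n_significant_terms": {
                k: v["n_significant_terms"] for k, v in coverage.items()
            },
            "coverage": {k: v["coverage_count"] for k, v in coverage.items()},
        },
        "association_p": {
            str(k): float(v) for k, v in results.association.p_values.items()
        },
        "classification": None if c is None else {
            "confusion": c.confusion.tolist(),
            "sensitivity": c.sensitivity,
            "precision": c.precision,
            "f1": c.f1,
            "accuracy": c.accuracy,
            "auc": c.auc,
            "odds_ratio": c.odds_ratio,
            "fisher_p": c.fisher_p,
        },
    }
    if truth_payload:
        manifest["ground_truth"] = truth_payload
    return manifest


def _write_bundle(out: Path, config, results: PCAFEResults, enrichments, manifest):
    results.selection.as_frame().to_csv(out / "selection.tsv", sep="\t", index=False)
    results.association.as_frame().to_csv(out / "association.tsv", sep="\t", index=False)
    if results.second_association is not None:
        results.second_association.as_frame().to_csv(
            out / "association_pass2.tsv", sep="\t", index=False
        )
    if results.classification is not None:
        (out / "classification.json").write_text(
            json.dumps(results.classification.to_dict(), indent=2)
        )
        results.classification.confusion_frame().to_csv(out / "confusion.tsv", sep="\t")
    if results.gene_symbols is not None:
        (out / "gene_symbols.txt").write_text("\n".join(results.gene_symbols) + "\n")
    for name, records in enrichments.items():
        records_to_frame(records).to_csv(
            out / f"enrichment_{name}.tsv", sep="\t", index=False
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (out / "report.txt").write_text(make_report_from_parts(results, manifest))


def make_report(bundle: ReportBundle) -> str:
    """Human-readable summary of a finished run."""
    return make_report_from_parts(bundle.results, bundle.manifest)


def make_report_from_parts(results: PCAFEResults, manifest: dict) -> str:
    lines = [results.summary(), ""]
    counts = manifest["stage_counts"]
    if counts["n_libraries"] == 0:
        lines.append("enrichment: no libraries supplied or empty selection")
    for name, n_sig in (counts.get("n_significant_terms") or {}).items():
        if n_sig == 0:
            lines.append(f"library {name}: no significant terms")
        else:
            lines.append(
                f"library {name}: {n_sig} significant terms; "
                f"{counts['coverage'][name]} selected symbols covered"
            )
    return "\n".join(lines) + "\n"
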