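"""End-to-end orchestration: population -> table -> clusters -> indices ->
heatmap -> rarefaction -> model fits -> Nexus, with a provenance record.

Every artifact is a TSV/Nexus/JSON text file under one output directory;
the same seed and config always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import __version__
from .pham_core import (PhamTable, build_pham_table, read_gene_assignments,
                        shared_pham_matrix, write_gene_assignments)
from .sequence_compare import (ClusterPartition, assign_clusters, read_fasta,
                               similarity_span_matrix, write_fasta,
                               SimilaritySpanMatrix)
from .diversity import cluster_report, write_report_tsv
from .rarefaction import rarefaction
from .model_fit import FitError, fit_closed_model, fit_open_model
from .nexus import write_nexus_distances
from .synthetic_data import PopulationConfig, generate_population, generate_sequences

__all__ = ["RunConfig", "run_full_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters of one pipeline run.  Defaults mirror the study's
    conventions: word length 10, span threshold 0.5 on both genomes,
    10,000 rarefaction iterations, hyperbola fit to the first half."""

    out_dir: str = "phagepan_out"
    assignments_path: str | None = None
    fasta_path: str | None = None
    span_matrix_path: str | None = None
    population: PopulationConfig | None = None
    word_length: int = 10
    merge_gap: int | None = None
    threshold: float = 0.5
    rule: str = "both"
    iterations: int = 10_000
    fit_fraction: float = 0.5
    tail_window: int | None = None
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters; the output location is excluded
        so the same analysis is recognisable wherever it is written."""
        payload = _serialisable(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _serialisable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _serialisable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_serialisable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _serialisable(v) for k, v in obj.items()}
    return obj


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts; returns a result bundle.

    Stages: (1) read or generate the population; (2) pham table;
    (3) optional span matrix + cluster partition from sequences;
    (4) diversity indices; (5) shared-pham heatmap matrix; (6) rarefaction;
    (7) closed and open model fits; (8) Nexus export.  Any failure aborts
    with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"phagepan {__version__} config={config.config_hash()} seed={config.seed}"
    bundle: dict = {"config_hash": config.config_hash(), "out_dir": str(out)}

    # 1. population
    stage = "population"
    try:
        sequences = None
        if config.population is not None:
            pop = generate_population(config.population)
            assignments = pop.assignments
            write_gene_assignments(assignments, out / "assignments.tsv", tag)
            (out / "truth.json").write_text(json.dumps(pop.truth, indent=2, sort_keys=True))
            if config.population.sequence_opts is not None:
                sequences = generate_sequences(pop)
                write_fasta(sequences, out / "genomes.fasta")
        elif config.assignments_path:
            assignments = read_gene_assignments(config.assignments_path)
            if config.fasta_path:
                sequences = read_fasta(config.fasta_path)
        else:
            raise ValueError("need either a population config or an assignments path")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 2. pham table
    stage = "pham_table"
    try:
        table = build_pham_table(assignments)
        table.write_tsv(out / "pham_table.tsv", tag)
        bundle["n_genomes"], bundle["n_phams"] = table.n_genomes, table.n_phams
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 3. spans + clusters
    stage = "clustering"
    try:
        partition = None
        spans = None
        if config.span_matrix_path:
            spans = SimilaritySpanMatrix.read_tsv(config.span_matrix_path)
        elif sequences is not None:
            spans = similarity_span_matrix(sequences, config.word_length, config.merge_gap)
        if spans is not None:
            spans.write_tsv(out / "span_matrix.tsv", tag)
            partition = assign_clusters(spans, config.threshold, config.rule)
            (out / "clusters.json").write_text(
                json.dumps({"assignment": partition.assignment,
                            "singletons": sorted(partition.singletons)},
                           indent=2, sort_keys=True))
        else:
            # gene-content-only runs fall back to the truth partition if present
            truth_path = out / "truth.json"
            if truth_path.exists():
                cluster_of = json.loads(truth_path.read_text())["cluster_of"]
                labels = {}
                for g, c in cluster_of.items():
                    labels.setdefault(c, []).append(g)
                singles = {c for c, gs in labels.items() if len(gs) == 1}
                partition = ClusterPartition(dict(cluster_of), singles)
        bundle["partition"] = partition
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 4. indices
    stage = "indices"
    try:
        if partition is not None:
            report = cluster_report(table, partition)
            write_report_tsv(report, out / "cluster_indices.tsv", tag)
            bundle["report"] = report
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 5. heatmap matrix
    stage = "heatmap"
    try:
        shared = shared_pham_matrix(table)
        shared.write_tsv(out / "shared_pham_matrix.tsv", tag)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 6. rarefaction
    stage = "rarefaction"
    try:
        curve = rarefaction(table, config.iterations, config.seed)
        curve.write_tsv(out / "rarefaction.tsv", tag)
        bundle["rarefaction"] = curve
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 7. model fits
    stage = "model_fit"
    try:
        fits = {}
        try:
            closed = fit_closed_model(curve, config.fit_fraction)
            fits["closed"] = {"pham_max": closed.pham_max, "k_m": closed.k_m,
                              "fit_range": list(closed.fit_range), "r": closed.r}
        except FitError as e:
            fits["closed"] = {"error": str(e)}
        try:
            opened = fit_open_model(curve, config.fit_fraction, config.tail_window)
            fits["open"] = {"c_phage": opened.c_phage, "pham_max": opened.pham_max,
                            "k_m": opened.k_m, "fit_range": list(opened.fit_range),
                            "tail_window": opened.tail_window, "r": opened.r}
        except FitError as e:
            fits["open"] = {"error": str(e)}
        (out / "model_fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
        bundle["fits"] = fits
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # 8. nexus
    stage = "nexus"
    try:
        write_nexus_distances(shared, out / "gene_content.nex")
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    provenance = {"version": __version__, "config": _serialisable(config),
                  "config_hash": config.config_hash()}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    return bundle
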