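"""End-to-end orchestration: simulate -> qc -> map -> quantify -> call ->
homology -> divergence -> reciprocal -> presence -> report.

Every stage's parameters and output files are recorded in a manifest
(with sha256 checksums) so that a rerun with the same configuration can
be verified byte-identical.  The in-silico presence check stands in for
the original genomic PCR assay: a flagged gene found near-verbatim in
the polyploid genome sequences is a *silenced candidate*, one absent
from them a *deletion candidate*.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .absence import AbsenceResult, call_undetected
from .align import HOMOLOGY_SCHEME, MAPPING_SCHEME, ReferenceIndex, ScoringScheme
from .containers import ReferenceContig
from .divergence import (
    DEFAULT_BIN_EDGES,
    HomologySearcher,
    IdentityDistribution,
    ReciprocalSummary,
    compare_distributions,
    hits_frame,
    identity_distribution,
    results_frame,
    reciprocal_classify,
    sample_control,
    search_all,
)
from .errors import ConfigurationError
from .expression import ExpressionMatrix, count_unique
from .io import write_tsv
from .qc import QCParams, qc_library
from .simulate import DELETED, SILENCED, SimulationConfig, SyntheticExperiment, simulate_experiment

log = logging.getLogger("allosilence")


@dataclass
class RunConfig:
    """Full pipeline configuration with the study defaults surfaced by name."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QCParams = field(default_factory=QCParams)
    mapping_scheme: ScoringScheme = MAPPING_SCHEME
    homology_scheme: ScoringScheme = HOMOLOGY_SCHEME
    min_parent_reads: int = 10
    expression_fraction_f: float = 1.0 / 3.0
    min_block_length: int = 100
    presence_min_identity: float = 98.0
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_control: int = 200
    control_seed: int = 20_140_914
    output_dir: str = "results/pipeline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw.pop("simulation"))
        if "qc" in raw:
            kwargs["qc"] = QCParams(**raw.pop("qc"))
        for key in ("mapping_scheme", "homology_scheme"):
            if key in raw:
                kwargs[key] = ScoringScheme(**raw.pop(key))
        if "bin_edges" in raw:
            raw["bin_edges"] = tuple(raw["bin_edges"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    config: RunConfig
    experiment: SyntheticExperiment
    qc_report: pd.DataFrame
    matrix: ExpressionMatrix
    absence: AbsenceResult
    flagged_hits: dict
    control_hits: dict
    flagged_distribution: IdentityDistribution
    control_distribution: IdentityDistribution
    per_class_tests: pd.DataFrame
    global_test: pd.DataFrame
    reciprocal: ReciprocalSummary
    presence: pd.DataFrame
    confusion: pd.DataFrame
    manifest: dict


def genome_presence_check(
    flagged: Sequence[ReferenceContig],
    genome: Sequence[ReferenceContig],
    min_block_length: int = 100,
    min_identity: float = 98.0,
    scheme: ScoringScheme = HOMOLOGY_SCHEME,
) -> pd.DataFrame:
    """Classify flagged genes as present (silenced candidate) or absent
    (deletion candidate) by searching the polyploid genome sequences."""
    if not genome:
        raise ConfigurationError("polyploid genome sequence set is empty")
    searcher = HomologySearcher(
        genome, "polyploid_genome", scheme, min_block_length
    )
    rows = []
    for gene in flagged:
        hit = searcher.best_hit(gene)
        present = hit is not None and hit.aggregated_identity >= min_identity
        rows.append(
            {
                "contig": gene.id,
                "present_in_genome": present,
                "best_genome_match": hit.subject_id if hit else None,
                "genome_identity": hit.aggregated_identity if hit else np.nan,
                "classification": "silenced candidate" if present else "deletion candidate",
            }
        )
    return pd.DataFrame(rows).set_index("contig")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> PipelineResult:
    """Execute all stages on a synthetic experiment; see module docstring."""
    outdir = Path(config.output_dir)
    stage = "simulate"
    try:
        exp = simulate_experiment(config.simulation)
        genes_by_id = {g.id: g for g in exp.genes}

        stage = "qc"
        cleaned, reports = [], []
        for lib in exp.libraries:
            c, rep = qc_library(lib, config.qc)
            cleaned.append(c)
            reports.append(rep.to_row())
        qc_report = pd.DataFrame(reports).set_index("library")
        log.info("qc: %d reads rejected", int(qc_report["rejected_reads"].sum()))

        stage = "map"
        index = ReferenceIndex(exp.genes, config.mapping_scheme)
        mappings = [index.map_library(lib) for lib in cleaned]

        stage = "quantify"
        depths = {lib.library_id: lib.n_reads for lib in cleaned}
        species = {lib.library_id: lib.species for lib in cleaned}
        matrix = count_unique(mappings, exp.genes, depths, species)

        stage = "call_absent"
        absence = call_undetected(
            matrix,
            min_parent_reads=config.min_parent_reads,
            f=config.expression_fraction_f,
        )
        flagged_ids = absence.high_confidence_ids
        log.info(
            "absence: %d all-undetected, %d high-confidence",
            len(absence.undetected_ids),
            len(flagged_ids),
        )

        stage = "homology"
        searcher = HomologySearcher(
            exp.comparators,
            "partner_subgenome",
            config.homology_scheme,
            config.min_block_length,
        )
        flagged_genes = [genes_by_id[g] for g in flagged_ids]
        flagged_hits = search_all(flagged_genes, searcher)

        stage = "divergence"
        control_ids = sample_control(
            exp.genes,
            n=config.n_control,
            seed=config.control_seed,
            exclude=set(absence.undetected_ids),
        )
        control_hits = search_all([genes_by_id[g] for g in control_ids], searcher)
        flagged_dist = identity_distribution(
            {q: (h.aggregated_identity if h else None) for q, h in flagged_hits.items()},
            config.bin_edges,
        )
        control_dist = identity_distribution(
            {q: (h.aggregated_identity if h else None) for q, h in control_hits.items()},
            config.bin_edges,
        )
        per_class = results_frame(
            compare_distributions(flagged_dist, control_dist, mode="per-class")
        )
        global_test = results_frame(
            compare_distributions(flagged_dist, control_dist, mode="global")
        )

        stage = "reciprocal"
        reciprocal = reciprocal_classify(
            [h for h in flagged_hits.values() if h is not None],
            exp.comparators,
            exp.genes,
            config.homology_scheme,
            config.min_block_length,
        )

        stage = "presence"
        presence = genome_presence_check(
            flagged_genes,
            exp.polyploid_genome,
            config.min_block_length,
            config.presence_min_identity,
            config.homology_scheme,
        )

        stage = "report"
        truth = exp.truth.set_index("gene_id")
        confusion = pd.crosstab(
            truth["status"],
            pd.Series(
                np.where(truth.index.isin(flagged_ids), "flagged", "not_flagged"),
                index=truth.index,
                name="called",
            ),
        )
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "seed": config.simulation.seed,
        "parameters": {
            "qc": dataclasses.asdict(config.qc),
            "mapping_scheme": dataclasses.asdict(config.mapping_scheme),
            "homology_scheme": dataclasses.asdict(config.homology_scheme),
            "min_parent_reads": config.min_parent_reads,
            "expression_fraction_f": config.expression_fraction_f,
            "min_block_length": config.min_block_length,
            "presence_min_identity": config.presence_min_identity,
            "n_control": config.n_control,
            "simulation": dataclasses.asdict(config.simulation),
        },
        "outputs": {},
    }
    result = PipelineResult(
        config,
        exp,
        qc_report,
        matrix,
        absence,
        flagged_hits,
        control_hits,
        flagged_dist,
        control_dist,
        per_class,
        global_test,
        reciprocal,
        presence,
        confusion,
        manifest,
    )
    if write_outputs:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "qc_report.tsv": result.qc_report,
        "counts.tsv": result.matrix.counts,
        "rpkm.tsv": result.matrix.rpkm(),
        "absence_calls.tsv": result.absence.table,
        "flagged_hits.tsv": hits_frame(result.flagged_hits),
        "control_hits.tsv": hits_frame(result.control_hits),
        "identity_distributions.tsv": result.flagged_distribution.to_frame(
            "non_expressed"
        ).join(result.control_distribution.to_frame("control")),
        "chi2_per_class.tsv": result.per_class_tests,
        "chi2_global.tsv": result.global_test,
        "reciprocal.tsv": result.reciprocal.table,
        "presence_check.tsv": result.presence,
        "confusion.tsv": result.confusion,
    }
    for name, df in tables.items():
        write_tsv(df, outdir / name)
        result.manifest["outputs"][name] = _sha256(outdir / name)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
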