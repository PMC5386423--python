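"""End-to-end orchestration: QC -> dual-caller CNV calling -> consensus ->
gene overlap -> association -> discrete FDR, on in-memory domain objects."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .association import GenomewideResults, build_outcomes, run_genomewide
from .calling import apply_consensus_filters, call_hmm, call_segmentation, merge_consensus
from .config import PipelineConfig
from .io import IntensityReport
from .overlap import CarrierMatrix, build_gene_intervals, intersect_deletions_genes
from .qc import compute_sample_metrics, filter_samples

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    kept_samples: list
    excluded_samples: list
    consensus_calls: list = field(repr=False)
    removed_calls: list = field(repr=False)
    matrix: CarrierMatrix = field(repr=False)
    genomewide: GenomewideResults = field(repr=False)
    association_table: pd.DataFrame = field(repr=False)


def run_pipeline(
    report: IntensityReport,
    transcripts: pd.DataFrame,
    phenotypes: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the whole analysis on one cohort.

    Samples failing QC are dropped; both callers run on every kept sample;
    per-sample calls are merged into consensus calls and filtered; kept
    deletions are intersected with transcript-union gene intervals; each
    gene with carriers gets a retrospective-likelihood score test for the
    configured endpoint; q-values use count filtering plus Benjamini-
    Hochberg.
    """
    config = config or PipelineConfig()
    metrics = [compute_sample_metrics(report, s, config) for s in report.samples]
    kept_samples, excluded = filter_samples(metrics, config)

    calls = []
    for sample in kept_samples:
        calls.extend(call_hmm(report, sample, config.hmm))
        calls.extend(call_segmentation(report, sample, config.seg))
    consensus = merge_consensus(calls, config) if calls else []
    kept_calls, removed = apply_consensus_filters(consensus, config)

    genes = build_gene_intervals(transcripts)
    matrix = intersect_deletions_genes(kept_calls, genes, samples=kept_samples)

    outcomes = build_outcomes(
        phenotypes[phenotypes["sample"].isin(kept_samples)], config.analysis.endpoint
    )
    gw = run_genomewide(matrix, outcomes, config.incidence(config.analysis.endpoint))
    table = gw.with_qvalues(
        count_threshold=config.analysis.qvalue_count_threshold,
        alpha=config.analysis.alpha,
    )
    return PipelineResult(
        kept_samples=kept_samples, excluded_samples=excluded,
        consensus_calls=kept_calls, removed_calls=removed,
        matrix=matrix, genomewide=gw, association_table=table,
    )
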