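"""Pipeline configuration: QC thresholds, caller parameters, consensus rules,
baseline incidence tables and analysis options.

Defaults mirror the thresholds used for Illumina 610k-class array QC
(log R ratio s.d. > 0.28, BAF drift > 0.01, |waviness factor| > 0.05,
BAF outliers > 0.1, LRR outliers >= 0.1, BAF s.d. >= 0.2, LRR s.d. >= 0.4)
and the consensus filters (calls >= 1000 kb or supported by a single
algorithm are dropped; conflicting MHC calls are dropped).
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, asdict

import yaml

from .errors import ValidationError
from .incidence import IncidenceModel, default_breast_incidence, default_ovarian_incidence

__all__ = [
    "QcRule",
    "QcThresholds",
    "HmmParams",
    "SegParams",
    "ConsensusParams",
    "AnalysisOptions",
    "PipelineConfig",
    "load_config",
]

_OPS = {">": operator.gt, ">=": operator.ge}


@dataclass(frozen=True)
class QcRule:
    """One exclusion rule: a sample fails if ``op(metric, threshold)``."""

    name: str
    metric: str  # attribute of SampleQcMetrics; "abs_waviness_factor" allowed
    op: str  # ">" (strict) or ">=" (inclusive), exactly as quoted
    threshold: float

    def fires(self, value: float) -> bool:
        return _OPS[self.op](value, self.threshold)


def default_qc_rules() -> tuple:
    return (
        QcRule("lrr_sd_gt_0.28", "lrr_sd", ">", 0.28),
        QcRule("baf_drift_gt_0.01", "baf_drift", ">", 0.01),
        QcRule("waviness_abs_gt_0.05", "abs_waviness_factor", ">", 0.05),
        QcRule("baf_outliers_gt_0.1", "baf_outlier_rate", ">", 0.1),
        QcRule("lrr_outliers_ge_0.1", "lrr_outlier_rate", ">=", 0.1),
        QcRule("baf_sd_ge_0.2", "baf_sd", ">=", 0.2),
        QcRule("lrr_sd_ge_0.4", "lrr_sd", ">=", 0.4),
    )


@dataclass(frozen=True)
class QcThresholds:
    rules: tuple = field(default_factory=default_qc_rules)
    # band of drifted homozygote BAF values counted toward baf_drift
    drift_band_low: tuple = (0.20, 0.25)
    drift_band_high: tuple = (0.75, 0.80)
    # heterozygous mid-band used for baf_sd and BAF outlier rate
    het_band: tuple = (0.25, 0.75)
    waviness_window_bp: int = 1_000_000
    min_usable_probes: int = 100
    exclude_chromosomes: tuple = ("X", "Y", "chrX", "chrY", "23", "24")


@dataclass(frozen=True)
class HmmParams:
    """Five-state (copy number 0-4) HMM over ordered probes.

    Emission: LRR ~ Normal(mu_state, sigma_state); BAF ~ equal-weight mixture
    over the genotype clusters implied by the state (copy 0 emits uniform BAF).
    Transitions are distance-dependent: stay probability
    ``1 - p_event * (1 - exp(-d / distance_scale_bp))`` for inter-probe gap d,
    with the off-diagonal mass split evenly over the other four states.
    """

    lrr_means: tuple = (-3.5, -0.66, 0.0, 0.40, 0.68)
    lrr_sds: tuple = (1.0, 0.20, 0.20, 0.20, 0.20)
    baf_sd: float = 0.04
    p_event: float = 0.005
    distance_scale_bp: float = 100_000.0
    min_probes: int = 3

    def __post_init__(self):
        if len(self.lrr_means) != 5 or len(self.lrr_sds) != 5:
            raise ValidationError("HMM needs 5 LRR means and s.d.s (copy 0-4)")
        if self.lrr_means[1] >= 0:
            raise ValidationError("copy-1 LRR mean must be negative")
        if not 0 < self.p_event < 1:
            raise ValidationError("p_event must lie in (0,1)")


@dataclass(frozen=True)
class SegParams:
    """Recursive (circular-style) binary segmentation of LRR.

    Each segment is scanned for the interior window whose mean differs most
    from the rest by the pooled two-sample t statistic; a window touching a
    segment end is an ordinary binary split.  Windows are capped at
    ``max_width_probes`` (events near or above the consensus length filter
    need no wider scan), keeping the scan linear in segment length.
    """

    t_threshold: float = 5.0
    min_probes: int = 3
    max_width_probes: int = 300
    del_threshold: float = -0.30  # segment mean below -> copy 1
    hom_del_threshold: float = -2.0  # segment mean below -> copy 0
    dup_threshold: float = 0.25  # segment mean above -> copy 3


@dataclass(frozen=True)
class ConsensusParams:
    min_support: int = 2
    max_length_bp: int = 1_000_000
    mhc_chromosome: str = "chr6"
    mhc_start: int = 29_600_000
    mhc_end: int = 33_100_000

    def __post_init__(self):
        if self.min_support < 1:
            raise ValidationError("min_support must be >= 1")


@dataclass(frozen=True)
class AnalysisOptions:
    endpoint: str = "breast"
    qvalue_count_threshold: int = 4  # genes with fewer deletions are filtered
    alpha: float = 0.05
    frequency_convention: str = "carrier"  # carrier proportion, not allele count/2N


@dataclass(frozen=True)
class PipelineConfig:
    qc: QcThresholds = field(default_factory=QcThresholds)
    hmm: HmmParams = field(default_factory=HmmParams)
    seg: SegParams = field(default_factory=SegParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    incidence_breast: IncidenceModel = field(default_factory=default_breast_incidence)
    incidence_ovarian: IncidenceModel = field(default_factory=default_ovarian_incidence)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    def incidence(self, endpoint: str) -> IncidenceModel:
        if endpoint == "breast":
            return self.incidence_breast
        if endpoint == "ovarian":
            return self.incidence_ovarian
        raise ValidationError(f"unknown endpoint {endpoint!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _build(cls, data, **overrides):
    return cls(**{**data, **overrides}) if data else cls(**overrides)


def load_config(path=None) -> PipelineConfig:
    """Load a YAML config; omitted sections keep their defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    if "qc" in raw:
        qc = dict(raw["qc"])
        if "rules" in qc:
            qc["rules"] = tuple(QcRule(**r) for r in qc["rules"])
        for key in ("drift_band_low", "drift_band_high", "het_band", "exclude_chromosomes"):
            if key in qc:
                qc[key] = tuple(qc[key])
        kwargs["qc"] = QcThresholds(**qc)
    if "hmm" in raw:
        hmm = dict(raw["hmm"])
        for key in ("lrr_means", "lrr_sds"):
            if key in hmm:
                hmm[key] = tuple(hmm[key])
        kwargs["hmm"] = HmmParams(**hmm)
    if "seg" in raw:
        kwargs["seg"] = SegParams(**raw["seg"])
    if "consensus" in raw:
        kwargs["consensus"] = ConsensusParams(**raw["consensus"])
    for key in ("incidence_breast", "incidence_ovarian"):
        if key in raw:
            inc = dict(raw[key])
            inc["breaks"] = tuple(inc["breaks"])
            inc["hazards"] = tuple(inc["hazards"])
            kwargs[key] = IncidenceModel(**inc)
    if "analysis" in raw:
        kwargs["analysis"] = AnalysisOptions(**raw["analysis"])
    return PipelineConfig(**kwargs)
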