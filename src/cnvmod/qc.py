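"""Per-sample array quality metrics and exclusion rules.

The metrics mirror the PennCNV/QuantiSNP-style summaries used to screen
Illumina array data: s.d. of autosomal LRR, BAF drift (mass in the
drifted-homozygote bands), a signed waviness factor from 1 Mb moving medians
of LRR, robust outlier rates for LRR and mid-band BAF, and mid-band BAF s.d.
A sample is excluded if any configured threshold rule fires; inequalities
are applied exactly as stated (e.g. LRR s.d. > 0.28 strict, LRR outliers
>= 0.1 inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InsufficientDataError
from .io import IntensityReport

__all__ = ["SampleQcMetrics", "compute_sample_metrics", "filter_samples", "metrics_table"]

MAD_SCALE = 1.4826  # consistency factor: MAD -> Gaussian s.d.


@dataclass(frozen=True)
class SampleQcMetrics:
    sample: str
    lrr_sd: float
    baf_drift: float
    waviness_factor: float
    baf_outlier_rate: float
    lrr_outlier_rate: float
    baf_sd: float
    passed: bool = True
    failed_rules: tuple = field(default_factory=tuple)

    @property
    def abs_waviness_factor(self) -> float:
        return abs(self.waviness_factor)


def _robust_outlier_rate(x: np.ndarray) -> float:
    """Fraction of values beyond ±3 robust s.d. (1.4826*MAD) of the median."""
    if x.size == 0:
        return 0.0
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    sd = MAD_SCALE * mad
    if sd == 0:
        return float(np.mean(x != med))
    return float(np.mean(np.abs(x - med) > 3.0 * sd))


def _waviness_factor(lrr, positions, chromosomes, window_bp) -> float:
    """Signed s.d. of per-window median LRR.

    Windows are consecutive ``window_bp`` bins within each chromosome; the
    sign is the sign of the lag-1 autocorrelation of the window medians
    (positive autocorrelation = slowly varying waves).
    """
    medians = []
    for chrom in pd.unique(chromosomes):
        m = chromosomes == chrom
        pos = positions[m]
        vals = lrr[m]
        ok = ~np.isnan(vals)
        pos, vals = pos[ok], vals[ok]
        if pos.size == 0:
            continue
        bins = (pos - pos[0]) // window_bp
        for b in np.unique(bins):
            medians.append(np.median(vals[bins == b]))
    medians = np.asarray(medians)
    if medians.size < 2:
        return 0.0
    sd = float(np.std(medians, ddof=1))
    a, b = medians[:-1], medians[1:]
    va, vb = np.std(a), np.std(b)
    if va == 0 or vb == 0:
        sign = 1.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
        sign = -1.0 if corr < 0 else 1.0
    return sign * sd


def compute_sample_metrics(
    report: IntensityReport, sample: str, params: PipelineConfig
) -> SampleQcMetrics:
    """Compute the QC metric vector for one sample (autosomes only)."""
    qc = params.qc
    auto = ~report.probes["chromosome"].isin(qc.exclude_chromosomes).to_numpy()
    lrr = report.sample_lrr(sample)[auto]
    baf = report.sample_baf(sample)[auto]
    positions = report.probes["position"].to_numpy()[auto]
    chroms = report.probes["chromosome"].to_numpy()[auto]

    usable = ~np.isnan(lrr)
    if int(usable.sum()) < qc.min_usable_probes:
        raise InsufficientDataError(
            f"sample {sample!r}: {int(usable.sum())} usable probes "
            f"(need >= {qc.min_usable_probes})"
        )
    lrr_ok = lrr[usable]
    baf_ok = baf[~np.isnan(baf)]

    lo, hi = qc.het_band
    het = baf_ok[(baf_ok >= lo) & (baf_ok <= hi)]
    (dl0, dl1), (dh0, dh1) = qc.drift_band_low, qc.drift_band_high
    drifted = ((baf_ok >= dl0) & (baf_ok < dl1)) | ((baf_ok > dh0) & (baf_ok <= dh1))

    metrics = SampleQcMetrics(
        sample=sample,
        lrr_sd=float(np.std(lrr_ok, ddof=1)),
        baf_drift=float(np.mean(drifted)) if baf_ok.size else 0.0,
        waviness_factor=_waviness_factor(lrr, positions, chroms, qc.waviness_window_bp),
        baf_outlier_rate=_robust_outlier_rate(het),
        lrr_outlier_rate=_robust_outlier_rate(lrr_ok),
        baf_sd=float(np.std(het, ddof=1)) if het.size > 1 else 0.0,
    )
    failed = tuple(
        rule.name for rule in qc.rules if rule.fires(getattr(metrics, rule.metric))
    )
    return SampleQcMetrics(
        **{**metrics.__dict__, "passed": not failed, "failed_rules": failed}
    )


def filter_samples(metrics, params: PipelineConfig):
    """Partition samples into (kept sample names, excluded metric records)."""
    kept, excluded = [], []
    for m in metrics:
        failed = tuple(
            rule.name for rule in params.qc.rules if rule.fires(getattr(m, rule.metric))
        )
        if failed:
            excluded.append(
                SampleQcMetrics(**{**m.__dict__, "passed": False, "failed_rules": failed})
            )
        else:
            kept.append(m.sample)
    return kept, excluded


def metrics_table(metrics) -> pd.DataFrame:
    rows = []
    for m in metrics:
        d = dict(m.__dict__)
        d["failed_rules"] = ";".join(d["failed_rules"])
        rows.append(d)
    return pd.DataFrame(rows)
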