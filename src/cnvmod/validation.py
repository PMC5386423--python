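"""Concordance arithmetic: detection sensitivity/specificity against a truth
set, validation-rate summaries and CNV-map overlap checks.

"Specificity" here is the fraction of calls confirmed by truth (a positive
predictive value): true negatives are not countable for rare structural
variants, so the convention follows how array-CNV studies report it (e.g.
14/14 confirmed calls = 100% specificity).  Percentages are rounded to the
nearest integer, half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "TruthComparison",
    "round_half_up",
    "locus_detection_metrics",
    "validation_rate",
    "false_negative_rate",
    "map_concordance",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (64.5 -> 65)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _pct(num: int, den: int) -> int:
    return round_half_up(100.0 * num / den)


@dataclass(frozen=True)
class TruthComparison:
    """Detection counts for one locus and the derived rates."""

    n_called_confirmed: int
    n_called_unconfirmed: int
    n_truth_detected: int
    n_truth_missed: int

    @property
    def sensitivity(self) -> float:
        """Detected truth / all truth; NaN when there is no truth."""
        tot = self.n_truth_detected + self.n_truth_missed
        return np.nan if tot == 0 else self.n_truth_detected / tot

    @property
    def specificity(self) -> float:
        """Confirmed calls / all calls (positive predictive value)."""
        tot = self.n_called_confirmed + self.n_called_unconfirmed
        return np.nan if tot == 0 else self.n_called_confirmed / tot

    @property
    def sensitivity_pct(self):
        s = self.sensitivity
        return None if np.isnan(s) else round_half_up(100.0 * s)

    @property
    def specificity_pct(self):
        s = self.specificity
        return None if np.isnan(s) else round_half_up(100.0 * s)


def _overlaps(a_start, a_end, b_start, b_end) -> bool:
    return max(a_start, b_start) <= min(a_end, b_end)


def locus_detection_metrics(called, truth_segments, locus) -> TruthComparison:
    """Compare kept consensus deletions against truth segments at one locus.

    A truth segment is detected if a deletion call of the same sample
    overlaps it by >= 1 bp; a call overlapping the locus is confirmed if it
    overlaps a truth segment of the same sample.  ``truth_segments`` is a
    frame with sample/chromosome/start/end restricted to the locus.
    """
    calls = [
        c for c in called
        if c.direction == "deletion" and c.chromosome == locus.chromosome
        and _overlaps(c.start, c.end, locus.start, locus.end)
    ]
    truth = truth_segments[truth_segments["chromosome"] == locus.chromosome]
    detected = missed = 0
    for _, seg in truth.iterrows():
        hit = any(
            c.sample == seg["sample"] and _overlaps(c.start, c.end, seg["start"], seg["end"])
            for c in calls
        )
        detected += hit
        missed += not hit
    confirmed = unconfirmed = 0
    for c in calls:
        own = truth[truth["sample"] == c.sample]
        hit = any(_overlaps(c.start, c.end, s, e) for s, e in zip(own["start"], own["end"]))
        confirmed += hit
        unconfirmed += not hit
    return TruthComparison(
        n_called_confirmed=confirmed, n_called_unconfirmed=unconfirmed,
        n_truth_detected=detected, n_truth_missed=missed,
    )


def validation_rate(attempted, confirmed) -> int:
    """Percentage of attempted loci confirmed by assay (e.g. 8 of 29 -> 28)."""
    attempted, confirmed = set(attempted), set(confirmed)
    if not confirmed <= attempted:
        raise ValidationError("confirmed loci must be a subset of attempted loci")
    if not attempted:
        raise ValidationError("no attempted loci")
    return _pct(len(confirmed), len(attempted))


def false_negative_rate(assay_positive_call_negative: int, call_negative_total: int) -> int:
    """Percentage of call-negative sites the assay found positive (7/352 -> 2)."""
    if call_negative_total <= 0:
        raise ValidationError("denominator must be > 0")
    return _pct(assay_positive_call_negative, call_negative_total)


def map_concordance(loci, map_regions):
    """Which loci overlap a published CNV-map region by >= 1 bp.

    ``map_regions`` is an iterable of (chromosome, start, end).  Returns
    ``(per-locus bool list, on-map percentage)``; an empty locus list yields
    0% with no flags.
    """
    regions = list(map_regions)
    flags = [
        any(r[0] == g.chromosome and _overlaps(g.start, g.end, r[1], r[2]) for r in regions)
        for g in loci
    ]
    pct = _pct(sum(flags), len(flags)) if flags else 0
    return flags, pct
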