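"""Per-sample CNV calling and cross-caller consensus.

Two independent callers are provided: a five-state hidden Markov model over
ordered probes (copy numbers 0-4, distance-dependent transitions, joint
LRR/BAF emissions, Viterbi decoding) and a recursive binary segmentation of
the LRR signal.  Their calls are merged per sample and direction by
transitive >=1 bp overlap into consensus calls, which are then filtered:
calls >= ``max_length_bp`` are dropped, calls supported by fewer than
``min_support`` callers are dropped, and within the configured MHC region a
sample showing both a supported deletion and a supported duplication has
both removed as irreconcilable.

All boundaries are probe positions; coordinates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .config import HmmParams, SegParams, PipelineConfig
from .errors import ValidationError
from .io import IntensityReport

__all__ = [
    "CnvCall",
    "ConsensusCall",
    "call_hmm",
    "call_segmentation",
    "merge_consensus",
    "apply_consensus_filters",
    "hmm_log_emissions",
    "hmm_transition_probs",
    "best_interior_window",
]

# genotype BAF cluster means implied by each copy-number state; copy 0 has no
# genotype and emits uniform BAF
_BAF_CLUSTERS = {
    1: (0.0, 1.0),
    2: (0.0, 0.5, 1.0),
    3: (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0),
    4: (0.0, 0.25, 0.5, 0.75, 1.0),
}

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class CnvCall:
    sample: str
    chromosome: str
    start: int
    end: int
    state: int  # copy number, never 2
    n_probes: int
    confidence: float  # log-likelihood ratio vs. the all-diploid path
    caller: str

    def __post_init__(self):
        if self.state == 2:
            raise ValidationError("a CNV call cannot have copy number 2")
        if self.start > self.end:
            raise ValidationError("call start must be <= end")

    @property
    def direction(self) -> str:
        return "deletion" if self.state < 2 else "duplication"


@dataclass(frozen=True)
class ConsensusCall:
    sample: str
    chromosome: str
    start: int
    end: int
    direction: str
    support: frozenset
    member_calls: tuple = field(default_factory=tuple)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def hmm_log_emissions(lrr, baf, params: HmmParams) -> np.ndarray:
    """Per-probe log emission densities, shape ``(n_probes, 5)``.

    LRR term: Normal(mu_state, sigma_state).  BAF term: equal-weight Gaussian
    mixture over the state's genotype clusters; copy 0 emits uniform BAF
    (log-density 0).  A missing LRR or BAF contributes 0 to its term, so
    masked probes are effectively skipped without breaking the probe order.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    n = lrr.size
    out = np.zeros((n, 5))
    mus = np.asarray(params.lrr_means)
    sds = np.asarray(params.lrr_sds)
    ok = ~np.isnan(lrr)
    z = (lrr[ok, None] - mus[None, :]) / sds[None, :]
    out[ok, :] = -0.5 * z * z - np.log(sds)[None, :] - 0.5 * _LOG_2PI
    okb = ~np.isnan(baf)
    bsd = params.baf_sd
    for state, clusters in _BAF_CLUSTERS.items():
        c = np.asarray(clusters)
        zz = (baf[okb, None] - c[None, :]) / bsd
        dens = np.exp(-0.5 * zz * zz) / (bsd * np.sqrt(2.0 * np.pi))
        out[okb, state] += np.log(dens.mean(axis=1) + 1e-300)
    # copy 0: uniform BAF on [0,1] -> log-density 0, nothing to add
    return out


def hmm_transition_probs(gaps_bp, params: HmmParams):
    """(stay, off) probabilities per inter-probe step.

    stay = 1 - p_event * (1 - exp(-d / D)); the remaining mass is split
    evenly over the four other states.
    """
    d = np.asarray(gaps_bp, dtype=float)
    stay = 1.0 - params.p_event * (1.0 - np.exp(-d / params.distance_scale_bp))
    off = (1.0 - stay) / 4.0
    return stay, off


@njit(cache=False)
def _viterbi(log_emit, log_stay, log_off):  # pragma: no cover - exercised via call_hmm
    n, k = log_emit.shape
    dp = np.empty((n, k))
    back = np.zeros((n, k), dtype=np.int64)
    for s in range(k):
        dp[0, s] = log_emit[0, s]  # uniform initial distribution (constant dropped)
    for t in range(1, n):
        for s in range(k):
            best = -1e300
            arg = 0
            for r in range(k):
                step = log_stay[t - 1] if r == s else log_off[t - 1]
                v = dp[t - 1, r] + step
                if v > best:
                    best = v
                    arg = r
            dp[t, s] = best + log_emit[t, s]
            back[t, s] = arg
    path = np.empty(n, dtype=np.int64)
    s = int(np.argmax(dp[n - 1]))
    path[n - 1] = s
    for t in range(n - 2, -1, -1):
        s = back[t + 1, s]
        path[t] = s
    return path


def viterbi_path(log_emit, log_stay, log_off) -> np.ndarray:
    """Most likely state path (uniform initial distribution, ties -> lower state)."""
    return np.asarray(
        _viterbi(np.ascontiguousarray(log_emit, dtype=np.float64),
                 np.ascontiguousarray(log_stay, dtype=np.float64),
                 np.ascontiguousarray(log_off, dtype=np.float64))
    )


def call_hmm(report: IntensityReport, sample: str, params: HmmParams) -> list:
    """Call CNVs for one sample with the five-state HMM.

    Maximal constant-state non-diploid runs spanning >= ``min_probes`` probes
    become calls; confidence is the log-likelihood of the decoded path minus
    the all-diploid path over the run (emissions plus boundary transitions).
    """
    lrr_all = report.sample_lrr(sample)
    baf_all = report.sample_baf(sample)
    positions = report.probes["position"].to_numpy()
    calls = []
    for chrom in report.chromosomes():
        mask = report.chromosome_mask(chrom)
        pos = positions[mask]
        n = pos.size
        if n < params.min_probes:
            continue
        log_emit = hmm_log_emissions(lrr_all[mask], baf_all[mask], params)
        stay, off = hmm_transition_probs(np.diff(pos), params)
        log_stay, log_off = np.log(stay), np.log(off)
        path = viterbi_path(log_emit, log_stay, log_off)
        for lo, hi, state in _constant_runs(path):
            if state == 2 or hi - lo + 1 < params.min_probes:
                continue
            conf = float(np.sum(log_emit[lo : hi + 1, state] - log_emit[lo : hi + 1, 2]))
            if lo > 0:
                conf += float(log_off[lo - 1] - log_stay[lo - 1])
            if hi < n - 1:
                conf += float(log_off[hi] - log_stay[hi])
            calls.append(
                CnvCall(sample=sample, chromosome=chrom,
                        start=int(pos[lo]), end=int(pos[hi]), state=int(state),
                        n_probes=hi - lo + 1, confidence=conf, caller="hmm")
            )
    return calls


def _constant_runs(path):
    """Yield (first_index, last_index, value) for maximal constant runs."""
    n = len(path)
    lo = 0
    for i in range(1, n + 1):
        if i == n or path[i] != path[lo]:
            yield lo, i - 1, path[lo]
            lo = i


@njit(cache=False)
def _best_interior(x, min_probes, max_width):  # pragma: no cover - exercised via caller
    """Best interior window [i, j) vs. the rest by pooled two-sample |t|.

    Returns ``(i, j, |t|)`` maximized over windows with
    ``min_probes <= j - i <= max_width`` and at least ``min_probes``
    observations outside.  Windows touching a segment end reduce to a plain
    binary split.  Zero pooled variance with unequal means gives t = inf
    (a noiseless step is always accepted); equal means give t = 0.
    """
    n = x.size
    s = np.empty(n + 1)
    q = np.empty(n + 1)
    s[0] = 0.0
    q[0] = 0.0
    for k in range(n):
        s[k + 1] = s[k] + x[k]
        q[k + 1] = q[k] + x[k] * x[k]
    best_t = -1.0
    bi = 0
    bj = 0
    for i in range(0, n - min_probes + 1):
        j_hi = min(n, i + max_width)
        for j in range(i + min_probes, j_hi + 1):
            n_in = j - i
            n_out = n - n_in
            if n_out < min_probes:
                continue
            sum_in = s[j] - s[i]
            m_in = sum_in / n_in
            m_out = (s[n] - sum_in) / n_out
            ss_in = (q[j] - q[i]) - n_in * m_in * m_in
            ss_out = (q[n] - (q[j] - q[i])) - n_out * m_out * m_out
            pooled = (ss_in + ss_out) / (n - 2)
            diff = m_in - m_out
            if pooled <= 1e-300:
                t = np.inf if abs(diff) > 0 else 0.0
            else:
                t = abs(diff) / np.sqrt(pooled * (1.0 / n_in + 1.0 / n_out))
            if t > best_t:
                best_t = t
                bi = i
                bj = j
    return bi, bj, best_t


def best_interior_window(x, min_probes: int, max_width: int):
    """Python wrapper over the compiled interior-window scan (for tests too)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.size < 2 * min_probes:
        return 0, 0, -1.0
    i, j, t = _best_interior(x, min_probes, max_width)
    return int(i), int(j), float(t)


def _segment(x: np.ndarray, lo: int, hi: int, params: SegParams, edges: list) -> None:
    """Recursively collect changepoints (relative to x) inside [lo, hi)."""
    i, j, t = best_interior_window(x[lo:hi], params.min_probes, params.max_width_probes)
    if t <= params.t_threshold:
        return
    cuts = [lo + i, lo + j]
    pieces = sorted({lo, hi, *cuts})
    for c in cuts:
        if c not in (lo, hi):
            edges.append(c)
    for a, b in zip(pieces[:-1], pieces[1:]):
        if b - a < hi - lo:  # strictly smaller: guarantees termination
            _segment(x, a, b, params, edges)


def call_segmentation(report: IntensityReport, sample: str, params: SegParams) -> list:
    """Call CNVs by recursive binary segmentation of the LRR signal.

    Splits maximize the pooled two-sample t statistic and are accepted while
    |t| exceeds ``t_threshold`` with both sides >= ``min_probes``.  Final
    segments are classified by mean LRR (copy 1 below ``del_threshold``,
    copy 0 below ``hom_del_threshold``, copy 3 above ``dup_threshold``);
    diploid segments produce no call.  Masked (NaN) probes are skipped.
    """
    lrr_all = report.sample_lrr(sample)
    positions = report.probes["position"].to_numpy()
    calls = []
    for chrom in report.chromosomes():
        mask = report.chromosome_mask(chrom)
        lrr = lrr_all[mask]
        pos = positions[mask]
        usable = ~np.isnan(lrr)
        x = lrr[usable]
        p = pos[usable]
        if x.size < params.min_probes:
            continue
        edges = [0, x.size]
        _segment(x, 0, x.size, params, edges)
        edges = sorted(set(edges))
        for lo, hi in zip(edges[:-1], edges[1:]):
            mean = float(np.mean(x[lo:hi]))
            if mean < params.hom_del_threshold:
                state = 0
            elif mean < params.del_threshold:
                state = 1
            elif mean > params.dup_threshold:
                state = 3
            else:
                continue
            if hi - lo < params.min_probes:
                continue
            # confidence: separation of the segment mean from 0 in s.e. units
            sd = float(np.std(x[lo:hi], ddof=1)) if hi - lo > 1 else 0.0
            conf = abs(mean) * np.sqrt(hi - lo) / sd if sd > 0 else np.inf
            calls.append(
                CnvCall(sample=sample, chromosome=chrom,
                        start=int(p[lo]), end=int(p[hi - 1]), state=state,
                        n_probes=hi - lo, confidence=float(conf), caller="seg")
            )
    return calls


def merge_consensus(calls, params: PipelineConfig | None = None) -> list:
    """Merge per-caller calls into consensus calls.

    Per sample and direction (deletion: state < 2; duplication: state > 2),
    calls overlapping by >= 1 bp are grouped transitively; each group yields
    one consensus call with the union interval and the set of distinct
    supporting callers.
    """
    by_group = {}
    for c in calls:
        by_group.setdefault((c.sample, c.direction), []).append(c)
    out = []
    for (sample, direction), group in sorted(by_group.items()):
        group = sorted(group, key=lambda c: (c.chromosome, c.start, c.end))
        cur = [group[0]]
        cur_end = group[0].end
        cur_chrom = group[0].chromosome

        def flush(members, chrom, end):
            out.append(
                ConsensusCall(
                    sample=sample, chromosome=chrom,
                    start=min(m.start for m in members), end=end,
                    direction=direction,
                    support=frozenset(m.caller for m in members),
                    member_calls=tuple(members),
                )
            )

        for c in group[1:]:
            if c.chromosome == cur_chrom and c.start <= cur_end:
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                flush(cur, cur_chrom, cur_end)
                cur = [c]
                cur_end = c.end
                cur_chrom = c.chromosome
        flush(cur, cur_chrom, cur_end)
    return sorted(out, key=lambda c: (c.chromosome, c.start, c.end, c.sample, c.direction))


def apply_consensus_filters(calls, params: PipelineConfig):
    """Apply the consensus exclusion rules; returns (kept, removed).

    ``removed`` is a list of ``(call, reason)``.  Rules: union length
    >= ``max_length_bp``; support below ``min_support``; within the MHC
    region, a sample carrying both a supported deletion and a supported
    duplication has both removed.
    """
    cp = params.consensus
    kept, removed = [], []
    for c in calls:
        if c.length_bp >= cp.max_length_bp:
            removed.append((c, f"length_ge_{cp.max_length_bp}bp"))
        elif len(c.support) < cp.min_support:
            removed.append((c, f"support_lt_{cp.min_support}"))
        else:
            kept.append(c)

    def in_mhc(c):
        return (c.chromosome == cp.mhc_chromosome
                and max(c.start, cp.mhc_start) <= min(c.end, cp.mhc_end))

    mhc_by_sample = {}
    for c in kept:
        if in_mhc(c):
            mhc_by_sample.setdefault(c.sample, set()).add(c.direction)
    conflicted = {s for s, dirs in mhc_by_sample.items() if len(dirs) == 2}
    if conflicted:
        still = []
        for c in kept:
            if c.sample in conflicted and in_mhc(c):
                removed.append((c, "mhc_deletion_duplication_conflict"))
            else:
                still.append(c)
        kept = still
    return kept, removed
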