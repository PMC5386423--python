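import itertools

import numpy as np
import pytest

from cnvmod.calling import (
    CnvCall,
    ConsensusCall,
    apply_consensus_filters,
    best_interior_window,
    call_hmm,
    call_segmentation,
    hmm_log_emissions,
    hmm_transition_probs,
    merge_consensus,
    viterbi_path,
)
from cnvmod.config import PipelineConfig
from cnvmod.errors import ValidationError


def brute_force_viterbi(log_emit, log_stay, log_off):
    """Exhaustive argmax over all 5^n state paths (oracle)."""
    n, k = log_emit.shape
    paths = np.array(list(itertools.product(range(k), repeat=n)))
    scores = log_emit[np.arange(n)[None, :], paths].sum(axis=1)
    for t in range(n - 1):
        same = paths[:, t] == paths[:, t + 1]
        scores += np.where(same, log_stay[t], log_off[t])
    return paths[np.argmax(scores)], scores.max()


class TestHmm:
    @pytest.mark.parametrize("n,seed", [(2, 0), (3, 1), (4, 2), (5, 3), (6, 4), (8, 5)])
    def test_viterbi_matches_exhaustive_enumeration(self, n, seed, config):
        rng = np.random.default_rng(seed)
        lrr = rng.normal(-0.3, 0.6, n)
        baf = rng.random(n)
        gaps = rng.integers(1000, 200_000, n - 1)
        log_emit = hmm_log_emissions(lrr, baf, config.hmm)
        stay, off = hmm_transition_probs(gaps, config.hmm)
        path = viterbi_path(log_emit, np.log(stay), np.log(off))
        oracle_path, oracle_score = brute_force_viterbi(log_emit, np.log(stay), np.log(off))
        assert list(path) == list(oracle_path)

    def test_noiseless_diploid_no_calls(self, make_report, diploid_baf, config):
        n = 200
        rep = make_report(np.zeros(n), diploid_baf(n))
        assert call_hmm(rep, "S0", config.hmm) == []

    def test_noiseless_deletion_exact_boundaries(self, make_report, config):
        n = 200
        lrr = np.zeros(n)
        lrr[50:60] = config.hmm.lrr_means[1]
        baf = np.tile([0.0, 0.5, 1.0], n // 3 + 1)[:n]
        baf[50:60] = np.tile([0.0, 1.0], 5)  # hemizygous: no het cluster
        rep = make_report(lrr, baf)
        calls = call_hmm(rep, "S0", config.hmm)
        assert len(calls) == 1
        call = calls[0]
        pos = rep.probes["position"].to_numpy()
        assert (call.start, call.end) == (pos[50], pos[59])
        assert call.state == 1
        assert call.n_probes == 10
        assert call.confidence > 0

    def test_too_few_probes_yields_no_calls(self, make_report, config):
        rep = make_report(np.full(2, -0.66), np.array([0.0, 1.0]))
        assert call_hmm(rep, "S0", config.hmm) == []

    def test_call_boundaries_are_probe_positions(self, make_report, diploid_baf, config):
        rng = np.random.default_rng(9)
        n = 400
        lrr = rng.normal(0, 0.15, n)
        lrr[100:115] += config.hmm.lrr_means[1]
        rep = make_report(lrr, diploid_baf(n))
        pos = set(rep.probes["position"])
        for c in call_hmm(rep, "S0", config.hmm):
            assert c.start in pos and c.end in pos


class TestSegmentation:
    def test_constant_signal_no_calls(self, make_report, diploid_baf, config):
        n = 300
        rep = make_report(np.zeros(n), diploid_baf(n))
        assert call_segmentation(rep, "S0", config.seg) == []

    def test_noisy_step_recovered_within_one_probe(self, make_report, diploid_baf, config):
        rng = np.random.default_rng(4)
        n = 200
        lrr = rng.normal(0, 0.15, n)
        lrr[90:110] -= 0.66
        rep = make_report(lrr, diploid_baf(n))
        calls = call_segmentation(rep, "S0", config.seg)
        assert len(calls) == 1
        pos = rep.probes["position"].to_numpy()
        assert calls[0].state == 1
        assert abs(np.searchsorted(pos, calls[0].start) - 90) <= 1
        assert abs(np.searchsorted(pos, calls[0].end) - 109) <= 1

    def test_noiseless_boundaries_match_exhaustive_scan(self, config):
        # oracle: brute-force scan of every interior window
        x = np.zeros(120)
        x[40:55] = -0.66
        best = (-1.0, None)
        n = x.size
        for i in range(n):
            for j in range(i + config.seg.min_probes, n + 1):
                n_in, n_out = j - i, n - (j - i)
                if n_out < config.seg.min_probes:
                    continue
                m_in, m_out = x[i:j].mean(), np.concatenate([x[:i], x[j:]]).mean()
                ss = ((x[i:j] - m_in) ** 2).sum() + (
                    (np.concatenate([x[:i], x[j:]]) - m_out) ** 2
                ).sum()
                s2 = ss / (n - 2)
                t = np.inf if s2 == 0 and m_in != m_out else (
                    0.0 if s2 == 0 else abs(m_in - m_out) / np.sqrt(s2 * (1 / n_in + 1 / n_out))
                )
                if t > best[0]:
                    best = (t, (i, j))
        i, j, t = best_interior_window(x, config.seg.min_probes, config.seg.max_width_probes)
        assert (i, j) == best[1] == (40, 55)
        assert t == best[0] == np.inf

    def test_homozygous_deletion_classified_copy_zero(self, make_report, diploid_baf, config):
        n = 200
        lrr = np.zeros(n)
        lrr[80:95] = -3.5
        rep = make_report(lrr, diploid_baf(n))
        calls = call_segmentation(rep, "S0", config.seg)
        assert [c.state for c in calls] == [0]


def _call(sample="S1", chrom="chr1", start=100, end=200, state=1, caller="hmm"):
    return CnvCall(sample=sample, chromosome=chrom, start=start, end=end,
                   state=state, n_probes=5, confidence=10.0, caller=caller)


class TestConsensus:
    def test_overlapping_same_direction_merges_with_support_two(self, config):
        calls = [_call(caller="hmm"), _call(start=150, end=260, caller="seg")]
        merged = merge_consensus(calls, config)
        assert len(merged) == 1
        assert merged[0].support == {"hmm", "seg"}
        assert (merged[0].start, merged[0].end) == (100, 260)

    def test_deletion_and_duplication_stay_separate(self, config):
        calls = [_call(state=1), _call(state=3, caller="seg")]
        merged = merge_consensus(calls, config)
        assert len(merged) == 2
        assert {m.direction for m in merged} == {"deletion", "duplication"}

    @pytest.mark.parametrize("seed", range(5))
    def test_grouping_equals_connected_components_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        calls = []
        for k in range(40):
            start = int(rng.integers(1, 5000))
            calls.append(_call(
                sample=f"S{rng.integers(3)}", chrom=f"chr{rng.integers(2) + 1}",
                start=start, end=start + int(rng.integers(1, 800)),
                state=int(rng.choice([1, 3])), caller=str(rng.choice(["hmm", "seg"])),
            ))
        merged = merge_consensus(calls, config)
        # oracle: transitive closure of pairwise >=1 bp overlap per (sample, direction)
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(calls)))
        for i, a in enumerate(calls):
            for j, b in enumerate(calls[:i]):
                if (a.sample, a.direction, a.chromosome) == (b.sample, b.direction, b.chromosome) \
                        and max(a.start, b.start) <= min(a.end, b.end):
                    g.add_edge(i, j)
        components = {
            frozenset((calls[i].sample, calls[i].direction, calls[i].start, calls[i].end)
                      for i in comp)
            for comp in nx.connected_components(g)
        }
        merged_groups = {
            frozenset((m.sample, m.direction, c.start, c.end) for c in m.member_calls)
            for m in merged
        }
        assert merged_groups == components

    def test_consensus_calls_pairwise_nonoverlapping(self, config):
        rng = np.random.default_rng(12)
        calls = []
        for _ in range(60):
            start = int(rng.integers(1, 3000))
            calls.append(_call(sample="S1", start=start, end=start + int(rng.integers(1, 400))))
        merged = merge_consensus(calls, config)
        merged = sorted(merged, key=lambda m: m.start)
        for a, b in zip(merged[:-1], merged[1:]):
            assert a.end < b.start


def _consensus(sample="S1", chrom="chr1", start=1000, end=2000,
               direction="deletion", callers=("hmm", "seg")):
    return ConsensusCall(sample=sample, chromosome=chrom, start=start, end=end,
                         direction=direction, support=frozenset(callers))


class TestConsensusFilters:
    def test_exactly_1000kb_removed(self, config):
        call = _consensus(start=1, end=1_000_000)  # length exactly 1,000,000
        kept, removed = apply_consensus_filters([call], config)
        assert kept == []
        assert "length_ge" in removed[0][1]
        shorter = _consensus(start=2, end=1_000_000)
        kept, removed = apply_consensus_filters([shorter], config)
        assert kept == [shorter]

    def test_single_caller_support_removed(self, config):
        call = _consensus(callers=("hmm",))
        kept, removed = apply_consensus_filters([call], config)
        assert kept == []
        assert "support" in removed[0][1]

    def test_mhc_deletion_duplication_conflict_removes_both(self, config):
        cp = config.consensus
        mid = (cp.mhc_start + cp.mhc_end) // 2
        dele = _consensus(chrom=cp.mhc_chromosome, start=mid, end=mid + 5000)
        dup = _consensus(chrom=cp.mhc_chromosome, start=mid + 100, end=mid + 4000,
                         direction="duplication")
        other = _consensus(sample="S2", chrom=cp.mhc_chromosome, start=mid, end=mid + 5000)
        kept, removed = apply_consensus_filters([dele, dup, other], config)
        assert kept == [other]
        assert {r for _, r in removed} == {"mhc_deletion_duplication_conflict"}

    def test_non_mhc_conflict_untouched(self, config):
        dele = _consensus(chrom="chr2")
        dup = _consensus(chrom="chr2", direction="duplication")
        kept, removed = apply_consensus_filters([dele, dup], config)
        assert len(kept) == 2 and removed == []


def test_cnv_call_rejects_diploid_state():
    with pytest.raises(ValidationError):
        _call(state=2)


def test_noiseless_recovery_equals_truth_segments(config):
    """With zero noise, kept consensus calls = truth segments (>= min probes)."""
    from cnvmod.simulate import SignalModel, make_truth_set

    truth = make_truth_set(
        n_chromosomes=2, probes_per_chromosome=400, n_loci=3,
        n_target_per_stratum=10, pool_factor=150, seed=21,
        signal=SignalModel(lrr_sd=0.0, baf_sd=0.0, waviness_amplitude=0.0),
    )
    calls = []
    for s in truth.samples:
        calls.extend(call_hmm(truth.report, s, config.hmm))
        calls.extend(call_segmentation(truth.report, s, config.seg))
    kept, _ = apply_consensus_filters(merge_consensus(calls, config), config)
    called = {(c.sample, c.chromosome, c.start, c.end) for c in kept}
    expected = {
        (seg["sample"], seg["chromosome"], seg["start"], seg["end"])
        for _, seg in truth.segments.iterrows()
    }
    assert called == expected
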