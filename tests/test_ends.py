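"""TSS/TTS calling: counting, clustering, thresholds, and truth recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_call_tss, brute_call_tts, brute_clusters
from phagetx import (
    AlignedRead,
    EndCallingParams,
    call_tss,
    call_tts,
    collect_end_counts,
)
from phagetx.ends import _peak_clusters


def _read(i, strand, five, three, library="enriched"):
    return AlignedRead(f"r{i}", strand, five, three, library)


class TestCollectEndCounts:
    def test_counts_simple_pileup(self):
        reads = [_read(0, "+", 100, 500), _read(1, "+", 100, 600), _read(2, "+", 105, 700)]
        counts = collect_end_counts(reads, "five_prime")
        assert counts["+"] == {100: 2, 105: 1}
        assert counts["-"] == {}

    def test_empty_input(self):
        counts = collect_end_counts([], "three_prime")
        assert counts == {"+": {}, "-": {}}

    @given(
        st.lists(
            st.tuples(st.sampled_from("+-"), st.integers(0, 300)),
            min_size=0, max_size=60,
        )
    )
    def test_totals_conserved_per_strand(self, spec):
        reads = [
            _read(i, s, p, p + 10) if s == "+" else _read(i, s, p + 10, p)
            for i, (s, p) in enumerate(spec)
        ]
        counts = collect_end_counts(reads, "five_prime")
        total = sum(counts["+"].values()) + sum(counts["-"].values())
        assert total == len(reads)


class TestClustering:
    def test_nearby_peaks_group_to_the_larger(self):
        # two 5'-end peaks 3 nt apart, counts 10 and 7, window 5 -> one call
        reads = [_read(i, "+", 100, 500) for i in range(10)]
        reads += [_read(10 + i, "+", 103, 500) for i in range(7)]
        control = [_read(100, "+", 400, 500, "control")]
        calls = call_tss(
            collect_end_counts(reads, "five_prime"),
            collect_end_counts(control, "five_prime"),
            {"enriched": len(reads), "control": len(control)},
        )
        assert len(calls) == 1
        assert calls[0].position == 100
        assert calls[0].count_enriched == 17

    @settings(max_examples=200)
    @given(
        weights=st.dictionaries(
            st.integers(0, 120), st.integers(1, 20), min_size=1, max_size=30
        ),
        window=st.integers(1, 10),
        strand=st.sampled_from("+-"),
    )
    def test_matches_brute_force_grouping(self, weights, window, strand):
        from collections import Counter

        ours = _peak_clusters(Counter(weights), window, strand)
        assert ours == brute_clusters(weights, window, strand)


class TestCallTSS:
    def test_hand_computed_enrichment_ratio(self):
        # enriched CPM 50 vs control CPM 5 -> ratio 50.5/5.5 ~ 9.2 >= 3
        enriched = [_read(i, "+", 1000, 2000) for i in range(50)]
        control = [_read(i, "+", 1000, 2000, "control") for i in range(5)]
        calls = call_tss(
            collect_end_counts(enriched, "five_prime"),
            collect_end_counts(control, "five_prime"),
            {"enriched": 1_000_000, "control": 1_000_000},
        )
        assert len(calls) == 1
        assert calls[0].position == 1000
        assert calls[0].enrichment_ratio == pytest.approx(50.5 / 5.5)

    def test_no_enrichment_no_calls(self):
        reads_e = [_read(i, "+", 700, 900) for i in range(30)]
        reads_c = [_read(i, "+", 700, 900, "control") for i in range(30)]
        calls = call_tss(
            collect_end_counts(reads_e, "five_prime"),
            collect_end_counts(reads_c, "five_prime"),
            {"enriched": 30, "control": 30},
        )
        assert calls == []

    def test_zero_mapped_reads_is_an_error(self):
        with pytest.raises(ValueError, match="cannot normalize"):
            call_tss({"+": {}, "-": {}}, {"+": {}, "-": {}}, {"enriched": 0, "control": 5})

    def test_calls_satisfy_their_thresholds(self, pipeline_result):
        params = EndCallingParams()
        for c in pipeline_result.tss_calls:
            assert c.count_enriched >= params.min_count
            assert c.enrichment_ratio >= params.min_ratio
            assert c.cluster_span[0] <= c.position <= c.cluster_span[1]


class TestCallTTS:
    def test_all_reads_terminate(self):
        reads = [_read(i, "+", 1000, 2000) for i in range(50)]
        calls = call_tts(reads)
        assert len(calls) == 1
        assert calls[0].termination_efficiency == 1.0
        assert calls[0].position == 2000

    def test_partial_readthrough_efficiency(self):
        reads = [_read(i, "+", 1000, 2000) for i in range(10)]
        reads += [_read(10 + i, "+", 1000, 3000) for i in range(30)]
        calls = call_tts(reads)
        by_pos = {c.position: c for c in calls}
        assert by_pos[2000].termination_efficiency == pytest.approx(10 / 40)
        assert by_pos[2000].n_readthrough == 30

    def test_low_coverage_suppresses_calls(self):
        reads = [_read(i, "+", 1000, 2000) for i in range(10)]
        params = EndCallingParams(min_coverage=20)
        assert call_tts(reads, params) == []

    def test_empty_input(self):
        assert call_tts([]) == []


class TestOracleEquivalence:
    """Full-call agreement with exhaustive reimplementations (<= 500 reads)."""

    def _random_reads(self, seed, n=400):
        rng = np.random.default_rng(seed)
        reads = []
        for i in range(n):
            strand = "+" if rng.random() < 0.7 else "-"
            # ends concentrated on a few hotspots plus scatter
            five = int(rng.choice([100, 102, 500, 900]) + rng.integers(-2, 3))
            length = int(rng.integers(50, 400))
            library = "enriched" if rng.random() < 0.5 else "control"
            if strand == "+":
                reads.append(_read(i, "+", five, five + length, library))
            else:
                reads.append(_read(i, "-", five + length, five, library))
        return reads

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tss_calls_match_brute_force(self, seed):
        reads = self._random_reads(seed)
        enriched = [r for r in reads if r.library == "enriched"]
        control = [r for r in reads if r.library == "control"]
        params = EndCallingParams(min_count=3)
        ours = call_tss(
            collect_end_counts(enriched, "five_prime"),
            collect_end_counts(control, "five_prime"),
            {"enriched": len(enriched), "control": len(control)},
            params,
        )
        got = sorted((c.strand, c.position, c.count_enriched, c.count_control) for c in ours)
        assert got == brute_call_tss(enriched, control, params)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_tts_calls_match_brute_force(self, seed):
        reads = self._random_reads(seed)
        params = EndCallingParams(min_coverage=5, min_te=0.1)
        ours = call_tts(reads, params)
        got = sorted((c.strand, c.position, c.n_terminated, c.n_readthrough) for c in ours)
        assert got == brute_call_tts(reads, params)


class TestRecoveryOnDefaultData:
    def test_planted_boundaries_recovered(self, pipeline_result):
        assert pipeline_result.recovery["tss_f1"] >= 0.9
        assert pipeline_result.recovery["tts_f1"] >= 0.9

    def test_termination_efficiencies_recovered(self, pipeline_result):
        assert pipeline_result.recovery["te_max_abs_error"] <= 0.1
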