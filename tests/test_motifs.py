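"""Promoter windows, motif discovery, sigma70 scoring, classification, rescan."""

import inspect

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_pwm_scan, brute_sigma70
from phagetx import (
    Genome,
    PositionWeightMatrix,
    classify_promoter,
    discover_motif,
    extract_promoter_window,
    motif_significance,
    rescan_genome,
    score_sigma70,
)
from phagetx._seq import revcomp
from phagetx.motifs import SIGMA70_MAX_SCORE
from phagetx.synthetic import PHAGE_MOTIF


def _random_genome(seed, length=2000):
    rng = np.random.default_rng(seed)
    return Genome("toy", "".join(rng.choice(list("ACGT"), size=length)))


def _pwm_from(kmers):
    counts = np.zeros((len(kmers[0]), 4))
    for k in kmers:
        for j, b in enumerate(k):
            counts[j, "ACGT".index(b)] += 1
    return PositionWeightMatrix(counts)


class TestPromoterWindow:
    def test_forward_window_is_101_nt_ending_on_tss(self):
        g = _random_genome(0)
        w = extract_promoter_window(g, 500, "+")
        assert len(w) == 101
        assert w == g.seq[400:501]

    def test_clipped_at_genome_start(self):
        g = _random_genome(0)
        assert len(extract_promoter_window(g, 50, "+")) == 51

    def test_outside_genome_is_an_error(self):
        with pytest.raises(ValueError, match="outside genome"):
            extract_promoter_window(_random_genome(0), 5000, "+")

    @settings(max_examples=80)
    @given(pos=st.integers(0, 1999), strand=st.sampled_from("+-"))
    def test_strand_symmetry(self, pos, strand):
        g = _random_genome(1)
        mirror = Genome("rc", revcomp(g.seq))
        w = extract_promoter_window(g, pos, strand)
        w2 = extract_promoter_window(
            mirror, len(g.seq) - 1 - pos, "-" if strand == "+" else "+"
        )
        assert w == w2


class TestDiscoverMotif:
    def test_identical_planted_kmer_is_the_consensus(self):
        rng = np.random.default_rng(2)
        windows = []
        for _ in range(20):
            w = list(rng.choice(list("ACGT"), size=60))
            i = int(rng.integers(0, 60 - 17))
            w[i:i + 17] = list(PHAGE_MOTIF)
            windows.append("".join(w))
        res = discover_motif(windows, width=17, seed=0)
        assert res.pwm.consensus == PHAGE_MOTIF

    def test_default_width_is_17(self):
        sig = inspect.signature(discover_motif)
        assert sig.parameters["width"].default == 17

    def test_short_window_is_an_error(self):
        with pytest.raises(ValueError, match="shorter than motif width"):
            discover_motif(["ACGTACGT", "A" * 30], width=17)

    def test_random_windows_are_not_significant(self):
        rng = np.random.default_rng(3)
        windows = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(10)]
        _, significant = motif_significance(windows, width=17, n_shuffles=30, seed=0)
        assert not significant

    def test_planted_motif_is_significant(self):
        rng = np.random.default_rng(4)
        windows = []
        for _ in range(10):
            w = list(rng.choice(list("ACGT"), size=80))
            i = int(rng.integers(0, 80 - 17))
            w[i:i + 17] = list(PHAGE_MOTIF)
            windows.append("".join(w))
        _, significant = motif_significance(windows, width=17, n_shuffles=30, seed=0)
        assert significant

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        windows = ["".join(rng.choice(list("ACGT"), size=70)) for _ in range(8)]
        a = discover_motif(windows, seed=1)
        b = discover_motif(windows, seed=1)
        assert a.sites == b.sites
        assert np.array_equal(a.pwm.counts, b.pwm.counts)


class TestSigma70:
    def test_consensus_with_17_nt_spacer_attains_the_maximum(self):
        window = "C" * 30 + "TTGACA" + "G" * 17 + "TATAAT" + "C" * 20
        assert score_sigma70(window) == pytest.approx(SIGMA70_MAX_SCORE)

    def test_uninformative_window_scores_minimal_placement(self):
        window = "C" * 80
        # every placement scores 2 matches (the two C-free consensus columns
        # never match C), i.e. 12 mismatch terms
        assert score_sigma70(window) == pytest.approx(brute_sigma70(window))
        assert score_sigma70(window) < 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        window = "".join(rng.choice(list("ACGT"), size=101))
        assert score_sigma70(window) == pytest.approx(brute_sigma70(window))


@pytest.fixture(scope="module")
def phage_pwm():
    return _pwm_from([PHAGE_MOTIF] * 10)


class TestClassifyPromoter:
    def test_planted_motif_classifies_phage_specific(self, phage_pwm):
        rng = np.random.default_rng(6)
        w = list(rng.choice(list("ACGT"), size=101))
        w[40:57] = list(PHAGE_MOTIF)
        call = classify_promoter("".join(w), phage_pwm)
        assert call.promoter_class == "phage_specific"
        assert call.motif_location == (40, 57)

    def test_sigma70_boxes_classify_host(self, phage_pwm):
        window = "C" * 40 + "TTGACA" + "A" * 17 + "TATAAT" + "C" * 32
        call = classify_promoter(window, phage_pwm)
        assert call.promoter_class == "host_sigma70"

    def test_neither_motif_is_ambiguous(self, phage_pwm):
        call = classify_promoter("CA" * 50 + "C", phage_pwm)
        assert call.promoter_class == "ambiguous"
        assert call.sigma70_score is not None


class TestRescanGenome:
    def test_planted_instances_recovered_exactly(self):
        rng = np.random.default_rng(7)
        seq = list(rng.choice(list("ACGT"), size=5000))
        pwm = _pwm_from([PHAGE_MOTIF] * 10)
        planted = [200, 900, 1500, 2300, 3100, 3700, 4200, 4800]
        for i, p in enumerate(planted):
            inst = list(PHAGE_MOTIF)
            if i % 2:
                inst[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[inst[5]]
            seq[p:p + 17] = inst
        genome = Genome("toy", "".join(seq))
        scores = [pwm.best_site(genome.seq[p:p + 17])[1] for p in planted]
        hits = rescan_genome(genome, pwm, threshold=min(scores))
        assert [(h.position, h.strand) for h in hits] == [(p, "+") for p in planted]

    def test_threshold_above_maximum_yields_no_hits(self):
        genome = _random_genome(8)
        pwm = _pwm_from([PHAGE_MOTIF] * 4)
        assert rescan_genome(genome, pwm, threshold=pwm.max_score + 1) == []

    def test_reverse_strand_equals_scan_of_reverse_complement(self):
        genome = _random_genome(9, 800)
        pwm = _pwm_from(["ACGTACGTAC", "ACGTACGAAC", "TCGTACGTAC"])
        hits = rescan_genome(genome, pwm, threshold=2.0)
        flipped = rescan_genome(Genome("rc", revcomp(genome.seq)), pwm, threshold=2.0)
        L = len(genome.seq)
        want = sorted(
            (L - h.position - pwm.width, {"+": "-", "-": "+"}[h.strand], round(h.score, 6))
            for h in flipped
        )
        got = sorted((h.position, h.strand, round(h.score, 6)) for h in hits)
        assert got == want

    @pytest.mark.parametrize("seed", [10, 11])
    def test_matches_position_by_position_oracle(self, seed):
        genome = _random_genome(seed, 1500)
        pwm = _pwm_from([PHAGE_MOTIF[:10], PHAGE_MOTIF[1:11], PHAGE_MOTIF[2:12]])
        threshold = 0.5 * pwm.max_score
        hits = rescan_genome(genome, pwm, threshold)
        got = sorted((h.position, h.strand, round(h.score, 9)) for h in hits)
        assert got == brute_pwm_scan(genome.seq, pwm.probs.tolist(), threshold)

    def test_known_vs_candidate_labels(self, pipeline_result):
        res = pipeline_result
        hits = rescan_genome(
            res.genome, res.motif.pwm,
            threshold=0.8 * res.motif.pwm.max_score,
            known_tss=res.tss_calls,
        )
        assert hits, "planted motifs must be found on rescan"
        assert all(h.label == "known" for h in hits)


class TestPWMProperties:
    def test_probabilities_normalised(self):
        pwm = _pwm_from([PHAGE_MOTIF, PHAGE_MOTIF[::-1]])
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)

    def test_width_below_four_rejected(self):
        with pytest.raises(ValueError, match="width"):
            PositionWeightMatrix(np.ones((3, 4)))

    def test_meme_text_round_trip_probabilities(self):
        pwm = _pwm_from([PHAGE_MOTIF] * 3)
        text = pwm.to_meme_text()
        rows = [
            [float(x) for x in line.split()]
            for line in text.splitlines()
            if line and line[0].isdigit()
        ]
        assert np.allclose(np.array(rows), pwm.probs, atol=1e-6)
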