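"""Comparison of called boundaries and classifications against planted truth."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class RecoveryStats:
    n_truth: int
    n_called: int
    true_positives: int
    matches: list  # (truth, call) pairs

    @property
    def precision(self):
        return self.true_positives / self.n_called if self.n_called else 0.0

    @property
    def recall(self):
        return self.true_positives / self.n_truth if self.n_truth else 0.0

    @property
    def f1(self):
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def match_calls(truth, calls, tolerance: int = 5) -> RecoveryStats:
    """Greedy one-to-one strand-aware matching of calls to planted elements.

    Both inputs need ``position`` and ``strand`` attributes. Each truth entry
    is matched to the nearest unclaimed call within ``tolerance`` nt.
    """
    claimed = set()
    matches = []
    for t in sorted(truth, key=lambda e: (e.strand, e.position)):
        best = None
        for i, c in enumerate(calls):
            if i in claimed or c.strand != t.strand:
                continue
            d = abs(c.position - t.position)
            if d <= tolerance and (best is None or d < best[0]):
                best = (d, i)
        if best is not None:
            claimed.add(best[1])
            matches.append((t, calls[best[1]]))
    return RecoveryStats(len(list(truth)), len(list(calls)), len(matches), matches)


def termination_efficiency_errors(truth_tts, tts_calls, tolerance: int = 5):
    """Absolute TE error per matched terminator; unmatched truth is skipped."""
    stats = match_calls(truth_tts, tts_calls, tolerance)
    return [
        abs(call.termination_efficiency - t.termination_efficiency)
        for t, call in stats.matches
    ]


def expected_tu_pairs(truth, reads_per_tss: float, min_span_support: int = 3):
    """Oracle TU catalogue implied by the planted truth and sequencing depth.

    For every TSS, walks its same-strand downstream terminator chain and keeps
    each (TSS, TTS) pair whose expected number of spanning reads (depth times
    the product of upstream read-through probabilities times the termination
    efficiency) reaches ``min_span_support``. Mirrors sequential read-through.
    """
    sign = {"+": 1, "-": -1}
    pairs = []
    tss_list = [e for e in truth if e.kind in ("tss_host", "tss_phage")]
    tts_all = [e for e in truth if e.kind == "tts"]
    for tss in tss_list:
        s = tss.strand
        chain = sorted(
            (t for t in tts_all if t.strand == s
             and sign[s] * (t.position - tss.position) > 0),
            key=lambda t: sign[s] * t.position,
        )
        reach = reads_per_tss * tss.expression_weight
        for tts in chain:
            expected = reach * tts.termination_efficiency
            if expected >= min_span_support:
                pairs.append((tss, tts))
            reach *= 1.0 - tts.termination_efficiency
            if reach < 1e-9:
                break
    return pairs
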