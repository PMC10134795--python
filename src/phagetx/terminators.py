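"""Intrinsic (factor-independent) terminator detection.

An intrinsic bacterial terminator is an RNA hairpin immediately followed by a
U-rich tract. Here candidate hairpins are searched exhaustively in a window
around each called TTS (on the DNA template the U-tract reads as a T-tract).
Scoring uses simple integer base-pair weights rather than nearest-neighbour
free energies; the thresholds below define what counts as intrinsic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._seq import revcomp

# Watson-Crick plus GU wobble (DNA alphabet: U -> T)
_PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}

TERMINATOR_WINDOW_UP = 60    # nt upstream of the TTS
TERMINATOR_WINDOW_DOWN = 40  # nt downstream of the TTS


@dataclass(frozen=True)
class HairpinParams:
    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 10
    max_mismatch: int = 1          # internal mismatches tolerated in the stem
    mismatch_penalty: float = -2.0
    loop_penalty: float = 0.5      # per loop nt, subtracted from the stem score
    tail_len: int = 8              # nt inspected for the U(T)-tract
    stem_threshold: float = 12.0
    tail_threshold: int = 4


@dataclass(frozen=True)
class Hairpin:
    start: int        # stem 5' arm start, window coordinates
    stem_length: int
    loop_length: int
    stem_score: float
    u_tail_score: int

    @property
    def end(self) -> int:
        """One past the stem 3' arm (window coordinates)."""
        return self.start + 2 * self.stem_length + self.loop_length


@dataclass(frozen=True)
class TerminatorCall:
    """Classification of one TTS window."""

    window: str
    intrinsic: bool
    stem_length: int
    loop_length: int
    stem_score: float
    u_tail_score: int
    hairpin: Hairpin | None
    readthrough: float | None = None  # 1 - termination efficiency, if known


def extract_terminator_window(genome, position: int, strand: str) -> str:
    """Strand-oriented -60..+40 window (101 nt) around a TTS, clipped at ends."""
    seq = genome.seq
    if not 0 <= position < len(seq):
        raise ValueError(f"TTS position {position} outside genome of length {len(seq)}")
    if strand == "+":
        lo = max(0, position - TERMINATOR_WINDOW_UP)
        hi = min(len(seq), position + TERMINATOR_WINDOW_DOWN + 1)
        return seq[lo:hi]
    lo = max(0, position - TERMINATOR_WINDOW_DOWN)
    hi = min(len(seq), position + TERMINATOR_WINDOW_UP + 1)
    return revcomp(seq[lo:hi])


def _score_stem(window: str, i: int, stem: int, loop: int, params: HairpinParams):
    """Pair the 5' arm against the 3' arm; None if too many mismatches."""
    score = 0.0
    mismatches = 0
    for k in range(stem):
        a = window[i + k]
        b = window[i + stem + loop + (stem - 1 - k)]
        w = _PAIR_WEIGHT.get((a, b))
        if w is None:
            mismatches += 1
            if mismatches > params.max_mismatch:
                return None
            score += params.mismatch_penalty
        else:
            score += w
    return score - params.loop_penalty * loop


def detect_intrinsic_terminator(window: str, params: HairpinParams | None = None) -> TerminatorCall:
    """Exhaustive hairpin + U-tail search over one terminator window.

    The reported hairpin is the best-scoring one that meets both the stem and
    tail thresholds if any exists (ranked by stem_score + u_tail_score),
    otherwise the best hairpin by stem score alone; ``intrinsic`` is True
    exactly when the reported hairpin meets both thresholds.
    """
    params = params or HairpinParams()
    if len(window) < 20:
        raise ValueError("terminator window shorter than 20 nt")
    best = None            # best by stem_score
    best_qual = None       # best qualifying, by stem_score + u_tail_score
    n = len(window)
    for stem in range(params.stem_min, params.stem_max + 1):
        for loop in range(params.loop_min, params.loop_max + 1):
            total = 2 * stem + loop
            for i in range(0, n - total + 1):
                s = _score_stem(window, i, stem, loop, params)
                if s is None:
                    continue
                tail = window[i + total:i + total + params.tail_len]
                hp = Hairpin(i, stem, loop, s, tail.count("T"))
                if best is None or hp.stem_score > best.stem_score:
                    best = hp
                if (
                    hp.stem_score >= params.stem_threshold
                    and hp.u_tail_score >= params.tail_threshold
                ):
                    if best_qual is None or (
                        hp.stem_score + hp.u_tail_score
                        > best_qual.stem_score + best_qual.u_tail_score
                    ):
                        best_qual = hp
    reported = best_qual if best_qual is not None else best
    if reported is None:
        return TerminatorCall(window, False, 0, 0, 0.0, 0, None)
    return TerminatorCall(
        window=window,
        intrinsic=best_qual is not None,
        stem_length=reported.stem_length,
        loop_length=reported.loop_length,
        stem_score=reported.stem_score,
        u_tail_score=reported.u_tail_score,
        hairpin=reported,
    )


def with_readthrough(call: TerminatorCall, termination_efficiency: float) -> TerminatorCall:
    return replace(call, readthrough=1.0 - termination_efficiency)
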