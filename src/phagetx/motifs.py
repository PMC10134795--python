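"""Promoter motif modelling: PWM discovery, sigma70 scoring, classification.

Two promoter classes are modelled:

* host sigma70 promoters, scored with a consensus-derived log-odds model of
  the -35 (TTGACA) and -10 (TATAAT) boxes with a 15-19 nt spacer;
* phage RNAP promoters, which share one conserved motif (17 bp by default)
  discovered de novo from the promoter windows with a seeded, multi-restart
  one-occurrence-per-sequence (OOPS) site sampler.

Scores are log-odds in nats against a uniform 0.25 background; they are not
comparable to MEME/MAST E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._seq import revcomp

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}

PROMOTER_WINDOW_UP = 100  # -100..+1 relative to the TSS (window length 101)

SIGMA35_CONSENSUS = "TTGACA"
SIGMA10_CONSENSUS = "TATAAT"
SIGMA_SPACER_RANGE = (15, 19)
_SIGMA_MATCH_P = 0.85  # probability mass on the consensus base per position


def _encode(seq: str) -> np.ndarray:
    return np.array([_INDEX.get(b, 0) for b in seq], dtype=np.int64)


class PositionWeightMatrix:
    """Nucleotide count matrix with pseudocount-normalised probabilities."""

    def __init__(self, counts: np.ndarray, pseudocount: float = 0.5):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (width, 4)")
        if counts.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        self.counts = counts
        self.pseudocount = pseudocount
        with np.errstate(divide="ignore"):
            probs = (counts + pseudocount) / (counts + pseudocount).sum(
                axis=1, keepdims=True
            )
        self.probs = probs
        self.log_odds = np.log(probs / 0.25)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def information_content(self) -> float:
        """Total IC in bits: sum over columns of 2 + sum_b p log2 p."""
        p = self.probs
        return float(np.sum(2.0 + np.sum(p * np.log2(p), axis=1)))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def score_positions(self, seq: str) -> np.ndarray:
        """Log-odds score of every placement of the motif along ``seq``."""
        enc = _encode(seq)
        n = len(enc) - self.width + 1
        if n <= 0:
            return np.empty(0)
        scores = np.zeros(n)
        for j in range(self.width):
            scores += self.log_odds[j, enc[j:j + n]]
        return scores

    def best_site(self, seq: str) -> tuple[int, float]:
        """(position, score) of the best placement; ties to the leftmost."""
        scores = self.score_positions(seq)
        if scores.size == 0:
            raise ValueError("sequence shorter than motif width")
        i = int(scores.argmax())
        return i, float(scores[i])

    def to_meme_text(self, name: str = "MOTIF_1") -> str:
        """Serialise in MEME minimal format."""
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25",
            "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width}",
        ]
        for row in self.probs:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class MotifResult:
    pwm: PositionWeightMatrix
    sites: list  # per-window best site start positions
    significant: bool | None = None
    ic_threshold: float | None = None


def _pwm_from_sites(encoded, sites, width, skip=None) -> np.ndarray:
    counts = np.zeros((width, 4))
    for i, (enc, s) in enumerate(zip(encoded, sites)):
        if i == skip:
            continue
        for j in range(width):
            counts[j, enc[s + j]] += 1
    return counts


def discover_motif(
    windows,
    width: int = 17,
    n_restarts: int = 5,
    seed: int = 0,
    max_iter: int = 100,
    pseudocount: float = 0.5,
) -> MotifResult:
    """One-occurrence-per-sequence motif discovery by seed-and-refine EM.

    Every window contributes exactly one site. Every k-mer occurring in any
    window is evaluated as a candidate seed (under a single-site PWM the
    log-odds objective reduces to Hamming matches against the seed, so this
    enumeration is exact and cheap); the ``n_restarts`` best seeds are each
    refined by iteratively reassigning every window's site to its best
    placement under the PWM built from the other windows' sites, to a fixed
    point. The refinement with the highest final information content wins.
    The procedure is deterministic; ``seed`` is accepted for API uniformity
    with the stochastic significance test.
    """
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("motif discovery needs at least 2 windows")
    for w in windows:
        if len(w) < width:
            raise ValueError(f"window of length {len(w)} shorter than motif width {width}")
    encoded = [_encode(w) for w in windows]
    slices = [
        np.lib.stride_tricks.sliding_window_view(enc, width) for enc in encoded
    ]

    # Rank all candidate seed k-mers by the sum over windows of the best
    # Hamming match count. Ties resolve to the earliest (window, position).
    seeds = np.concatenate(slices, axis=0)
    totals = np.zeros(len(seeds), dtype=np.int64)
    for sl in slices:
        matches = (seeds[:, None, :] == sl[None, :, :]).sum(axis=2)
        totals += matches.max(axis=1)
    order = np.argsort(-totals, kind="stable")[: max(1, n_restarts)]

    best = None  # (ic, sites, counts)
    for idx in order:
        kmer = seeds[idx]
        # initial assignment: best Hamming match to the seed k-mer
        sites = [int((sl == kmer).sum(axis=1).argmax()) for sl in slices]
        for _ in range(max_iter):
            changed = False
            for i, sl in enumerate(slices):
                counts = _pwm_from_sites(encoded, sites, width, skip=i)
                lo = PositionWeightMatrix(counts, pseudocount).log_odds
                scores = lo[np.arange(width)[None, :], sl].sum(axis=1)
                s = int(scores.argmax())
                if s != sites[i]:
                    sites[i] = s
                    changed = True
            if not changed:
                break
        counts = _pwm_from_sites(encoded, sites, width)
        ic = PositionWeightMatrix(counts, pseudocount).information_content
        if best is None or ic > best[0]:
            best = (ic, list(sites), counts)

    return MotifResult(
        pwm=PositionWeightMatrix(best[2], pseudocount), sites=best[1]
    )


def motif_significance(
    windows,
    width: int = 17,
    n_shuffles: int = 100,
    seed: int = 0,
    n_restarts: int = 2,
    quantile: float = 0.95,
) -> tuple[float, bool]:
    """Compare discovered IC against a null of within-window shuffled inputs.

    Returns ``(ic_threshold, significant)`` where the threshold is the given
    quantile of information contents from ``n_shuffles`` re-discoveries on
    letter-shuffled windows.
    """
    rng = np.random.default_rng(seed)
    observed = discover_motif(windows, width, n_restarts=max(n_restarts, 2), seed=seed)
    null = []
    for k in range(n_shuffles):
        shuffled = [
            "".join(rng.permutation(list(w))) for w in windows
        ]
        res = discover_motif(
            shuffled, width, n_restarts=n_restarts, seed=int(rng.integers(2**31))
        )
        null.append(res.pwm.information_content)
    threshold = float(np.quantile(null, quantile))
    return threshold, observed.pwm.information_content > threshold


def extract_promoter_window(genome, position: int, strand: str) -> str:
    """Strand-oriented -100..+1 window (101 nt incl. the TSS base), clipped."""
    seq = genome.seq
    if not 0 <= position < len(seq):
        raise ValueError(f"TSS position {position} outside genome of length {len(seq)}")
    if strand == "+":
        lo = max(0, position - PROMOTER_WINDOW_UP)
        return seq[lo:position + 1]
    hi = min(len(seq), position + PROMOTER_WINDOW_UP + 1)
    return revcomp(seq[position:hi])


def _box_log_odds(consensus: str) -> np.ndarray:
    off = (1.0 - _SIGMA_MATCH_P) / 3.0
    lo = np.full((len(consensus), 4), math.log(off / 0.25))
    for j, b in enumerate(consensus):
        lo[j, _INDEX[b]] = math.log(_SIGMA_MATCH_P / 0.25)
    return lo


_BOX35 = _box_log_odds(SIGMA35_CONSENSUS)
_BOX10 = _box_log_odds(SIGMA10_CONSENSUS)

SIGMA70_MAX_SCORE = float(_BOX35.max(axis=1).sum() + _BOX10.max(axis=1).sum())


def score_sigma70(window: str, detail: bool = False):
    """Best sigma70 promoter score over all -35/spacer/-10 placements.

    Scans every placement of the -35 hexamer, spacer length 15-19 nt, and -10
    hexamer within the window; log-odds against a uniform background.
    """
    if len(window) < 35:
        raise ValueError("sigma70 scoring needs a window of >= 35 nt")
    enc = _encode(window)
    n = len(enc)
    s35 = np.zeros(n - 6 + 1)
    s10 = np.zeros(n - 6 + 1)
    for j in range(6):
        s35 += _BOX35[j, enc[j:j + n - 5]]
        s10 += _BOX10[j, enc[j:j + n - 5]]
    best = -math.inf
    best_place = None
    lo_sp, hi_sp = SIGMA_SPACER_RANGE
    for i in range(len(s35)):
        for spacer in range(lo_sp, hi_sp + 1):
            k = i + 6 + spacer
            if k >= len(s10):
                break
            score = s35[i] + s10[k]
            if score > best:
                best = score
                best_place = (i, spacer, k)
    if detail:
        return best, best_place
    return best


@dataclass(frozen=True)
class PromoterThresholds:
    """Class-decision thresholds as fractions of each model's maximum score."""

    phage_fraction: float = 0.7
    sigma70_fraction: float = 0.7


@dataclass(frozen=True)
class PromoterCall:
    window: str
    promoter_class: str  # host_sigma70 | phage_specific | ambiguous
    sigma70_score: float
    phage_motif_score: float
    motif_location: tuple[int, int] | None  # window coords, half-open
    tss = None


def classify_promoter(
    window: str,
    phage_pwm: PositionWeightMatrix,
    thresholds: PromoterThresholds | None = None,
) -> PromoterCall:
    """Phage-specific beats host sigma70 beats ambiguous.

    A window is phage_specific when its best phage-motif placement reaches the
    phage threshold; otherwise host_sigma70 when the sigma70 model reaches its
    threshold; otherwise ambiguous. Both scores are always reported.
    """
    thresholds = thresholds or PromoterThresholds()
    pos, phage_score = phage_pwm.best_site(window)
    sigma_score = score_sigma70(window)
    if phage_score >= thresholds.phage_fraction * phage_pwm.max_score:
        klass = "phage_specific"
        loc = (pos, pos + phage_pwm.width)
    elif sigma_score >= thresholds.sigma70_fraction * SIGMA70_MAX_SCORE:
        klass, loc = "host_sigma70", None
    else:
        klass, loc = "ambiguous", None
    return PromoterCall(
        window=window,
        promoter_class=klass,
        sigma70_score=float(sigma_score),
        phage_motif_score=float(phage_score),
        motif_location=loc,
    )


@dataclass(frozen=True)
class MotifHit:
    position: int  # forward-strand start of the motif occurrence
    strand: str
    score: float
    label: str  # "known" (overlaps a called TSS) or "candidate"


def rescan_genome(
    genome,
    pwm: PositionWeightMatrix,
    threshold: float,
    known_tss=None,
    tolerance: int = 5,
) -> list[MotifHit]:
    """Exhaustive both-strand PWM scan; hits are positions scoring >= threshold.

    A hit is labelled ``known`` when a previously called same-strand TSS lies
    within ``tolerance`` nt of the motif occurrence interval, else
    ``candidate`` — candidates mirror promoters recoverable only by motif
    rescanning.
    """
    if pwm.width > len(genome.seq):
        raise ValueError("PWM wider than genome")
    known = [(t.position, t.strand) for t in (known_tss or [])]

    def _label(start: int, strand: str) -> str:
        lo, hi = start - tolerance, start + pwm.width + tolerance
        for pos, s in known:
            if s == strand and lo <= pos < hi:
                return "known"
        return "candidate"

    hits = []
    fwd = pwm.score_positions(genome.seq)
    for i in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(int(i), "+", float(fwd[i]), _label(int(i), "+")))
    rev = pwm.score_positions(revcomp(genome.seq))
    L = len(genome.seq)
    for j in np.flatnonzero(rev >= threshold):
        start = L - int(j) - pwm.width
        hits.append(MotifHit(start, "-", float(rev[j]), _label(start, "-")))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits
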