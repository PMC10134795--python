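"""Transcript boundary calling from strand-aware long-read alignments.

Transcription start sites (TSS) are called by comparing 5'-end pileups between
a 5'-enriched library (which retains triphosphorylated primary 5' ends) and a
non-enriched control library. Positions are clustered, normalised to counts per
million mapped reads (CPM), and a site is called when it has both sufficient
raw support in the enriched library and a sufficient enriched/control CPM
ratio.

Transcription termination sites (TTS) are called from pooled 3'-end pileups
(5'-cap enrichment does not bias 3' ends). Each candidate cluster receives a
termination efficiency: the fraction of covering transcripts that actually end
there rather than reading through.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

STRANDS = ("+", "-")


@dataclass(frozen=True)
class AlignedRead:
    """One mapped long read.

    ``five_prime`` and ``three_prime`` are 0-based genome coordinates of the
    biological transcript ends (both inclusive, i.e. covered bases). On the
    forward strand the 5' end is the smaller coordinate; on the reverse strand
    it is the larger one.
    """

    read_id: str
    strand: str
    five_prime: int
    three_prime: int
    library: str  # "enriched" or "control"

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.strand == "+" and not self.five_prime < self.three_prime:
            raise ValueError(
                f"read {self.read_id}: + strand requires five_prime < three_prime"
            )
        if self.strand == "-" and not self.five_prime > self.three_prime:
            raise ValueError(
                f"read {self.read_id}: - strand requires five_prime > three_prime"
            )

    @property
    def interval(self) -> tuple[int, int]:
        """Covered interval on forward coordinates, 0-based half-open."""
        lo = min(self.five_prime, self.three_prime)
        hi = max(self.five_prime, self.three_prime)
        return lo, hi + 1


@dataclass(frozen=True)
class TSSCall:
    position: int
    strand: str
    count_enriched: int
    count_control: int
    enrichment_ratio: float
    cluster_span: tuple[int, int]  # inclusive position range of the cluster


@dataclass(frozen=True)
class TTSCall:
    position: int
    strand: str
    n_terminated: int
    n_readthrough: int
    termination_efficiency: float
    cluster_span: tuple[int, int]


@dataclass(frozen=True)
class EndCallingParams:
    """Thresholds for boundary calling (all exposed in the pipeline config)."""

    cluster_window: int = 5      # nt; max width of an end cluster
    min_count: int = 5           # reads; min enriched support for a TSS
    min_ratio: float = 3.0       # min (CPM_enriched+pc)/(CPM_control+pc)
    pseudocount: float = 0.5     # CPM pseudocount
    min_coverage: int = 20       # reads; min terminated+readthrough for a TTS
    min_te: float = 0.25         # min termination efficiency
    flank: int = 10              # nt a read must extend past a cluster to count
                                 # as read-through


def collect_end_counts(reads, end: str = "five_prime", library: str | None = None):
    """Per-strand position -> count maps for one read end.

    ``end`` is ``"five_prime"`` or ``"three_prime"``; ``library`` optionally
    restricts to one library tag.
    """
    if end not in ("five_prime", "three_prime"):
        raise ValueError(f"unknown end {end!r}")
    counts = {s: Counter() for s in STRANDS}
    for r in reads:
        if library is not None and r.library != library:
            continue
        counts[r.strand][getattr(r, end)] += 1
    return counts


def _peak_clusters(weights: Counter, window: int, strand: str) -> list[list[int]]:
    """Peak-seeded clustering of end positions.

    Repeatedly seed a cluster at the unclaimed position with the highest
    count (ties to the most-upstream position on the strand) and absorb all
    unclaimed positions within ``window`` nt of that peak. Deterministic, and
    robust to a jittered pileup straddling a fixed grid.
    """
    unclaimed = set(weights)
    clusters = []
    upstream = (lambda p: -p) if strand == "+" else (lambda p: p)
    while unclaimed:
        peak = max(unclaimed, key=lambda p: (weights[p], upstream(p)))
        members = [p for p in unclaimed if abs(p - peak) <= window]
        unclaimed -= set(members)
        clusters.append(sorted(members))
    clusters.sort(key=lambda c: c[0])
    return clusters


def _mode_position(cluster: list[int], weights: Counter, strand: str) -> int:
    """Highest-count position; ties break to the most-upstream on the strand."""
    best = None
    for p in sorted(cluster, reverse=(strand == "-")):
        if best is None or weights[p] > weights[best]:
            best = p
    return best


def call_tss(enriched, control, total_mapped: dict, params: EndCallingParams | None = None):
    """Call TSSs from per-strand 5'-end count maps of the two libraries.

    ``total_mapped`` maps library name -> total mapped reads, used for CPM
    normalisation. Returns TSSCall objects sorted by (strand, position).
    """
    params = params or EndCallingParams()
    for lib in ("enriched", "control"):
        if total_mapped.get(lib, 0) <= 0:
            raise ValueError(f"zero mapped reads in {lib} library: cannot normalize")
    scale = {lib: 1e6 / total_mapped[lib] for lib in ("enriched", "control")}
    calls = []
    for strand in STRANDS:
        e, c = enriched[strand], control[strand]
        weights = Counter({p: e[p] for p in set(e) | set(c)})
        for cluster in _peak_clusters(weights, params.cluster_window, strand):
            count_e = sum(e[p] for p in cluster)
            count_c = sum(c[p] for p in cluster)
            cpm_e = count_e * scale["enriched"]
            cpm_c = count_c * scale["control"]
            ratio = (cpm_e + params.pseudocount) / (cpm_c + params.pseudocount)
            if count_e >= params.min_count and ratio >= params.min_ratio:
                calls.append(
                    TSSCall(
                        position=_mode_position(cluster, e, strand),
                        strand=strand,
                        count_enriched=count_e,
                        count_control=count_c,
                        enrichment_ratio=ratio,
                        cluster_span=(min(cluster), max(cluster)),
                    )
                )
    calls.sort(key=lambda c: (c.strand, c.position))
    return calls


def call_tts(reads, params: EndCallingParams | None = None, tss_positions=None):
    """Call TTSs with termination efficiencies from pooled 3'-end pileups.

    For each cluster of 3' ends, ``n_terminated`` counts reads ending inside
    the cluster and ``n_readthrough`` counts same-strand reads that cover the
    cluster and extend at least ``flank`` nt beyond it (strand-aware).

    When ``tss_positions`` is given (objects with ``position``/``strand``,
    e.g. TSS calls), the efficiency counts are restricted to 5'-anchored
    reads — reads starting within ``cluster_window`` of a same-strand TSS.
    Anchored reads are full-length primary transcripts, which removes the
    length bias that partially degraded reads introduce (a fragment of a
    read-through transcript can span a terminator, but a fragment of a
    terminated transcript carries no evidence). A cluster falls back to the
    all-read counts when fewer than ``min_coverage`` anchored reads cover it.
    """
    params = params or EndCallingParams()
    counts = collect_end_counts(reads, end="three_prime")
    by_strand = {s: [r for r in reads if r.strand == s] for s in STRANDS}
    anchors = None
    if tss_positions is not None:
        anchors = {s: [t.position for t in tss_positions if t.strand == s] for s in STRANDS}

    def tally(candidates, strand, members, lo, hi):
        n_term = 0
        n_rt = 0
        for r in candidates:
            if r.three_prime in members:
                n_term += 1
            elif strand == "+":
                if r.five_prime < lo and r.three_prime >= hi + params.flank:
                    n_rt += 1
            else:
                if r.five_prime > hi and r.three_prime <= lo - params.flank:
                    n_rt += 1
        return n_term, n_rt

    calls = []
    for strand in STRANDS:
        weights = counts[strand]
        pool = by_strand[strand]
        anchored_pool = None
        if anchors is not None:
            anchored_pool = [
                r for r in pool
                if any(abs(r.five_prime - p) <= params.cluster_window for p in anchors[strand])
            ]
        for cluster in _peak_clusters(weights, params.cluster_window, strand):
            lo, hi = min(cluster), max(cluster)
            members = set(cluster)
            n_term, n_rt = tally(pool, strand, members, lo, hi)
            if anchored_pool is not None:
                n_term_a, n_rt_a = tally(anchored_pool, strand, members, lo, hi)
                if n_term_a + n_rt_a >= params.min_coverage:
                    n_term, n_rt = n_term_a, n_rt_a
            coverage = n_term + n_rt
            if coverage < params.min_coverage:
                continue
            te = n_term / coverage
            if te < params.min_te:
                continue
            calls.append(
                TTSCall(
                    position=_mode_position(cluster, weights, strand),
                    strand=strand,
                    n_terminated=n_term,
                    n_readthrough=n_rt,
                    termination_efficiency=te,
                    cluster_span=(lo, hi),
                )
            )
    calls.sort(key=lambda c: (c.strand, c.position))
    return calls
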