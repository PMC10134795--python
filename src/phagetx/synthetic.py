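"""Synthetic phage transcriptome generator with planted ground truth.

Emulates a small linear dsDNA phage genome in the T7 style: direct terminal
repeats (DTRs) at both ends, ~61% GC, densely packed single-strand genes laid
out in early/middle/late temporal modules. Regulatory truth is planted into
the sequence:

* host-type TSSs receive a sigma70-like promoter (-35 TTGACA-like box,
  15-19 nt spacer, -10 TATAAT-like box written into the DNA);
* phage-type TSSs receive instances of one shared 17-bp motif, optionally
  with a bounded number of mismatches (the phage RNAP promoter);
* intrinsic TTSs receive a written GC-rich hairpin followed by a T-tract
  (the U-tract on the transcript); non-intrinsic TTSs are positions only, and
  their surroundings are scrubbed of chance hairpins so the truth table is
  consistent with the intrinsic-terminator definition.

Read simulation then emits strand-aware alignment records for a 5'-enriched
and a control library, with Gaussian end jitter, stochastic termination and
read-through at each TTS, 5'-degraded (processed) ends, background reads, and
per-read 5' truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import revcomp
from .ends import AlignedRead
from .motifs import SIGMA10_CONSENSUS, SIGMA35_CONSENSUS
from .terminators import detect_intrinsic_terminator

# The planted phage RNAP promoter motif (17 bp); chosen once for this
# generator, loosely echoing single-subunit RNAP promoter architecture.
PHAGE_MOTIF = "TAGTACGACTCCTATAG"

TRUNCATION_GEOM_P = 0.01  # geometric parameter for 5' truncation length (mean 100 nt)


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    genome_length: int = 37343
    dtr_length: int = 244
    gc_content: float = 0.61
    n_genes: int = 56
    module_layout: tuple = (("early", 1.0), ("middle", 1.1), ("late", 1.2))
    rng_seed: int = 7

    def validate(self):
        if self.genome_length <= 2 * self.dtr_length:
            raise ValueError("genome_length must exceed 2*dtr_length")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must lie strictly between 0 and 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dtr_length < 0:
            raise ValueError("dtr_length must be >= 0")


@dataclass(frozen=True)
class GeneFeature:
    gene_id: str
    start: int  # 0-based half-open, forward coordinates
    end: int
    strand: str
    module: str


@dataclass(frozen=True)
class Genome:
    name: str
    seq: str

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class PlantedElement:
    """One row of the ground-truth table."""

    kind: str  # tss_host | tss_phage | tts
    position: int
    strand: str
    expression_weight: float = 1.0
    promoter_sequence: str | None = None
    termination_efficiency: float | None = None
    intrinsic: bool | None = None

    def __post_init__(self):
        if self.kind not in ("tss_host", "tss_phage", "tts"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if (self.termination_efficiency is not None) != (self.kind == "tts"):
            raise ValueError("termination_efficiency present iff kind == 'tts'")


@dataclass(frozen=True)
class ElementRequest:
    """Where and what to plant; positions must be intergenic."""

    kind: str
    position: int
    strand: str = "+"
    expression_weight: float = 1.0
    termination_efficiency: float | None = None
    intrinsic: bool = False
    mismatches: int = 0       # promoter mismatches vs the consensus/motif
    spacer: int = 17          # sigma70 spacer length (15-19)
    stem_length: int = 8      # intrinsic hairpin geometry
    loop_length: int = 4
    tail_length: int = 8


@dataclass(frozen=True)
class ReadSimParams:
    depth_primary: int = 200
    capture_efficiency_enriched: float = 0.9
    capture_efficiency_control: float = 0.2
    end_jitter_sd: float = 1.0
    truncation_probability: float = 0.02
    background_read_rate: float = 0.05
    rng_seed: int = 7

    def validate(self):
        for name in (
            "capture_efficiency_enriched",
            "capture_efficiency_control",
            "truncation_probability",
            "background_read_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if self.depth_primary < 0:
            raise ValueError("depth_primary must be >= 0")
        if self.end_jitter_sd < 0:
            raise ValueError("end_jitter_sd must be >= 0")


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[Genome, list[GeneFeature]]:
    """Random genome of exact length with DTRs and modular gene layout.

    Genes are non-overlapping, forward-strand, sorted by start, and separated
    by intergenic gaps wide enough to host planted regulatory elements.
    Deterministic for a fixed ``rng_seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    gc = spec.gc_content
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(list("ACGT"), size=spec.genome_length, p=p)
    if spec.dtr_length:
        seq[-spec.dtr_length:] = seq[:spec.dtr_length]

    lead = spec.dtr_length + min(400, max(60, spec.genome_length // 20))
    tail = spec.dtr_length + 200
    budget = (spec.genome_length - lead - tail) / spec.n_genes
    if budget < 60:
        raise ValueError("n_genes too large for genome_length")

    labels = [m for m, _ in spec.module_layout]
    per = spec.n_genes // len(labels)
    module_of = []
    for i, lab in enumerate(labels):
        count = per if i < len(labels) - 1 else spec.n_genes - per * (len(labels) - 1)
        module_of += [lab] * count

    features = []
    cursor = lead
    for i in range(spec.n_genes):
        gap = int(rng.uniform(0.22, 0.38) * budget)
        glen = int(rng.uniform(0.55, 0.75) * budget)
        start = cursor + gap
        end = start + glen
        if end > spec.genome_length - tail:
            raise ValueError("gene layout overflows genome; reduce n_genes")
        features.append(GeneFeature(f"g{i:03d}", start, end, "+", module_of[i]))
        cursor = end
    return Genome("synthetic_phage", "".join(seq)), features


def _mutate(seq: str, n: int, rng) -> str:
    """Introduce n deterministic substitutions spread along ``seq``."""
    s = list(seq)
    for k in range(n):
        i = (3 + 5 * k) % len(s)
        choices = [b for b in "ACGT" if b != s[i]]
        s[i] = choices[int(rng.integers(0, 3))]
    return "".join(s)


def _place(seq: list, strand: str, tss: int, d: int, fragment: str):
    """Write ``fragment`` (transcript orientation) ending ``d`` nt upstream of
    the 5' position ``tss`` (d=0 places the last base on the TSS itself).
    Returns the forward-coordinate half-open interval written."""
    L = len(fragment)
    if strand == "+":
        lo = tss - d - L + 1
        seq[lo:lo + L] = list(fragment)
        return lo, lo + L
    lo = tss + d
    seq[lo:lo + L] = list(revcomp(fragment))
    return lo, lo + L


def _overlaps_gene(lo, hi, features):
    return [f for f in features if lo < f.end and f.start < hi]


def plant_regulatory_elements(
    genome: Genome,
    features: list,
    requests: list,
    rng_seed: int = 0,
    motif: str = PHAGE_MOTIF,
) -> tuple[Genome, list[PlantedElement]]:
    """Write requested regulatory elements into the sequence; return the truth.

    Raises if a written element would collide with an annotated gene. The
    windows of non-intrinsic TTSs are resampled until free of chance hairpins
    that would qualify as intrinsic, so the truth table is self-consistent.
    """
    rng = np.random.default_rng(rng_seed)
    seq = list(genome.seq)
    written: list[tuple[int, int]] = []
    truth: list[PlantedElement] = []

    def check(lo, hi, what):
        bad = _overlaps_gene(lo, hi, features)
        if bad:
            ids = ", ".join(f.gene_id for f in bad)
            raise ValueError(f"{what} placement [{lo},{hi}) collides with gene(s) {ids}")

    for req in requests:
        if not 0 <= req.position < len(seq):
            raise ValueError(f"element position {req.position} outside genome")
        if req.kind == "tss_host":
            if not 15 <= req.spacer <= 19:
                raise ValueError("sigma70 spacer must be 15-19 nt")
            box35 = _mutate(SIGMA35_CONSENSUS, req.mismatches, rng)
            lo10, hi10 = _place(seq, req.strand, req.position, 7, SIGMA10_CONSENSUS)
            lo35, hi35 = _place(seq, req.strand, req.position, 13 + req.spacer, box35)
            lo, hi = min(lo10, lo35), max(hi10, hi35)
            check(lo, hi, "sigma70 promoter")
            written.append((lo, hi))
            if req.strand == "+":
                prom = "".join(seq[lo:req.position + 1])
            else:
                prom = revcomp("".join(seq[req.position:hi]))
            truth.append(
                PlantedElement("tss_host", req.position, req.strand,
                               req.expression_weight, promoter_sequence=prom)
            )
        elif req.kind == "tss_phage":
            inst = _mutate(motif, req.mismatches, rng)
            lo, hi = _place(seq, req.strand, req.position, 0, inst)
            check(lo, hi, "phage promoter")
            written.append((lo, hi))
            truth.append(
                PlantedElement("tss_phage", req.position, req.strand,
                               req.expression_weight, promoter_sequence=inst)
            )
        elif req.kind == "tts":
            if req.termination_efficiency is None:
                raise ValueError("tts request needs a termination_efficiency")
            if req.intrinsic:
                stem_pool = list("GC")
                stem = "".join(
                    stem_pool[int(rng.integers(0, 2))] for _ in range(req.stem_length)
                )
                loop = "".join("ACTG"[int(rng.integers(0, 4))] for _ in range(req.loop_length))
                construct = stem + loop + revcomp(stem) + "T" * req.tail_length
                lo, hi = _place(seq, req.strand, req.position, 0, construct)
                check(lo, hi, "intrinsic terminator")
                written.append((lo, hi))
            truth.append(
                PlantedElement("tts", req.position, req.strand,
                               req.expression_weight,
                               termination_efficiency=req.termination_efficiency,
                               intrinsic=req.intrinsic)
            )
        else:
            raise ValueError(f"unknown request kind {req.kind!r}")

    _scrub_nonintrinsic_windows(seq, features, written, requests, rng)
    return Genome(genome.name, "".join(seq)), truth


def _scrub_nonintrinsic_windows(seq, features, written, requests, rng, pad=10, max_tries=40):
    """Resample intergenic, non-element bases around non-intrinsic TTSs until
    no hairpin in the (padded) window qualifies as intrinsic."""
    protected = sorted(written)

    def editable(i):
        if _overlaps_gene(i, i + 1, features):
            return False
        return not any(lo <= i < hi for lo, hi in protected)

    for req in requests:
        if req.kind != "tts" or req.intrinsic:
            continue
        if req.strand == "+":
            lo = max(0, req.position - 60 - pad)
            hi = min(len(seq), req.position + 41 + pad)
        else:
            lo = max(0, req.position - 40 - pad)
            hi = min(len(seq), req.position + 61 + pad)
        for attempt in range(max_tries):
            window = "".join(seq[lo:hi])
            if req.strand == "-":
                window = revcomp(window)
            if not detect_intrinsic_terminator(window).intrinsic:
                break
            for i in range(lo, hi):
                if editable(i):
                    seq[i] = "ACGT"[int(rng.integers(0, 4))]
        else:
            raise RuntimeError(
                f"could not scrub chance hairpins around non-intrinsic TTS at {req.position}"
            )


def default_element_requests(features: list, module_weights=None) -> list[ElementRequest]:
    """The default study layout: 3 host + 8 phage TSSs, 6 TTSs (3 intrinsic).

    Elements are anchored to intergenic gaps of the generated gene layout.
    One phage TSS/TTS pair is planted antisense to a late gene, emulating a
    noncoding antisense transcript. Termination efficiencies are chosen so
    that every downstream chain ends in a fully efficient terminator.
    """
    if module_weights is None:
        module_weights = {"early": 1.0, "middle": 1.1, "late": 1.2}
    n = len(features)
    if n < 56:
        raise ValueError("default layout expects the default 56-gene genome")

    def w(idx):
        return module_weights[features[idx].module]

    def tss_before(idx, kind, mm=0, weight=None):
        return ElementRequest(
            kind, features[idx].start - 25, "+",
            expression_weight=weight if weight is not None else w(idx),
            mismatches=mm,
        )

    def tts_after(idx, te, intrinsic):
        return ElementRequest(
            "tts", features[idx].end + 60, "+",
            termination_efficiency=te, intrinsic=intrinsic,
        )

    anti_gene = features[47]
    return [
        # early: host sigma70 promoters; P3 deviates by one -35 mismatch
        tss_before(0, "tss_host"),
        tss_before(1, "tss_host"),
        tss_before(2, "tss_host", mm=1, weight=0.8),
        tts_after(5, 0.8, True),
        tss_before(6, "tss_phage"),
        tts_after(11, 1.0, False),
        # middle
        tss_before(18, "tss_phage", mm=1),
        tss_before(20, "tss_phage"),
        tts_after(28, 0.9, True),
        tss_before(29, "tss_phage", mm=1),
        tss_before(33, "tss_phage"),
        tts_after(36, 1.0, False),
        # late
        tss_before(37, "tss_phage", mm=1),
        tss_before(42, "tss_phage"),
        tts_after(55, 1.0, True),
        # antisense pair over a late gene (noncoding transcript)
        ElementRequest("tss_phage", anti_gene.end + 30, "-", expression_weight=0.8),
        ElementRequest("tts", anti_gene.start - 70, "-",
                       termination_efficiency=1.0, intrinsic=False),
    ]


def default_dataset(seed: int = 7, sim_params: ReadSimParams | None = None):
    """Generate the full default fixture: genome, genes, truth, both libraries."""
    spec = SyntheticGenomeSpec(rng_seed=seed)
    genome, features = generate_genome(spec)
    genome, truth = plant_regulatory_elements(
        genome, features, default_element_requests(features), rng_seed=seed
    )
    params = sim_params or ReadSimParams(rng_seed=seed)
    enriched, control = simulate_reads(genome, truth, params)
    return genome, features, truth, enriched, control


def _downstream_tts(truth, strand):
    tts = [e for e in truth if e.kind == "tts" and e.strand == strand]
    return sorted(tts, key=lambda e: e.position, reverse=(strand == "-"))


def simulate_reads(
    genome: Genome, truth: list, params: ReadSimParams
) -> tuple[list, list]:
    """Simulate enriched and control libraries from the planted truth.

    Each primary transcript starts at a TSS (Gaussian end jitter) and walks
    downstream, terminating at each TTS with its planted efficiency, else
    reading through; transcripts passing every terminator drop off at a
    uniform position before the strand end. Library-specific 5'-capture keeps
    the primary 5' end with the library's capture efficiency; non-captured
    reads get a processed (degraded) 5' end uniform within the transcript.
    Background reads are drawn uniformly within active transcription units.
    Per-read 5' truncation removes a geometric amount of sequence.
    """
    params.validate()
    tss_list = [e for e in truth if e.kind in ("tss_host", "tss_phage")]
    if not tss_list:
        raise ValueError("no transcription sources")
    rng = np.random.default_rng(params.rng_seed)
    L = len(genome.seq)
    sign = {"+": 1, "-": -1}

    def jitter():
        if params.end_jitter_sd == 0:
            return 0
        return int(round(rng.normal(0.0, params.end_jitter_sd)))

    def clamp(pos):
        return min(max(pos, 0), L - 1)

    def terminate(five, strand):
        """Walk downstream of ``five``; return the 3'-end coordinate."""
        last = five
        for tts in _downstream_tts(truth, strand):
            if sign[strand] * (tts.position - five) <= 0:
                continue
            if rng.random() < tts.termination_efficiency:
                return clamp(tts.position + jitter())
            last = tts.position
        # drop-off: uniform between the last passed point and the strand end
        lo = last + sign[strand] * 50
        end = L - 1 if strand == "+" else 0
        if sign[strand] * (end - lo) <= 0:
            return end
        return int(rng.integers(min(lo, end), max(lo, end) + 1))

    def span_end(tss):
        """Furthest plausible reach of transcripts from this TSS."""
        chain = _downstream_tts(truth, tss.strand)
        for t in reversed(chain):
            if sign[tss.strand] * (t.position - tss.position) > 0:
                return t.position
        return L - 1 if tss.strand == "+" else 0

    libraries = {
        "enriched": params.capture_efficiency_enriched,
        "control": params.capture_efficiency_control,
    }
    out = {"enriched": [], "control": []}
    counter = 0
    for library, capture in libraries.items():
        for tss in tss_list:
            n = int(round(params.depth_primary * tss.expression_weight))
            strand = tss.strand
            for _ in range(n):
                five = clamp(tss.position + jitter())
                three = terminate(five, strand)
                if rng.random() >= capture:
                    # degradation product: both ends internal, drawn as order
                    # statistics of two uniforms over the transcript so that
                    # fragment ends do not pile up at either primary end
                    if abs(three - five) > 2:
                        lo, hi = sorted((five, three))
                        x = int(rng.integers(lo + 1, hi))
                        y = int(rng.integers(lo + 1, hi))
                        if x == y:
                            y = x + 1 if x < hi - 1 else x - 1
                        a, b = min(x, y), max(x, y)
                        five, three = (a, b) if strand == "+" else (b, a)
                if rng.random() < params.truncation_probability:
                    cut = int(rng.geometric(TRUNCATION_GEOM_P))
                    five = five + sign[strand] * cut
                if sign[strand] * (three - five) < 1:
                    five = three - sign[strand]
                counter += 1
                out[library].append(
                    AlignedRead(f"r{counter:06d}", strand, clamp(five), three, library)
                )
            # background (degradation) reads within the active TU
            n_bg = int(round(params.background_read_rate * n))
            s_end = span_end(tss)
            lo, hi = sorted((tss.position, s_end))
            for _ in range(n_bg):
                if hi - lo < 10:
                    break
                five = int(rng.integers(lo, hi))
                three = terminate(five, strand)
                if sign[strand] * (three - five) < 1:
                    continue
                counter += 1
                out[library].append(
                    AlignedRead(f"r{counter:06d}", strand, five, three, library)
                )
    return out["enriched"], out["control"]
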