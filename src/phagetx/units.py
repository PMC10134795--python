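"""Transcription unit (TU) delineation and operon construction.

A TU is a TSS-to-TTS span supported by long reads that cover the candidate
unit end to end. A TSS paired with several downstream TTSs (sequential
read-through) yields several nested TUs. A TSS with no supported terminator
pairing falls back to the longest observed transcript. Genes are assigned to
a TU when at least 90% of the gene body lies inside the span on the same
strand; operons are connected components of same-strand TUs sharing at least
one gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .ends import TSSCall, TTSCall


@dataclass(frozen=True)
class UnitParams:
    min_span_support: int = 3  # reads that must span a candidate (TSS,TTS) pair
    tol: int = 5               # nt tolerance matching read ends to calls


@dataclass
class TranscriptionUnit:
    tu_id: str
    strand: str
    start_tss: TSSCall
    end_tts: TTSCall | None
    span: tuple[int, int]  # forward coordinates, 0-based half-open
    supporting_reads: int
    genes: list = field(default_factory=list)
    noncoding_flag: bool = False

    @property
    def gene_ids(self):
        return [g.gene_id for g in self.genes]


@dataclass
class Operon:
    operon_id: str
    strand: str
    tus: list
    gene_union: set


def _span(strand, tss_pos, end_pos):
    if strand == "+":
        return (tss_pos, end_pos + 1)
    return (end_pos, tss_pos + 1)


def pair_boundaries(tss_calls, tts_calls, reads, params: UnitParams | None = None):
    """Enumerate supported (TSS, TTS) pairs into TUs, with longest-transcript
    fallback for TSSs lacking any supported terminator pairing."""
    params = params or UnitParams()
    sign = {"+": 1, "-": -1}
    tus = []
    for tss in sorted(tss_calls, key=lambda t: (t.strand, t.position)):
        s = tss.strand
        candidates = [
            r for r in reads
            if r.strand == s and abs(r.five_prime - tss.position) <= params.tol
        ]
        paired = False
        for tts in sorted(tts_calls, key=lambda t: sign[s] * t.position):
            if tts.strand != s:
                continue
            if sign[s] * (tts.position - tss.position) <= 0:
                continue
            support = sum(
                1 for r in candidates
                if abs(r.three_prime - tts.position) <= params.tol
            )
            if support >= params.min_span_support:
                paired = True
                tus.append(
                    TranscriptionUnit(
                        tu_id="",
                        strand=s,
                        start_tss=tss,
                        end_tts=tts,
                        span=_span(s, tss.position, tts.position),
                        supporting_reads=support,
                    )
                )
        if not paired and candidates:
            # longest transcript delineates the TU
            end = max(sign[s] * r.three_prime for r in candidates) * sign[s]
            tus.append(
                TranscriptionUnit(
                    tu_id="",
                    strand=s,
                    start_tss=tss,
                    end_tts=None,
                    span=_span(s, tss.position, end),
                    supporting_reads=len(candidates),
                )
            )
    # deduplicate identical (TSS position, end) pairs, summing support
    seen = {}
    for tu in tus:
        key = (tu.strand, tu.start_tss.position, tu.span)
        if key in seen:
            seen[key].supporting_reads += tu.supporting_reads
        else:
            seen[key] = tu
    tus = list(seen.values())
    tus.sort(key=lambda t: (t.span[0], t.span[1], t.strand))
    for i, tu in enumerate(tus, 1):
        tu.tu_id = f"TU{i:03d}"
    return tus


def assign_genes(tu: TranscriptionUnit, features, min_coverage: float = 0.90):
    """Assign genes covered >= ``min_coverage`` by the TU span, same strand."""
    lo, hi = tu.span
    assigned = []
    for g in features:
        if g.end <= g.start:
            raise ValueError(f"gene {g.gene_id} has non-positive length")
        if g.strand != tu.strand:
            continue
        overlap = max(0, min(hi, g.end) - max(lo, g.start))
        if overlap / (g.end - g.start) >= min_coverage:
            assigned.append(g)
    tu.genes = sorted(assigned, key=lambda g: g.start)
    tu.noncoding_flag = not tu.genes
    return tu


def build_operons(tus):
    """Connected components of same-strand TUs sharing >= 1 gene.

    Noncoding TUs form singleton operons; every TU lands in exactly one
    operon.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(tus)))
    for i in range(len(tus)):
        for j in range(i + 1, len(tus)):
            a, b = tus[i], tus[j]
            if a.strand != b.strand:
                continue
            if set(a.gene_ids) & set(b.gene_ids):
                graph.add_edge(i, j)
    operons = []
    for comp in nx.connected_components(graph):
        members = sorted((tus[i] for i in comp), key=lambda t: t.span)
        union = set()
        for tu in members:
            union |= set(tu.gene_ids)
        operons.append(Operon("", members[0].strand, members, union))
    operons.sort(key=lambda o: (o.tus[0].span, o.strand))
    for i, op in enumerate(operons, 1):
        op.operon_id = f"OP{i:03d}"
    return operons


def summarize_architecture(tus, operons) -> dict:
    """Headline TU/operon statistics (mean genes per TU to one decimal)."""
    n = len(tus)
    mean_genes = round(sum(len(t.genes) for t in tus) / n, 1) if n else 0.0
    return {
        "n_tus": n,
        "mean_genes_per_tu": mean_genes,
        "n_operons": len(operons),
        "n_noncoding": sum(1 for t in tus if t.noncoding_flag),
    }
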