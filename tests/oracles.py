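"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's data paths (no shared clustering,
no numpy vectorisation) so that agreement is evidence, not tautology.
"""

import math


def brute_clusters(weights: dict, window: int, strand: str):
    """Peak-seeded clustering, re-derived naively from its definition."""
    remaining = dict(weights)
    clusters = []
    while remaining:
        peak = None
        for p, c in remaining.items():
            if peak is None:
                peak = p
                continue
            better = c > remaining[peak]
            tie = c == remaining[peak]
            upstream = p < peak if strand == "+" else p > peak
            if better or (tie and upstream):
                peak = p
        members = sorted(p for p in remaining if abs(p - peak) <= window)
        for p in members:
            del remaining[p]
        clusters.append(members)
    return sorted(clusters, key=lambda c: c[0])


def brute_call_tss(enriched_reads, control_reads, params):
    """Exhaustive TSS calling over raw reads."""
    calls = []
    total_e = len(enriched_reads)
    total_c = len(control_reads)
    for strand in ("+", "-"):
        e = {}
        c = {}
        for r in enriched_reads:
            if r.strand == strand:
                e[r.five_prime] = e.get(r.five_prime, 0) + 1
        for r in control_reads:
            if r.strand == strand:
                c[r.five_prime] = c.get(r.five_prime, 0) + 1
        weights = {p: e.get(p, 0) for p in set(e) | set(c)}
        for cluster in brute_clusters(weights, params.cluster_window, strand):
            count_e = sum(e.get(p, 0) for p in cluster)
            count_c = sum(c.get(p, 0) for p in cluster)
            ratio = (count_e / total_e * 1e6 + params.pseudocount) / (
                count_c / total_c * 1e6 + params.pseudocount
            )
            if count_e >= params.min_count and ratio >= params.min_ratio:
                mode = None
                for p in cluster:
                    if (
                        mode is None
                        or e.get(p, 0) > e.get(mode, 0)
                        or (
                            e.get(p, 0) == e.get(mode, 0)
                            and (p < mode if strand == "+" else p > mode)
                        )
                    ):
                        mode = p
                calls.append((strand, mode, count_e, count_c))
    return sorted(calls)


def brute_call_tts(reads, params):
    calls = []
    for strand in ("+", "-"):
        ends = {}
        for r in reads:
            if r.strand == strand:
                ends[r.three_prime] = ends.get(r.three_prime, 0) + 1
        for cluster in brute_clusters(ends, params.cluster_window, strand):
            lo, hi = min(cluster), max(cluster)
            n_term = sum(ends[p] for p in cluster)
            n_rt = 0
            for r in reads:
                if r.strand != strand:
                    continue
                if strand == "+" and r.five_prime < lo and r.three_prime >= hi + params.flank:
                    n_rt += 1
                if strand == "-" and r.five_prime > hi and r.three_prime <= lo - params.flank:
                    n_rt += 1
            if n_term + n_rt < params.min_coverage:
                continue
            te = n_term / (n_term + n_rt)
            if te < params.min_te:
                continue
            mode = None
            for p in cluster:
                if (
                    mode is None
                    or ends[p] > ends[mode]
                    or (ends[p] == ends[mode] and (p < mode if strand == "+" else p > mode))
                ):
                    mode = p
            calls.append((strand, mode, n_term, n_rt))
    return sorted(calls)


def brute_gene_assignment(span, strand, genes, min_coverage=0.90):
    """Per-base overlap counter for the >=90% coverage rule."""
    lo, hi = span
    covered = set(range(lo, hi))
    assigned = []
    for g in genes:
        if g.strand != strand:
            continue
        inside = sum(1 for b in range(g.start, g.end) if b in covered)
        if inside / (g.end - g.start) >= min_coverage:
            assigned.append(g.gene_id)
    return sorted(assigned)


def brute_operon_partition(tu_genes, tu_strands):
    """Transitive closure by repeated merging of same-strand gene-sharing TUs."""
    groups = [
        {"members": {i}, "genes": set(tu_genes[i]), "strand": tu_strands[i]}
        for i in range(len(tu_genes))
    ]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if (
                    groups[a]["strand"] == groups[b]["strand"]
                    and groups[a]["genes"] & groups[b]["genes"]
                ):
                    groups[a]["members"] |= groups[b]["members"]
                    groups[a]["genes"] |= groups[b]["genes"]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return sorted(frozenset(g["members"]) for g in groups)


_MATCH = math.log(0.85 / 0.25)
_MISS = math.log(0.05 / 0.25)


def brute_sigma70(window):
    """Enumerate every -35/spacer/-10 placement with explicit arithmetic."""

    def box_score(seq, consensus):
        return sum(_MATCH if a == b else _MISS for a, b in zip(seq, consensus))

    best = None
    for i in range(len(window) - 6 + 1):
        for spacer in range(15, 20):
            j = i + 6 + spacer
            if j + 6 > len(window):
                continue
            s = box_score(window[i:i + 6], "TTGACA") + box_score(
                window[j:j + 6], "TATAAT"
            )
            if best is None or s > best:
                best = s
    return best


def brute_pwm_scan(seq, probs, threshold):
    """Position-by-position PWM scan of both strands with plain loops."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    width = len(probs)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    rc = "".join(comp[b] for b in reversed(seq))
    for strand, s in (("+", seq), ("-", rc)):
        for i in range(len(s) - width + 1):
            score = 0.0
            for j in range(width):
                score += math.log(probs[j][idx[s[i + j]]] / 0.25)
            if score >= threshold:
                pos = i if strand == "+" else len(seq) - i - width
                hits.append((pos, strand, round(score, 9)))
    return sorted(hits)
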