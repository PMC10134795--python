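#!/usr/bin/env python
"""Classify promoters (host sigma70 vs phage motif) and terminators.

Discovers the shared phage-promoter motif de novo from the -100..+1 windows
of all called TSSs (one-occurrence-per-sequence EM with a shuffled-input
significance test), scores each window against the sigma70 -35/-10 model and
the discovered PWM, rescans the genome for further motif occurrences, and
searches each TTS -60..+40 window for an intrinsic hairpin + U-tail.

Reads results/synthetic/ + results/boundaries/, writes results/regulatory/.
"""

import argparse
from pathlib import Path

import pandas as pd

from phagetx import (
    classify_promoter,
    discover_motif,
    extract_promoter_window,
    extract_terminator_window,
    formats,
    motif_significance,
    rescan_genome,
)
from phagetx.terminators import detect_intrinsic_terminator


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--boundaries", type=Path, default=Path("results/boundaries"))
    parser.add_argument("--outdir", type=Path, default=Path("results/regulatory"))
    parser.add_argument("--shuffles", type=int, default=50)
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = formats.read_genome_fasta(args.indir / "genome.fasta")
    tss = formats.read_tss_table(args.boundaries / "tss.tsv")
    tts = formats.read_tts_table(args.boundaries / "tts.tsv")

    windows = [extract_promoter_window(genome, c.position, c.strand) for c in tss]
    motif = discover_motif(windows, width=17)
    threshold, significant = motif_significance(
        windows, width=17, n_shuffles=args.shuffles, seed=0
    )
    print(
        f"discovered 17-bp motif {motif.pwm.consensus} "
        f"(IC {motif.pwm.information_content:.1f} bits vs null 95th pct "
        f"{threshold:.1f}; {'significant' if significant else 'not significant'})"
    )

    rows = []
    for c, w in zip(tss, windows):
        p = classify_promoter(w, motif.pwm)
        rows.append(
            {"position": c.position, "strand": c.strand, "class": p.promoter_class,
             "sigma70_score": round(p.sigma70_score, 3),
             "phage_motif_score": round(p.phage_motif_score, 3)}
        )
    df = pd.DataFrame(rows)
    df.to_csv(args.outdir / "promoters.tsv", sep="\t", index=False)
    (args.outdir / "motif.meme.txt").write_text(motif.pwm.to_meme_text("phage_promoter"))
    print(df["class"].value_counts().to_string())

    hits = rescan_genome(
        genome, motif.pwm, 0.8 * motif.pwm.max_score, known_tss=tss
    )
    pd.DataFrame(
        [{"position": h.position, "strand": h.strand,
          "score": round(h.score, 3), "label": h.label} for h in hits]
    ).to_csv(args.outdir / "motif_rescan.tsv", sep="\t", index=False)
    n_new = sum(1 for h in hits if h.label == "candidate")
    print(f"genome rescan: {len(hits)} motif hits, {n_new} beyond the called TSSs")

    trows = []
    for c in tts:
        w = extract_terminator_window(genome, c.position, c.strand)
        t = detect_intrinsic_terminator(w)
        trows.append(
            {"position": c.position, "strand": c.strand, "intrinsic": t.intrinsic,
             "stem_length": t.stem_length, "loop_length": t.loop_length,
             "stem_score": t.stem_score, "u_tail_score": t.u_tail_score,
             "termination_efficiency": round(c.termination_efficiency, 3)}
        )
    tdf = pd.DataFrame(trows)
    tdf.to_csv(args.outdir / "terminators.tsv", sep="\t", index=False)
    print(f"{int(tdf['intrinsic'].sum())}/{len(tdf)} terminators are intrinsic "
          "(hairpin + U-tail)")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
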