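#!/usr/bin/env python
"""Delineate transcription units and operons from the called boundaries.

A TU is a (TSS, TTS) pair supported by >= 3 reads spanning it end to end
(within 5 nt); a TSS without a supported terminator keeps its longest
transcript. Genes covered >= 90% on the same strand are assigned; operons are
connected components of same-strand TUs sharing at least one gene.

Reads results/synthetic/ + results/boundaries/, writes results/architecture/.
"""

import argparse
from pathlib import Path

from phagetx import assign_genes, build_operons, formats, pair_boundaries, summarize_architecture


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--boundaries", type=Path, default=Path("results/boundaries"))
    parser.add_argument("--outdir", type=Path, default=Path("results/architecture"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    reads = formats.read_alignments(args.indir / "alignments.bed")
    features = formats.read_genes_gff3(args.indir / "genes.gff3")
    genome = formats.read_genome_fasta(args.indir / "genome.fasta")
    tss = formats.read_tss_table(args.boundaries / "tss.tsv")
    tts = formats.read_tts_table(args.boundaries / "tts.tsv")

    tus = pair_boundaries(tss, tts, reads)
    for tu in tus:
        assign_genes(tu, features)
    operons = build_operons(tus)

    formats.write_tu_table(tus, args.outdir / "tus.tsv")
    formats.write_operon_table(operons, args.outdir / "operons.tsv")
    formats.write_architecture_gff3(
        args.outdir / "architecture.gff3", genome, tss, tts, tus, operons
    )
    summary = summarize_architecture(tus, operons)
    formats.write_json(summary, args.outdir / "summary.json")

    print(
        f"{summary['n_tus']} transcription units covering on average "
        f"{summary['mean_genes_per_tu']} genes"
    )
    print(
        f"{summary['n_operons']} operons; {summary['n_noncoding']} noncoding TU(s) "
        "(antisense transcript)"
    )
    nested = sum(
        1 for a in tus for b in tus
        if a is not b and a.strand == b.strand
        and a.span[0] == b.span[0] and a.span[1] < b.span[1]
    )
    print(f"{nested} TU pair(s) share a TSS with different terminators (read-through)")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
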