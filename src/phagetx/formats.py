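"""Readers and writers for the standard formats used by the pipeline.

Coordinate conventions: all in-memory intervals are 0-based half-open on
forward genome coordinates. BED output is 0-based half-open; GFF3 output is
1-based inclusive (GFF start == BED start + 1). For alignments, the library
tag (enriched/control) travels in the BED score column, or in the read-group
tag of SAM records.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ends import AlignedRead, TSSCall, TTSCall
from .synthetic import GeneFeature, Genome, PlantedElement

LIBRARIES = ("enriched", "control")


# ---------------------------------------------------------------- genome I/O

def write_genome_fasta(genome: Genome, path):
    record = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_genome_fasta(path) -> Genome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return Genome(record.id, str(record.seq).upper())


def write_genes_gff3(features, genome: Genome, path):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome.seq)}\n")
        for g in features:
            fh.write(
                "\t".join(
                    [
                        genome.name, "phagetx", "gene",
                        str(g.start + 1), str(g.end), ".", g.strand, ".",
                        f"ID={g.gene_id};module={g.module}",
                    ]
                )
                + "\n"
            )


def read_genes_gff3(path):
    features = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            features.append(
                GeneFeature(
                    attrs.get("ID", "?"), int(cols[3]) - 1, int(cols[4]),
                    cols[6], attrs.get("module", "unknown"),
                )
            )
    return features


# ------------------------------------------------------------ alignment I/O

def write_alignments_bed(reads, path, chrom: str):
    """BED6 with the library tag in the score column."""
    with open(path, "w") as fh:
        for r in reads:
            lo, hi = r.interval
            fh.write(f"{chrom}\t{lo}\t{hi}\t{r.read_id}\t{r.library}\t{r.strand}\n")


def _read_from_interval(read_id, lo, hi, strand, library):
    # BED half-open [lo, hi): the last covered base is hi-1
    if strand == "+":
        return AlignedRead(read_id, "+", lo, hi - 1, library)
    return AlignedRead(read_id, "-", hi - 1, lo, library)


def read_alignments_bed(path):
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 record needs 6 columns")
            try:
                lo, hi = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = cols[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            library = cols[4]
            if library not in LIBRARIES:
                raise ValueError(f"{path}:{lineno}: unknown library tag {library!r}")
            reads.append(_read_from_interval(cols[3], lo, hi, strand, library))
    return reads


def write_alignments_sam(reads, path, chrom: str, genome_length: int):
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": chrom, "LN": genome_length}],
        "RG": [{"ID": lib} for lib in LIBRARIES],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in reads:
            lo, hi = r.interval
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = r.read_id
            seg.flag = 16 if r.strand == "-" else 0
            seg.reference_id = 0
            seg.reference_start = lo
            seg.mapping_quality = 60
            seg.cigartuples = [(0, hi - lo)]
            seg.set_tag("RG", r.library)
            fh.write(seg)


def read_alignments_sam(path):
    reads = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            library = seg.get_tag("RG") if seg.has_tag("RG") else None
            if library not in LIBRARIES:
                raise ValueError(
                    f"read {seg.query_name}: missing/unknown read-group library tag"
                )
            strand = "-" if seg.is_reverse else "+"
            reads.append(
                _read_from_interval(
                    seg.query_name, seg.reference_start, seg.reference_end,
                    strand, library,
                )
            )
    return reads


def read_alignments(path, fmt: str | None = None):
    """Dispatch on ``fmt`` or the file extension (.bed / .sam)."""
    fmt = fmt or Path(path).suffix.lstrip(".").lower()
    if fmt == "bed":
        return read_alignments_bed(path)
    if fmt == "sam":
        return read_alignments_sam(path)
    raise ValueError(f"unknown alignment format {fmt!r}")


# ------------------------------------------------------------------ call I/O

def write_tss_table(calls, path):
    pd.DataFrame(
        [
            {
                "position": c.position, "strand": c.strand,
                "count_enriched": c.count_enriched,
                "count_control": c.count_control,
                "enrichment_ratio": c.enrichment_ratio,
                "cluster_start": c.cluster_span[0],
                "cluster_end": c.cluster_span[1],
            }
            for c in calls
        ],
        columns=[
            "position", "strand", "count_enriched", "count_control",
            "enrichment_ratio", "cluster_start", "cluster_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_tss_table(path):
    df = pd.read_csv(path, sep="\t")
    return [
        TSSCall(
            int(r.position), r.strand, int(r.count_enriched),
            int(r.count_control), float(r.enrichment_ratio),
            (int(r.cluster_start), int(r.cluster_end)),
        )
        for r in df.itertuples()
    ]


def write_tts_table(calls, path):
    pd.DataFrame(
        [
            {
                "position": c.position, "strand": c.strand,
                "n_terminated": c.n_terminated,
                "n_readthrough": c.n_readthrough,
                "termination_efficiency": c.termination_efficiency,
                "cluster_start": c.cluster_span[0],
                "cluster_end": c.cluster_span[1],
            }
            for c in calls
        ],
        columns=[
            "position", "strand", "n_terminated", "n_readthrough",
            "termination_efficiency", "cluster_start", "cluster_end",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_tts_table(path):
    df = pd.read_csv(path, sep="\t")
    return [
        TTSCall(
            int(r.position), r.strand, int(r.n_terminated),
            int(r.n_readthrough), float(r.termination_efficiency),
            (int(r.cluster_start), int(r.cluster_end)),
        )
        for r in df.itertuples()
    ]


def write_calls_bed(calls, path, chrom: str):
    """1-nt BED features for TSS/TTS tracks."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, 1):
            score = getattr(c, "count_enriched", None)
            if score is None:
                score = getattr(c, "n_terminated", 0)
            fh.write(
                f"{chrom}\t{c.position}\t{c.position + 1}\tsite{i:03d}\t{score}\t{c.strand}\n"
            )


def tu_table(tus) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tu_id": t.tu_id, "strand": t.strand,
                "start": t.span[0], "end": t.span[1],
                "tss_position": t.start_tss.position,
                "tts_position": t.end_tts.position if t.end_tts else -1,
                "supporting_reads": t.supporting_reads,
                "genes": ",".join(t.gene_ids),
                "noncoding": t.noncoding_flag,
            }
            for t in tus
        ],
        columns=[
            "tu_id", "strand", "start", "end", "tss_position", "tts_position",
            "supporting_reads", "genes", "noncoding",
        ],
    )


def write_tu_table(tus, path):
    tu_table(tus).to_csv(path, sep="\t", index=False)


def read_tu_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def write_operon_table(operons, path):
    pd.DataFrame(
        [
            {
                "operon_id": o.operon_id, "strand": o.strand,
                "n_tus": len(o.tus),
                "tus": ",".join(t.tu_id for t in o.tus),
                "genes": ",".join(sorted(o.gene_union)),
            }
            for o in operons
        ],
        columns=["operon_id", "strand", "n_tus", "tus", "genes"],
    ).to_csv(path, sep="\t", index=False)


def write_architecture_gff3(path, genome: Genome, tss_calls, tts_calls, tus, operons):
    """GFF3 with TSS, terminator, transcription_unit and operon features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome.seq)}\n")

        def row(ftype, start0, end0, strand, attrs):
            fh.write(
                "\t".join(
                    [genome.name, "phagetx", ftype, str(start0 + 1), str(end0),
                     ".", strand, ".", attrs]
                ) + "\n"
            )

        for i, c in enumerate(tss_calls, 1):
            row("TSS", c.position, c.position + 1, c.strand,
                f"ID=TSS{i:03d};enrichment_ratio={c.enrichment_ratio:.3f}")
        for i, c in enumerate(tts_calls, 1):
            row("terminator", c.position, c.position + 1, c.strand,
                f"ID=TTS{i:03d};termination_efficiency={c.termination_efficiency:.3f}")
        for t in tus:
            row("transcription_unit", t.span[0], t.span[1], t.strand,
                f"ID={t.tu_id};genes={','.join(t.gene_ids)}")
        for o in operons:
            lo = min(t.span[0] for t in o.tus)
            hi = max(t.span[1] for t in o.tus)
            row("operon", lo, hi, o.strand,
                f"ID={o.operon_id};tus={','.join(t.tu_id for t in o.tus)}")


# ----------------------------------------------------------------- truth I/O

def write_truth_table(truth, path):
    pd.DataFrame(
        [
            {
                "kind": e.kind, "position": e.position, "strand": e.strand,
                "expression_weight": e.expression_weight,
                "promoter_sequence": e.promoter_sequence or "",
                "termination_efficiency": (
                    "" if e.termination_efficiency is None else e.termination_efficiency
                ),
                "intrinsic": "" if e.intrinsic is None else e.intrinsic,
            }
            for e in truth
        ],
        columns=[
            "kind", "position", "strand", "expression_weight",
            "promoter_sequence", "termination_efficiency", "intrinsic",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_truth_table(path):
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    truth = []
    for r in df.itertuples():
        is_tts = r.kind == "tts"
        truth.append(
            PlantedElement(
                r.kind, int(r.position), r.strand, float(r.expression_weight),
                promoter_sequence=r.promoter_sequence or None,
                termination_efficiency=float(r.termination_efficiency) if is_tts else None,
                intrinsic=(str(r.intrinsic) == "True") if is_tts else None,
            )
        )
    return truth


# --------------------------------------------------------------- kinetics I/O

def read_growth_tsv(path):
    """Growth curves as TSV: columns ``time``, ``nc``, and ``moi_<value>``."""
    import numpy as np

    from .kinetics import GrowthCurveSet

    df = pd.read_csv(path, sep="\t")
    moi_cols = [c for c in df.columns if c.startswith("moi_")]
    return GrowthCurveSet(
        time_grid=df["time"].to_numpy(dtype=float),
        nc_curve=df["nc"].to_numpy(dtype=float),
        od_curves={float(c[4:]): df[c].to_numpy(dtype=float) for c in moi_cols},
    )


def write_growth_tsv(curves, path):
    df = pd.DataFrame({"time": curves.time_grid, "nc": curves.nc_curve})
    for moi in sorted(curves.od_curves):
        df[f"moi_{moi:g}"] = curves.od_curves[moi]
    df.to_csv(path, sep="\t", index=False)


def read_adsorption_tsv(path):
    """Adsorption assay TSV: columns ``time`` (min) and ``titer`` (PFU/mL);
    the t=0 row supplies P0."""
    from .kinetics import TiterSeries

    df = pd.read_csv(path, sep="\t").sort_values("time")
    t0 = df[df["time"] == 0]
    if t0.empty:
        raise ValueError("adsorption TSV needs a time=0 row for P0")
    rest = df[df["time"] > 0]
    return {
        "P0": float(t0["titer"].iloc[0]),
        "times": tuple(rest["time"].astype(float)),
        "P_t": tuple(rest["titer"].astype(float)),
    }


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
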