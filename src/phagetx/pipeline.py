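"""End-to-end orchestration: simulate/load -> call ends -> build units ->
annotate regulatory elements -> summarise.

Every numeric threshold in the effective configuration is logged, and all
outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import formats
from .config import PipelineConfig
from .ends import call_tss, call_tts, collect_end_counts
from .evaluate import match_calls, termination_efficiency_errors
from .motifs import (
    classify_promoter,
    discover_motif,
    extract_promoter_window,
    motif_significance,
    rescan_genome,
)
from .synthetic import (
    SyntheticGenomeSpec,
    default_element_requests,
    generate_genome,
    plant_regulatory_elements,
    simulate_reads,
)
from .terminators import (
    detect_intrinsic_terminator,
    extract_terminator_window,
    with_readthrough,
)
from .units import assign_genes, build_operons, pair_boundaries, summarize_architecture

log = logging.getLogger("phagetx")


@dataclass
class PipelineResult:
    manifest: dict
    genome: object
    features: list
    truth: list | None
    tss_calls: list
    tts_calls: list
    tus: list
    operons: list
    promoters: list
    terminators: list
    motif: object
    summary: dict
    recovery: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("effective configuration: %s", dataclasses.asdict(config))
    manifest = {}
    stage = "setup"

    def _stage(name):
        nonlocal stage
        stage = name
        log.info("stage: %s", name)

    try:
        _stage("inputs")
        truth = None
        if config.simulate:
            spec = SyntheticGenomeSpec(rng_seed=config.seed)
            genome, features = generate_genome(spec)
            genome, truth = plant_regulatory_elements(
                genome, features, default_element_requests(features),
                rng_seed=config.seed,
            )
            enriched, control = simulate_reads(genome, truth, config.sim_params())
            reads = enriched + control
            formats.write_genome_fasta(genome, outdir / "genome.fasta")
            manifest["genome.fasta"] = str(outdir / "genome.fasta")
            formats.write_genes_gff3(features, genome, outdir / "genes.gff3")
            manifest["genes.gff3"] = str(outdir / "genes.gff3")
            formats.write_truth_table(truth, outdir / "truth.tsv")
            manifest["truth.tsv"] = str(outdir / "truth.tsv")
            formats.write_alignments_bed(reads, outdir / "alignments.bed", genome.name)
            manifest["alignments.bed"] = str(outdir / "alignments.bed")
        else:
            if not (config.genome_fasta and config.annotation_gff and config.alignments):
                raise ValueError(
                    "simulate=False requires genome_fasta, annotation_gff and alignments"
                )
            genome = formats.read_genome_fasta(config.genome_fasta)
            features = formats.read_genes_gff3(config.annotation_gff)
            reads = formats.read_alignments(config.alignments)
            enriched = [r for r in reads if r.library == "enriched"]
            control = [r for r in reads if r.library == "control"]

        _stage("call-ends")
        params = config.end_params()
        total = {"enriched": len(enriched), "control": len(control)}
        tss_calls = call_tss(
            collect_end_counts(enriched, "five_prime"),
            collect_end_counts(control, "five_prime"),
            total,
            params,
        )
        tts_calls = call_tts(reads, params, tss_positions=tss_calls)
        formats.write_tss_table(tss_calls, outdir / "tss.tsv")
        manifest["tss.tsv"] = str(outdir / "tss.tsv")
        formats.write_tts_table(tts_calls, outdir / "tts.tsv")
        manifest["tts.tsv"] = str(outdir / "tts.tsv")
        formats.write_calls_bed(tss_calls, outdir / "tss.bed", genome.name)
        manifest["tss.bed"] = str(outdir / "tss.bed")
        formats.write_calls_bed(tts_calls, outdir / "tts.bed", genome.name)
        manifest["tts.bed"] = str(outdir / "tts.bed")

        _stage("build-units")
        tus = pair_boundaries(tss_calls, tts_calls, reads, config.unit_params())
        for tu in tus:
            assign_genes(tu, features, config.gene_coverage)
        operons = build_operons(tus)
        formats.write_tu_table(tus, outdir / "tus.tsv")
        manifest["tus.tsv"] = str(outdir / "tus.tsv")
        formats.write_operon_table(operons, outdir / "operons.tsv")
        manifest["operons.tsv"] = str(outdir / "operons.tsv")
        formats.write_architecture_gff3(
            outdir / "architecture.gff3", genome, tss_calls, tts_calls, tus, operons
        )
        manifest["architecture.gff3"] = str(outdir / "architecture.gff3")

        _stage("annotate-regulatory")
        promoters = []
        motif_result = None
        if len(tss_calls) >= 2:
            windows = [
                extract_promoter_window(genome, c.position, c.strand)
                for c in tss_calls
            ]
            motif_result = discover_motif(
                windows,
                width=config.motif_width,
                n_restarts=config.motif_restarts,
                seed=config.seed,
            )
            if config.motif_shuffles > 0:
                threshold, significant = motif_significance(
                    windows,
                    width=config.motif_width,
                    n_shuffles=config.motif_shuffles,
                    seed=config.seed,
                )
                motif_result = dataclasses.replace(
                    motif_result, significant=significant, ic_threshold=threshold
                )
            thresholds = config.promoter_thresholds()
            for call, window in zip(tss_calls, windows):
                promoters.append((call, classify_promoter(window, motif_result.pwm, thresholds)))
            (outdir / "motif.meme.txt").write_text(motif_result.pwm.to_meme_text("phage_promoter"))
            manifest["motif.meme.txt"] = str(outdir / "motif.meme.txt")
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "position": c.position,
                        "strand": c.strand,
                        "class": p.promoter_class,
                        "sigma70_score": p.sigma70_score,
                        "phage_motif_score": p.phage_motif_score,
                    }
                    for c, p in promoters
                ]
            ).to_csv(outdir / "promoters.tsv", sep="\t", index=False)
            manifest["promoters.tsv"] = str(outdir / "promoters.tsv")

            if config.rescan:
                hits = rescan_genome(
                    genome,
                    motif_result.pwm,
                    config.rescan_threshold_fraction * motif_result.pwm.max_score,
                    known_tss=tss_calls,
                )
                pd.DataFrame(
                    [
                        {"position": h.position, "strand": h.strand,
                         "score": h.score, "label": h.label}
                        for h in hits
                    ]
                ).to_csv(outdir / "motif_rescan.tsv", sep="\t", index=False)
                manifest["motif_rescan.tsv"] = str(outdir / "motif_rescan.tsv")

        terminators = []
        for call in tts_calls:
            window = extract_terminator_window(genome, call.position, call.strand)
            tcall = with_readthrough(
                detect_intrinsic_terminator(window), call.termination_efficiency
            )
            terminators.append((call, tcall))
        if terminators:
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "position": c.position, "strand": c.strand,
                        "intrinsic": t.intrinsic,
                        "stem_length": t.stem_length, "loop_length": t.loop_length,
                        "stem_score": t.stem_score, "u_tail_score": t.u_tail_score,
                        "readthrough": t.readthrough,
                    }
                    for c, t in terminators
                ]
            ).to_csv(outdir / "terminators.tsv", sep="\t", index=False)
            manifest["terminators.tsv"] = str(outdir / "terminators.tsv")

        _stage("summarize")
        summary = summarize_architecture(tus, operons)
        summary["n_tss"] = len(tss_calls)
        summary["n_tts"] = len(tts_calls)
        recovery = {}
        if truth is not None:
            truth_tss = [e for e in truth if e.kind.startswith("tss")]
            truth_tts = [e for e in truth if e.kind == "tts"]
            recovery["tss_f1"] = match_calls(truth_tss, tss_calls).f1
            recovery["tts_f1"] = match_calls(truth_tts, tts_calls).f1
            te_err = termination_efficiency_errors(truth_tts, tts_calls)
            recovery["te_max_abs_error"] = max(te_err) if te_err else float("nan")
            summary.update(recovery)
        formats.write_json(summary, outdir / "summary.json")
        manifest["summary.json"] = str(outdir / "summary.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(
        manifest=manifest,
        genome=genome,
        features=features,
        truth=truth,
        tss_calls=tss_calls,
        tts_calls=tts_calls,
        tus=tus,
        operons=operons,
        promoters=promoters,
        terminators=terminators,
        motif=motif_result,
        summary=summary,
        recovery=recovery,
    )
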