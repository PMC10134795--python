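"""Flat pipeline configuration with YAML round-tripping."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .ends import EndCallingParams
from .motifs import PromoterThresholds
from .synthetic import ReadSimParams
from .units import UnitParams


@dataclass
class PipelineConfig:
    # inputs / outputs
    simulate: bool = True
    genome_fasta: str | None = None
    annotation_gff: str | None = None
    alignments: str | None = None       # BED6 or SAM; library tag per record
    outdir: str = "results/pipeline"
    seed: int = 7

    # synthetic data (used when simulate=True)
    depth_primary: int = 200
    capture_efficiency_enriched: float = 0.9
    capture_efficiency_control: float = 0.2
    end_jitter_sd: float = 1.0
    truncation_probability: float = 0.02
    background_read_rate: float = 0.05

    # end calling
    cluster_window: int = 5
    min_count: int = 5
    min_ratio: float = 3.0
    pseudocount: float = 0.5
    min_coverage: int = 20
    min_te: float = 0.25
    flank: int = 10

    # transcription units
    min_span_support: int = 3
    boundary_tol: int = 5
    gene_coverage: float = 0.90

    # regulatory elements
    motif_width: int = 17
    motif_restarts: int = 5
    motif_shuffles: int = 50
    phage_threshold_fraction: float = 0.7
    sigma70_threshold_fraction: float = 0.7
    rescan: bool = True
    rescan_threshold_fraction: float = 0.8

    # kinetics
    phage_score_variant: str = "as_printed"

    def end_params(self) -> EndCallingParams:
        return EndCallingParams(
            cluster_window=self.cluster_window,
            min_count=self.min_count,
            min_ratio=self.min_ratio,
            pseudocount=self.pseudocount,
            min_coverage=self.min_coverage,
            min_te=self.min_te,
            flank=self.flank,
        )

    def unit_params(self) -> UnitParams:
        return UnitParams(min_span_support=self.min_span_support, tol=self.boundary_tol)

    def sim_params(self) -> ReadSimParams:
        return ReadSimParams(
            depth_primary=self.depth_primary,
            capture_efficiency_enriched=self.capture_efficiency_enriched,
            capture_efficiency_control=self.capture_efficiency_control,
            end_jitter_sd=self.end_jitter_sd,
            truncation_probability=self.truncation_probability,
            background_read_rate=self.background_read_rate,
            rng_seed=self.seed,
        )

    def promoter_thresholds(self) -> PromoterThresholds:
        return PromoterThresholds(
            phage_fraction=self.phage_threshold_fraction,
            sigma70_fraction=self.sigma70_threshold_fraction,
        )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
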