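"""Synthetic genome/read generator: planted truth must be recoverable."""

import numpy as np
import pytest

from phagetx import (
    ElementRequest,
    Genome,
    PlantedElement,
    ReadSimParams,
    SyntheticGenomeSpec,
    generate_genome,
    plant_regulatory_elements,
    simulate_reads,
)
from phagetx.synthetic import PHAGE_MOTIF, default_element_requests
from phagetx._seq import revcomp


class TestGenerateGenome:
    def test_direct_terminal_repeats(self):
        spec = SyntheticGenomeSpec(genome_length=37343, dtr_length=244, rng_seed=1)
        genome, _ = generate_genome(spec)
        assert len(genome.seq) == 37343
        assert genome.seq[:244] == genome.seq[37099:]

    def test_zero_length_repeat_is_allowed(self):
        spec = SyntheticGenomeSpec(genome_length=12000, dtr_length=0, n_genes=8, rng_seed=1)
        genome, _ = generate_genome(spec)
        assert len(genome.seq) == 12000

    def test_gc_content_realised(self):
        spec = SyntheticGenomeSpec(genome_length=50000, gc_content=0.61, rng_seed=3)
        genome, _ = generate_genome(spec)
        gc = (genome.seq.count("G") + genome.seq.count("C")) / len(genome.seq)
        assert abs(gc - 0.61) <= 0.01

    def test_genes_sorted_nonoverlapping_and_modular(self):
        genome, features = generate_genome(SyntheticGenomeSpec(rng_seed=5))
        assert len(features) == 56
        for a, b in zip(features, features[1:]):
            assert a.end <= b.start
        modules = [f.module for f in features]
        # early -> middle -> late blocks in order
        assert modules == sorted(modules, key=["early", "middle", "late"].index)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(genome_length=400, dtr_length=244), "genome_length"),
            (dict(gc_content=0.0), "gc_content"),
            (dict(n_genes=0), "n_genes"),
        ],
    )
    def test_invalid_spec_names_offending_field(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            generate_genome(SyntheticGenomeSpec(**kwargs))

    def test_deterministic_for_fixed_seed(self):
        a = generate_genome(SyntheticGenomeSpec(rng_seed=9))
        b = generate_genome(SyntheticGenomeSpec(rng_seed=9))
        assert a[0].seq == b[0].seq
        assert a[1] == b[1]


class TestPlantElements:
    def test_default_layout_counts(self, dataset):
        _, _, truth, _, _ = dataset
        kinds = [e.kind for e in truth]
        assert kinds.count("tss_host") == 3
        assert kinds.count("tss_phage") == 8
        assert kinds.count("tts") == 6
        intrinsic = [e for e in truth if e.kind == "tts" and e.intrinsic]
        assert len(intrinsic) == 3

    def test_intrinsic_hairpin_base_pairs_by_construction(self, dataset):
        genome, _, truth, _, _ = dataset
        stem, loop, tail = 8, 4, 8
        for e in truth:
            if e.kind != "tts" or not e.intrinsic or e.strand != "+":
                continue
            total = 2 * stem + loop + tail
            frag = genome.seq[e.position - total + 1:e.position + 1]
            arm1, arm2 = frag[:stem], frag[stem + loop:stem + loop + stem]
            assert arm2 == revcomp(arm1)
            assert frag[-tail:] == "T" * tail

    def test_phage_promoter_written_at_tss(self, dataset):
        genome, _, truth, _, _ = dataset
        exact = [
            e for e in truth
            if e.kind == "tss_phage" and e.promoter_sequence == PHAGE_MOTIF
        ]
        assert exact, "default layout plants exact motif copies"
        for e in exact:
            if e.strand == "+":
                observed = genome.seq[e.position - 16:e.position + 1]
            else:
                observed = revcomp(genome.seq[e.position:e.position + 17])
            assert observed == PHAGE_MOTIF

    def test_empty_request_list_leaves_genome_unchanged(self):
        genome, features = generate_genome(SyntheticGenomeSpec(rng_seed=2))
        out, truth = plant_regulatory_elements(genome, features, [])
        assert truth == []
        assert out.seq == genome.seq

    def test_collision_with_gene_is_reported(self):
        genome, features = generate_genome(SyntheticGenomeSpec(rng_seed=2))
        inside = (features[10].start + features[10].end) // 2
        req = ElementRequest("tss_phage", inside, "+")
        with pytest.raises(ValueError, match=features[10].gene_id):
            plant_regulatory_elements(genome, features, [req])

    def test_antisense_pair_planted(self, dataset):
        _, features, truth, _, _ = dataset
        minus = [e for e in truth if e.strand == "-"]
        assert {e.kind for e in minus} == {"tss_phage", "tts"}


def _toy_setup(seed=0, length=6000):
    rng = np.random.default_rng(seed)
    genome = Genome("toy", "".join(rng.choice(list("ACGT"), size=length)))
    return genome


class TestSimulateReads:
    def test_full_termination_no_noise_gives_exact_spans(self):
        genome = _toy_setup()
        truth = [
            PlantedElement("tss_phage", 1000, "+"),
            PlantedElement("tts", 2000, "+", termination_efficiency=1.0, intrinsic=False),
        ]
        params = ReadSimParams(
            depth_primary=50, capture_efficiency_enriched=1.0,
            capture_efficiency_control=1.0, end_jitter_sd=0.0,
            truncation_probability=0.0, background_read_rate=0.0, rng_seed=1,
        )
        enriched, control = simulate_reads(genome, truth, params)
        for r in enriched + control:
            assert (r.five_prime, r.three_prime) == (1000, 2000)

    def test_termination_efficiency_is_binomial(self):
        genome = _toy_setup()
        truth = [
            PlantedElement("tss_phage", 500, "+"),
            PlantedElement("tts", 2000, "+", termination_efficiency=0.75, intrinsic=False),
            PlantedElement("tts", 4000, "+", termination_efficiency=1.0, intrinsic=False),
        ]
        params = ReadSimParams(
            depth_primary=400, capture_efficiency_enriched=1.0,
            capture_efficiency_control=1.0, end_jitter_sd=0.0,
            truncation_probability=0.0, background_read_rate=0.0, rng_seed=5,
        )
        enriched, _ = simulate_reads(genome, truth, params)
        frac = sum(1 for r in enriched if r.three_prime == 2000) / len(enriched)
        assert abs(frac - 0.75) <= 0.05

    def test_enrichment_ratio_of_capture_efficiencies(self):
        genome = _toy_setup()
        truth = [
            PlantedElement("tss_phage", 1000, "+"),
            PlantedElement("tts", 4000, "+", termination_efficiency=1.0, intrinsic=False),
        ]
        params = ReadSimParams(
            depth_primary=300, capture_efficiency_enriched=1.0,
            capture_efficiency_control=0.2, end_jitter_sd=0.0,
            truncation_probability=0.0, background_read_rate=0.0, rng_seed=3,
        )
        enriched, control = simulate_reads(genome, truth, params)
        cpm_e = sum(1 for r in enriched if r.five_prime == 1000) / len(enriched) * 1e6
        cpm_c = sum(1 for r in control if r.five_prime == 1000) / len(control) * 1e6
        assert cpm_e / cpm_c >= 3

    def test_no_tss_is_an_error(self):
        genome = _toy_setup()
        with pytest.raises(ValueError, match="no transcription sources"):
            simulate_reads(genome, [], ReadSimParams())

    def test_five_prime_strictly_upstream_of_three_prime(self, dataset):
        _, _, _, enriched, control = dataset
        for r in enriched + control:
            if r.strand == "+":
                assert r.five_prime < r.three_prime
            else:
                assert r.five_prime > r.three_prime

    def test_truth_recoverability_of_primary_ends(self, dataset):
        _, _, truth, enriched, _ = dataset
        tss_pos = {
            (e.strand, e.position)
            for e in truth if e.kind.startswith("tss")
        }
        params = ReadSimParams()
        sd = params.end_jitter_sd
        near = sum(
            1 for r in enriched
            if any(s == r.strand and abs(r.five_prime - p) <= 2 * sd for s, p in tss_pos)
        )
        # primary = captured reads emitted at a TSS (excludes background reads)
        n_primary = params.capture_efficiency_enriched * sum(
            round(params.depth_primary * e.expression_weight)
            for e in truth if e.kind.startswith("tss")
        )
        assert near / n_primary >= 0.95

    def test_byte_identical_for_fixed_seed(self):
        genome, features = generate_genome(SyntheticGenomeSpec(rng_seed=4))
        genome, truth = plant_regulatory_elements(
            genome, features, default_element_requests(features), rng_seed=4
        )
        params = ReadSimParams(depth_primary=20, rng_seed=4)
        a = simulate_reads(genome, truth, params)
        b = simulate_reads(genome, truth, params)
        assert a == b
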