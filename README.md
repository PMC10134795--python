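# phagetx

Strand-aware mapping of a bacteriophage primary transcriptome from 5'-enriched
long-read libraries, plus the standard phage infection-kinetics metrics.

Phage genomes are small and transcriptionally dense: promoters, terminators and
overlapping transcription units (TUs) pack into a few tens of kilobases, and
partial termination ("read-through") produces nested transcripts that short-read
RNA-seq cannot resolve. Cappable-seq-style protocols sequence full-length primary
transcripts in two libraries — one enriched for triphosphorylated (primary) 5'
ends, one untreated control — so that transcript boundaries can be read directly
off the alignments. This package implements that analysis for phage-sized
genomes, for people characterising new phages or mining them for regulatory
parts:

* **TSS calling** — 5'-end positions are clustered (peak-seeded, window 5 nt)
  and called where the enriched library shows ≥ 5 reads and a ≥ 3-fold
  enriched/control CPM ratio (with a 0.5-CPM pseudocount).
* **TTS calling** — pooled 3'-end clusters annotated with a termination
  efficiency TE = n_terminated / (n_terminated + n_readthrough); with known
  TSSs the counts are restricted to 5'-anchored (full-length) reads, which
  removes the length bias that degraded fragments introduce.
* **TU and operon inference** — a TU is a (TSS, TTS) pair supported by ≥ 3
  reads spanning it end to end (±5 nt); a TSS with no supported terminator
  keeps its longest transcript. Genes ≥ 90% covered on the same strand are
  assigned; operons are connected components of same-strand TUs sharing a gene.
* **Regulatory elements** — promoter windows (−100..+1) are classified as host
  σ70-like (consensus log-odds for TTGACA ⟨15–19 nt spacer⟩ TATAAT) or
  phage-specific (a shared motif discovered de novo by a deterministic
  one-occurrence-per-sequence EM with a shuffled-input significance test, and
  rescanned genome-wide); terminator windows (−60..+40) are searched
  exhaustively for an intrinsic hairpin (stem 4–20 bp, loop 3–10 nt, GC/AU/GU
  weights 3/2/1) followed by a U-tract.
* **Infection kinetics** — adsorption constant k = 2.3/(B·t)·log10(P0/Pt),
  areas under OD600 infection curves, local virulence v_MOI = 1 − A_MOI/A_NC,
  virulence index V_φ (area under v vs log10 MOI, normalised to its maximum),
  and phage score P_s (1/MOI-weighted mean of normalised areas).

A first-class synthetic-data module generates a T7-like genome (direct terminal
repeats, 61% GC, early/middle/late gene modules) with planted promoters,
terminators, an antisense transcript and simulated read libraries, so the whole
pipeline is testable against known ground truth without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data:

```
$ python analysis/01_simulate_transcriptome.py
genome: 37343 nt, 56 genes
planted truth: 11 TSSs, 6 TTSs (3 intrinsic)
libraries: 2394 enriched + 2394 control reads

$ python analysis/02_call_transcript_boundaries.py
called 11 TSSs (F1 vs truth 1.000 at +-5 nt)
called 6 TTSs (F1 vs truth 1.000 at +-5 nt)
termination efficiency: max |error| 0.017

$ python analysis/03_build_transcription_units.py
16 transcription units covering on average 9.7 genes
4 operons; 1 noncoding TU(s) (antisense transcript)
5 TU pair(s) share a TSS with different terminators (read-through)

$ python analysis/04_classify_regulatory_elements.py
discovered 17-bp motif TAGTACGACTCCTATAG (IC 15.4 bits vs null 95th pct 9.5; significant)
phage_specific    8
host_sigma70      3
genome rescan: 8 motif hits, 0 beyond the called TSSs
3/6 terminators are intrinsic (hairpin + U-tail)

$ python analysis/05_infection_kinetics.py
control area A_NC = 109.3 OD*min
MOI 1: A = 29.6, local virulence v = 0.729
MOI 10: A = 20.0, local virulence v = 0.817
virulence index V_phi = 0.773 (0 = no killing, 1 = instant lysis)
phage score P_s = 0.263 (as printed: 1 = no killing)
adsorption constant at 15 min: k = 1.26e-09 mL/min
```

Reading the output: all 11 planted transcription start sites and 6 termination
sites are recovered exactly; the 16 TUs exceed the 6 terminators because
partial terminators (TE 0.8–0.9) let transcripts read through into nested,
TSS-sharing units — the mechanism that inflates TU counts in dense phage
transcriptomes. The 17-bp consensus is the planted phage-RNAP promoter motif,
found in all 8 phage-type promoter windows and nowhere else on the genome at
the 0.8·max score threshold. A virulence index of 0.77 describes an
aggressively lytic simulation; note the as-printed phage score has opposite
polarity (1 = harmless).

The same pipeline is exposed as a CLI (`phagetx simulate | call-ends |
build-units | annotate-regulatory | kinetics | run-all`) and as a library
(`phagetx.run_pipeline(PipelineConfig(...))`). Real data enter as a genome
FASTA, gene GFF3, and BED6 or SAM alignments with the library tag in the BED
score column or SAM read group.

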