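# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `phagetx`, and what the synthetic benchmark does and does
not demonstrate.

## Coordinates and read model

All intervals are 0-based half-open on forward genome coordinates; GFF3 output
is 1-based inclusive and BED output 0-based half-open (GFF start = BED start
+ 1, asserted in tests). An aligned read carries the genome coordinates of its
biological 5' and 3' ends (covered bases, so on the forward strand
5' < 3' and on the reverse strand 5' > 3') plus a library tag
(`enriched`/`control`). In BED6 the library tag travels in the score column;
in SAM, in the read group.

## TSS calling

5'-end positions are clustered per strand by a peak-seeded rule: repeatedly
take the unclaimed position with the highest enriched-library count (ties to
the most-upstream position on that strand) and absorb all unclaimed positions
within `cluster_window` (default 5 nt) of the peak. Peak seeding, rather than
left-anchored greedy grouping, keeps a jittered pileup that straddles a window
edge in one cluster. Each cluster is called a TSS when

* `count_enriched >= min_count` (default 5 reads), and
* `(CPM_e + pc) / (CPM_c + pc) >= min_ratio` (default 3, pseudocount
  pc = 0.5 CPM),

where CPMs are counts per million mapped reads per library (library sizes
differ). The reported position is the cluster mode. The thresholds are
deliberately exposed in the pipeline configuration: published workflows in
this space defer them to pipeline defaults, and they should be tuned to
library depth.

## TTS calling and termination efficiency

3'-end positions from both libraries are pooled (5'-cap enrichment does not
bias 3' ends) and clustered the same way. For a cluster spanning [lo, hi]:
`n_terminated` counts reads whose 3' end lies on a cluster position;
`n_readthrough` counts same-strand reads that start upstream of the cluster
and extend at least `flank` (10 nt) beyond it. A call requires coverage
`n_terminated + n_readthrough >= min_coverage` (20) and efficiency
`TE >= min_te` (0.25).

When TSS calls are available the pipeline restricts both counts to
*5'-anchored* reads — reads starting within `cluster_window` of a same-strand
TSS. The unrestricted estimator is length-biased in the presence of partially
degraded reads: a fragment of a read-through transcript can span the
terminator (and is counted as read-through), while a fragment of a terminated
transcript usually ends before it and carries no evidence; with an 80%-degraded
control library this biases TE by up to −0.05. Anchored reads are full-length
primary transcripts, making the estimate a plain binomial proportion. A
cluster with fewer than `min_coverage` anchored reads falls back to the
all-reads counts.

## Transcription units and operons

For every called TSS, every same-strand downstream TTS becomes a TU iff at
least `min_span_support` (3) reads start within `tol` (5 nt) of the TSS and
end within `tol` of the TTS — so partial terminators yield several nested,
TSS-sharing TUs (sequential read-through). A TSS with no supported pairing
keeps one TU ending at the 3'-most end among its reads (longest transcript).
Duplicate (TSS, end) pairs collapse with summed support. A gene is assigned to
a TU when at least 90% of the gene body lies inside the span on the same
strand; a TU with no genes is flagged noncoding (this is how the antisense
transcript surfaces). Operons are connected components (networkx) of the graph
joining same-strand TUs that share at least one gene; noncoding TUs are
singleton operons.

## Promoter models

Windows are −100..+1 around the TSS (101 nt including the TSS base; the "+1"
is taken as the TSS base itself), strand-oriented and clipped at genome ends.

**σ70 model.** Consensus-derived log-odds: each position of the −35 box
(TTGACA) and −10 box (TATAAT) carries probability 0.85 on the consensus base
and 0.05 elsewhere, scored in nats against a uniform 0.25 background
(max 14.69). The score of a window is the best over all placements with a
15–19 nt spacer. This is a deliberate simplification — not a model trained on
*Pseudomonas* promoter corpora — sufficient to separate written consensus-like
boxes from background.

**Phage motif.** The shared phage-RNAP promoter motif (width 17 by default) is
discovered by a deterministic one-occurrence-per-sequence EM: every k-mer
occurring in any window is evaluated as a seed (under a single-site PWM the
objective reduces to total best Hamming matches, so the enumeration is exact
and vectorised), the `n_restarts` best seeds are refined by iteratively
reassigning each window's site to its best placement under the PWM built from
the other windows (pseudocount 0.5), and the refinement with the highest total
information content wins. Significance is assessed against the 95th percentile
of information contents from re-discovery on within-window letter-shuffled
inputs (default 100 shuffles; the pipeline uses 50). Scores are log-odds in
nats and not comparable to MEME E-values.

**Classification.** A window is `phage_specific` when its best motif placement
reaches 0.7 of the PWM's maximum score; otherwise `host_sigma70` when the σ70
score reaches 0.7 of its maximum; otherwise `ambiguous`. Phage-before-host
ordering reflects that a single-subunit-RNAP promoter is the more specific
signal. The fraction-of-maximum form makes the thresholds robust to how sharp
the discovered PWM happens to be. Genome rescanning reports every position (on
either strand) scoring at or above a caller-chosen threshold — the pipeline
uses 0.8 of the maximum — labelled `known` when within 5 nt of a called TSS
occurrence and `candidate` otherwise; no non-maximum suppression is applied,
so the scan is exactly a thresholded position-by-position scorer.

## Intrinsic terminators

Windows are −60..+40 around the TTS (101 nt), strand-oriented. Candidate
hairpins with stem 4–20 bp, loop 3–10 nt and at most one internal mismatch are
enumerated exhaustively; the stem score sums pair weights (GC +3, AU +2, GU
+1, mismatch −2) minus 0.5 per loop nt, and the U-tail score counts T (U on
the transcript) in the 8 nt after the stem's 3' arm. A terminator is intrinsic
iff a hairpin reaches stem score ≥ 12 **and** U-tail ≥ 4; the reported hairpin
is the best such hairpin (by stem + tail score) when one exists, else the best
by stem score, so the reported scores are always consistent with the flag.
Integer pair weights stand in for nearest-neighbour free energies; only single
hairpins are modelled (no rho-dependent terminators, no multi-loop
structures).

## Infection kinetics

* Adsorption: k = 2.3/(B·t) · log10(P0/Pt) mL/min. The literal constant 2.3
  (the conventional rounding of ln 10) is kept. The argument order is fixed by
  the sign convention that k > 0 when free phage deplete; k = 0 when Pt = P0.
* Areas under OD600 curves are trapezoidal on the shared time grid.
* Local virulence v_MOI = 1 − A_MOI/A_NC, not clamped (an infected culture
  outgrowing the control legitimately yields v < 0).
* Virulence index V_φ: the virulence curve is v_MOI against log10(MOI);
  A_max is the area of v ≡ 1 over the tested log-MOI range, so V_φ ∈ (−∞, 1]
  with 0 = no killing and 1 = instantaneous complete lysis.
* Phage score P_s = [Σ (A_MOI(i)/A_NC)/MOI(i)] / [Σ 1/MOI(i)], implemented
  exactly in this printed form even though its polarity (1 = no killing) is
  opposite to V_φ; a `virulence_weighted` variant (numerators v_MOI) is
  available behind a flag, off by default.

The growth-curve simulator uses logistic control growth (OD0 0.3, capacity
1.4, r 0.025/min), a lysis onset of 30 min at MOI 10 plus 15 min per decade
below, exponential OD decay (0.12/min) to a floor of 0.03, a 15-min grid to
145 min, and additive Gaussian noise (σ 0.005) on infected curves only — the
control is noise-free so its monotonicity contract holds exactly.

## Synthetic study design

The default genome is 37,343 nt with 244-bp direct terminal repeats, 61% GC
and 56 forward-strand genes split into early/middle/late modules with
expression weights 1.0/1.1/1.2. The planted layout is 3 host σ70 promoters
(one carrying a −35 mismatch, mimicking a divergent promoter), 8 phage-type
promoters sharing a 17-bp motif (three carrying one mismatch; one antisense
to a late gene), and 6 terminators — efficiencies 0.8/1.0/0.9/1.0/1.0 along
the forward strand plus a fully efficient antisense terminator; the 0.8/0.9
terminators are intrinsic (written 8-bp GC stem, 4-nt loop, U8 tail) along
with the final one, the rest are positions only. Every read-through chain ends
in a TE = 1.0 terminator so that each (TSS, TTS) pairing has an expected
spanning-read count far above the support threshold (≥ 40 at default depth),
which keeps the expected TU catalogue (16 units) deterministic.

Reads: depth 200 per TSS per library, 5'-capture efficiency 0.9 (enriched)
vs 0.2 (control), Gaussian end jitter σ 1 nt, 2% of reads 5'-truncated by a
geometric(p = 0.01) amount (mean 100 nt, matching the broad 5' loss of
long-read cDNA rather than a sharp one), 5% background reads initiating
uniformly within active TUs. Non-captured reads are degradation products with
*both* ends internal, drawn as order statistics of two uniforms over the
transcript: keeping the true 3' end would re-create the length bias discussed
above, and drawing the 3' end sequentially after the 5' end piles fragment
ends log-divergently next to real terminators, producing satellite TTS calls —
the order-statistics draw has neither pathology. Windows around planted
non-intrinsic terminators are resampled (intergenic, non-element bases only)
until they contain no chance hairpin qualifying as intrinsic, so the truth
table is consistent with the detector's definition; in ~60% GC random
sequence such chance hairpins otherwise occur in a few percent of windows.
Simulated reads are reported against the left copy of the terminal repeat,
mirroring collapsed-repeat mapping.

What passing on this benchmark shows: the callers invert the generative model
they are tested against, at realistic depth, jitter, enrichment contrast and
degradation levels. What it does not show: robustness to mapping artefacts,
homopolymer basecalling error, RNA modifications, condition-dependent
expression, or manual curation of borderline sites — real long-read data have
all of these, and the thresholds exposed in the configuration are the knobs to
revisit there.

## Problem sizes and determinism

The default study simulates ~4,800 reads over a 37-kb genome; the full
pipeline (including 50-shuffle motif significance) runs in a couple of seconds,
and the test suite in well under a minute. Every stochastic component takes an
explicit integer seed (genome, planting, reads, growth noise, shuffle null);
fixed seed implies byte-identical outputs, which is asserted on the full
pipeline's files. Ties are broken deterministically throughout (cluster peaks:
most-upstream; motif seeds: first occurrence; hairpins: first encountered at
equal score).

## Known limitations

* TSS/TTS thresholds are depth-sensitive defaults, not universal constants.
* The anchored TE estimator needs called TSSs; without them the biased
  all-reads estimator is used.
* The σ70 and hairpin scores are simplified models adequate for planted-truth
  separation, not calibrated predictors for arbitrary genomes.
* Pooled-time-point libraries only: temporal expression enters through static
  module weights, not an infection-time model.
* The optional full-data route (aligning public accession reads) is out of
  scope here; the pipeline accepts such alignments as BED6/SAM but expects
  them to be produced externally.
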