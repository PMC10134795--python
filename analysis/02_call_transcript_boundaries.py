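#!/usr/bin/env python
"""Call TSSs and TTSs from the simulated libraries and score them vs truth.

TSSs require >= 5 enriched-library reads and a >= 3-fold enriched/control CPM
ratio at a clustered 5'-end position; TTSs are 3'-end clusters annotated with
a termination efficiency estimated from 5'-anchored (full-length) reads.

Reads results/synthetic/, writes results/boundaries/{tss.tsv, tts.tsv} and
prints recovery against the planted truth.
"""

import argparse
from pathlib import Path

from phagetx import call_tss, call_tts, collect_end_counts, formats
from phagetx.evaluate import match_calls, termination_efficiency_errors


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--outdir", type=Path, default=Path("results/boundaries"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    reads = formats.read_alignments(args.indir / "alignments.bed")
    truth = formats.read_truth_table(args.indir / "truth.tsv")
    enriched = [r for r in reads if r.library == "enriched"]
    control = [r for r in reads if r.library == "control"]

    tss = call_tss(
        collect_end_counts(enriched, "five_prime"),
        collect_end_counts(control, "five_prime"),
        {"enriched": len(enriched), "control": len(control)},
    )
    tts = call_tts(reads, tss_positions=tss)
    formats.write_tss_table(tss, args.outdir / "tss.tsv")
    formats.write_tts_table(tts, args.outdir / "tts.tsv")

    truth_tss = [e for e in truth if e.kind.startswith("tss")]
    truth_tts = [e for e in truth if e.kind == "tts"]
    m_tss = match_calls(truth_tss, tss, tolerance=5)
    m_tts = match_calls(truth_tts, tts, tolerance=5)
    te_err = termination_efficiency_errors(truth_tts, tts)
    print(f"called {len(tss)} TSSs (F1 vs truth {m_tss.f1:.3f} at +-5 nt)")
    print(f"called {len(tts)} TTSs (F1 vs truth {m_tts.f1:.3f} at +-5 nt)")
    if te_err:
        print(f"termination efficiency: max |error| {max(te_err):.3f}")
    print(f"wrote {args.outdir}/")


if __name__ == "__main__":
    main()
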