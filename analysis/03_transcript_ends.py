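#!/usr/bin/env python
"""Poly(A)-anchored end analysis of the ambiguous-code cohort.

Calls tails and primary stops from sequence alone, summarizes the 3'UTR
length distribution (median, zero-length fraction), counts codons
position-by-position toward the poly(A) site with the 0/1/2-nt
tail-completion convention, and tests each "stop" codon for proximal
depletion in the -90..-42 window against the distal coding sequence.
"""

import json
from pathlib import Path

from ambicode.codes import BUILTIN_CODES, read_fasta
from ambicode.ends import (
    PolyACall,
    base_frequency_profile,
    detect_polya,
    find_primary_stop,
    positional_codon_counts,
    stop_depletion_test,
    utr_length_distribution,
    write_positional_counts_tsv,
    write_primary_stop_calls_tsv,
)
from ambicode.simulate import GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = ROOT / "sim" / "ambiguous-cmag"
    transcripts = read_fasta(bundle / "transcripts.fasta")
    truth = GroundTruth.from_json(bundle / "ground_truth.json")
    bounds = dict(zip(truth.transcript_ids, zip(truth.cds_start, truth.cds_end)))
    for tr in transcripts:
        tr.cds_start, tr.cds_end = bounds[tr.id]
        tr.frame = tr.cds_start % 3
    stop_set = BUILTIN_CODES["ambiguous-cmag"].termination_set

    pairs, calls = [], []
    for tr in transcripts:
        polya = detect_polya(tr.seq, transcript_id=tr.id)
        if polya is None:
            continue
        pairs.append((tr, polya))
        call = find_primary_stop(tr, polya, stop_set=stop_set)
        if call is not None:
            calls.append(call)

    outdir = ROOT / "ends"
    outdir.mkdir(parents=True, exist_ok=True)
    write_primary_stop_calls_tsv(calls, outdir / "primary_stops.tsv")
    summary = utr_length_distribution(calls)
    print(
        f"tails: {len(pairs)}/{len(transcripts)}; primary stops: {len(calls)}; "
        f"3'UTR median {summary.median:.0f} nt (IQR {summary.q1:.0f}-{summary.q3:.0f}), "
        f"{100 * summary.fraction_zero:.1f}% UTR-less"
    )

    counts = positional_codon_counts(pairs, window=480)
    write_positional_counts_tsv(counts, outdir / "positional_counts.tsv")
    depletion = {}
    for codon in sorted(stop_set):
        rep = stop_depletion_test(counts, codon)
        depletion[codon] = {
            "proximal_rate": rep.proximal_rate,
            "distal_rate": rep.distal_rate,
            "ratio": rep.ratio,
            "p_value": rep.p_value,
        }
        print(
            f"{codon}: proximal/distal frequency ratio {rep.ratio:.2f} "
            f"(binomial p = {rep.p_value:.2e})"
        )
    profile = base_frequency_profile(pairs, window=240)
    profile.frequencies.to_csv(outdir / "base_frequencies.tsv", sep="\t", float_format="%.6g")
    print(
        "base-frequency flatness across -90..-42 (max abs deviation): "
        + ", ".join(f"{b}={v:.3f}" for b, v in profile.flatness.items())
    )
    (outdir / "depletion.json").write_text(json.dumps(depletion, indent=1, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
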