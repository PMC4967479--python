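#!/usr/bin/env python
"""Footprint geometry and readthrough on the ambiguous-code cohort.

Filters the mapped footprints (25-32 nt, <=1 mismatch), profiles 3' ends
around stop codons, classifies the termination signature (11/12 nt past the
stop's last base), and estimates per-transcript readthrough with the
stop-anchored denominator.
"""

from pathlib import Path

from ambicode.codes import read_fasta
from ambicode.ends import primary_stops_from_annotation
from ambicode.riboseq import (
    classify_termination,
    end_metaprofile,
    estimate_readthrough,
    filter_rpfs,
    frame_distribution,
    write_metaprofile_tsv,
    write_readthrough_tsv,
)
from ambicode.simulate import GroundTruth

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bundle = ROOT / "sim" / "ambiguous-cmag"
    transcripts = read_fasta(bundle / "transcripts.fasta")
    truth = GroundTruth.from_json(bundle / "ground_truth.json")
    for tr, s, e, p in zip(transcripts, truth.cds_start, truth.cds_end, truth.polya_site):
        tr.cds_start, tr.cds_end, tr.polya_site, tr.frame = s, e, p, s % 3

    rpfs, report = filter_rpfs(
        bundle / "rpfs.sam", references={tr.id: tr.seq for tr in transcripts}
    )
    print(f"footprints retained: {report.n_retained}/{report.n_input} (rejects {report.rejects})")

    frames = frame_distribution(rpfs, {tr.id: tr for tr in transcripts})
    outdir = ROOT / "riboseq"
    outdir.mkdir(parents=True, exist_ok=True)
    frames.to_csv(outdir / "frame_distribution.tsv", sep="\t", index=False, float_format="%.6g")

    stops = primary_stops_from_annotation(transcripts)
    anchors = [(c.transcript_id, c.stop_start) for c in stops]
    profile = end_metaprofile(rpfs, anchors, anchor_class="terminating-stop", rpf_length=30)
    write_metaprofile_tsv([profile], outdir / "stop_metaprofile.tsv", rpf_length="30")
    term = classify_termination(profile)
    print(
        f"termination signature: modal 3'-end offsets {term.modal_offsets} nt past the "
        f"stop 3' nt, {100 * term.fraction_in_modal:.1f}% of {term.total_ends} profiled ends"
    )

    estimates, summary = estimate_readthrough(rpfs, stops)
    write_readthrough_tsv(estimates, outdir / "readthrough.tsv")
    print(
        f"readthrough over {summary.n_covered} covered transcripts: "
        f"mean {100 * summary.mean_rate:.2f}%, median {100 * summary.median_rate:.1f}%, "
        f"{100 * summary.fraction_zero:.1f}% of transcripts show none"
    )


if __name__ == "__main__":
    main()
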