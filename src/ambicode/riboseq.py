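"""Ribosome-profiling evidence for context-dependent termination.

Footprints (ribosome-protected fragments, RPFs) of 25–32 nt are filtered
from transcript-mapped alignments (primary, ≤1 mismatch), and their 3'-end
geometry is profiled around anchor codons.  Terminating ribosomes protect
11–12 nt downstream of the stop codon's last base, so a stop codon's
metaprofile shows a sharp 3'-end peak at those two offsets — the
*termination signature* — while readthrough appears as footprints whose 3'
ends extend ≥13 nt past the primary stop.

Metaprofile offsets use the anchor-codon coordinate convention of stacked
ribo-seq figures: the anchor codon occupies positions 1–3, so a footprint
ending 11 nt after the stop's 3' nt sits at profile offset 14.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .codes import TranscriptRecord
from .ends import PrimaryStopCall

DEFAULT_LEN_MIN = 25
DEFAULT_LEN_MAX = 32
DEFAULT_MAX_MISMATCH = 1
TERMINATION_OFFSETS = (11, 12)  # nt past the stop codon 3' nt
DEFAULT_MIN_DOWNSTREAM = 13
DEFAULT_COVERAGE_MIN = 20


@dataclass
class RPFRecord:
    read_id: str
    transcript_id: str
    start: int  # 0-based half-open mapped span on the transcript
    end: int
    length: int
    mismatches: int = 0

    @property
    def end3(self) -> int:
        """0-based coordinate of the 3'-most mapped base."""
        return self.end - 1


@dataclass
class RPFFilterReport:
    n_input: int
    n_retained: int
    rejects: dict[str, int] = field(default_factory=dict)


def _mismatches(aln: pysam.AlignedSegment, references: Mapping[str, str] | None) -> int | None:
    if aln.has_tag("NM"):
        return int(aln.get_tag("NM"))
    if references is not None and aln.reference_name in references:
        ref = references[aln.reference_name]
        read = aln.query_sequence or ""
        n = 0
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            if read[qpos].upper() != ref[rpos].upper():
                n += 1
        return n
    return None


def filter_rpfs(
    alignments: str | Path | Iterable[pysam.AlignedSegment],
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    references: Mapping[str, str] | None = None,
) -> tuple[list[RPFRecord], RPFFilterReport]:
    """Retain primary mapped alignments within length and mismatch bounds.

    ``alignments`` may be a SAM/BAM path or an iterable of pysam records.
    The mismatch count is read from the NM tag when present, else recomputed
    against ``references`` (transcript id → sequence) when supplied.
    """
    handle = None
    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        stream: Iterable[pysam.AlignedSegment] = handle
    else:
        stream = alignments
    kept: list[RPFRecord] = []
    rejects: Counter[str] = Counter()
    n_input = 0
    try:
        for aln in stream:
            n_input += 1
            if aln.is_unmapped:
                rejects["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                rejects["secondary_or_supplementary"] += 1
                continue
            length = aln.query_length or aln.infer_query_length() or 0
            if not (len_min <= length <= len_max):
                rejects["length"] += 1
                continue
            nm = _mismatches(aln, references)
            if nm is None:
                rejects["no_mismatch_info"] += 1
                continue
            if nm > max_mismatch:
                rejects["mismatches"] += 1
                continue
            kept.append(
                RPFRecord(
                    read_id=aln.query_name,
                    transcript_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    length=length,
                    mismatches=nm,
                )
            )
    finally:
        if handle is not None:
            handle.close()
    return kept, RPFFilterReport(n_input, len(kept), dict(rejects))


def frame_distribution(
    rpfs: Sequence[RPFRecord],
    transcripts: Mapping[str, TranscriptRecord] | Iterable[TranscriptRecord],
) -> pd.DataFrame:
    """Per-length frame fractions of footprint 5' starts and 3' ends.

    Frames are 1/2/3 relative to the annotated CDS start: a position ``p``
    is in frame ``((p - cds_start) mod 3) + 1``.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {tr.id: tr for tr in transcripts}
    counts: dict[int, np.ndarray] = defaultdict(lambda: np.zeros((2, 3), dtype=np.int64))
    for r in rpfs:
        tr = transcripts.get(r.transcript_id)
        if tr is None or tr.cds_start is None:
            continue
        f5 = (r.start - tr.cds_start) % 3
        f3 = (r.end3 - tr.cds_start) % 3
        counts[r.length][0, f5] += 1
        counts[r.length][1, f3] += 1
    rows = []
    for length in sorted(counts):
        mat = counts[length]
        n = mat[0].sum()
        row: dict[str, float | int] = {"length": length, "n": int(n)}
        for which, name in ((0, "start5"), (1, "end3")):
            tot = mat[which].sum()
            for f in range(3):
                row[f"{name}_frame{f + 1}"] = mat[which, f] / tot if tot else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MetaProfile:
    """3'-end counts at offsets around anchor codons (anchor base 1 = offset 1)."""

    offsets: np.ndarray
    counts: np.ndarray
    anchor_class: str
    n_anchors: int
    n_skipped_anchors: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=pd.Index(self.offsets, name="offset"))


def end_metaprofile(
    rpfs: Sequence[RPFRecord],
    anchors: Sequence[tuple[str, int]],
    anchor_class: str = "sense-stop-set",
    flank: int = 30,
    rpf_length: int | None = None,
) -> MetaProfile:
    """Pool footprint 3'-end positions around anchor codons.

    ``anchors`` are (transcript_id, codon first-base coordinate) pairs.  The
    profile covers offsets ``-flank .. flank + 3`` in the anchor convention
    (anchor codon = positions 1–3).  ``rpf_length`` restricts to one
    footprint length (e.g. the 30-nt class); ``None`` pools all lengths.
    """
    offsets = np.arange(-flank, flank + 4)
    counts = np.zeros(len(offsets), dtype=np.int64)
    ends_by_tr: dict[str, list[int]] = defaultdict(list)
    for r in rpfs:
        if rpf_length is not None and r.length != rpf_length:
            continue
        ends_by_tr[r.transcript_id].append(r.end3)
    for tr_id in ends_by_tr:
        ends_by_tr[tr_id] = sorted(ends_by_tr[tr_id])
    n_skipped = 0
    for tr_id, anchor_start in anchors:
        if anchor_start < 0:
            n_skipped += 1
            continue
        ends = ends_by_tr.get(tr_id, ())
        # profile offset of an end at coordinate e is e - anchor_start + 1
        # (anchor codon occupies offsets 1..3)
        lo, hi = anchor_start - flank - 1, anchor_start + flank + 2
        i = np.searchsorted(ends, lo)
        j = np.searchsorted(ends, hi, side="right")
        for e in ends[i:j]:
            counts[e - anchor_start + 1 + flank] += 1
    return MetaProfile(
        offsets=offsets,
        counts=counts,
        anchor_class=anchor_class,
        n_anchors=len(anchors),
        n_skipped_anchors=n_skipped,
    )


@dataclass
class TerminationReport:
    modal_offsets: tuple[int, ...]  # nt past the stop codon 3' nt
    fraction_in_modal: float
    has_signature: bool
    total_ends: int


def classify_termination(
    profile: MetaProfile,
    signature_threshold: float = 0.5,
) -> TerminationReport:
    """Report the modal 3'-end offsets downstream of stop anchors.

    Offsets are re-expressed relative to the stop codon's 3' nt (profile
    offset 14 = 11 nt past the stop's last base).  The two modal downstream
    offsets are reported, collapsed to one when a single offset holds the
    mode outright (all ends at +11 → modal set {11}).  A termination
    signature is flagged when the modal offsets capture more than
    ``signature_threshold`` of all profiled ends.
    """
    if profile.total == 0:
        raise ValueError("empty metaprofile")
    rel = profile.offsets - 3  # nt past the stop 3' nt
    downstream = rel > 0
    ds_counts = profile.counts[downstream]
    ds_rel = rel[downstream]
    order = np.argsort(ds_counts, kind="stable")[::-1]
    top = [int(ds_rel[order[0]])]
    if len(order) > 1 and ds_counts[order[1]] > 0:
        top.append(int(ds_rel[order[1]]))
    modal = tuple(sorted(top))
    frac = float(ds_counts[np.isin(ds_rel, modal)].sum() / profile.total)
    return TerminationReport(
        modal_offsets=modal,
        fraction_in_modal=frac,
        has_signature=frac > signature_threshold,
        total_ends=profile.total,
    )


@dataclass
class ReadthroughEstimate:
    transcript_id: str
    n_stop_rpfs: int
    n_downstream_rpfs: int
    rate: float
    covered: bool


@dataclass
class ReadthroughSummary:
    n_transcripts: int
    n_covered: int
    mean_rate: float
    median_rate: float
    fraction_zero: float
    n_excluded_no_stop: int = 0


def estimate_readthrough(
    rpfs: Sequence[RPFRecord],
    primary_stops: Sequence[PrimaryStopCall],
    min_downstream: int = DEFAULT_MIN_DOWNSTREAM,
    coverage_min: int = DEFAULT_COVERAGE_MIN,
    signature_offsets: tuple[int, ...] = TERMINATION_OFFSETS,
) -> tuple[list[ReadthroughEstimate], ReadthroughSummary]:
    """Per-transcript readthrough rates and their cohort summary.

    For each transcript with a primary stop, ``n_stop`` counts footprints
    whose 3' end carries the termination signature (ends exactly
    ``signature_offsets`` nt past the stop's 3' nt) and ``n_downstream``
    counts footprints extending at least ``min_downstream`` nt past it.  The
    per-transcript rate is ``n_downstream / (n_downstream + n_stop)`` —
    the stop-anchored denominator; cohort mean/median/fraction-zero are over
    covered transcripts only (``n_stop + n_downstream > coverage_min``).
    """
    ends_by_tr: dict[str, list[int]] = defaultdict(list)
    for r in rpfs:
        ends_by_tr[r.transcript_id].append(r.end3)
    sig = set(signature_offsets)
    estimates: list[ReadthroughEstimate] = []
    for call in primary_stops:
        s3 = call.stop_start + 2
        offs = [e - s3 for e in ends_by_tr.get(call.transcript_id, ())]
        n_stop = sum(1 for o in offs if o in sig)
        n_down = sum(1 for o in offs if o >= min_downstream)
        denom = n_stop + n_down
        rate = n_down / denom if denom else 0.0
        estimates.append(
            ReadthroughEstimate(
                transcript_id=call.transcript_id,
                n_stop_rpfs=n_stop,
                n_downstream_rpfs=n_down,
                rate=rate,
                covered=denom > coverage_min,
            )
        )
    covered = [e.rate for e in estimates if e.covered]
    if covered:
        arr = np.array(covered)
        summary = ReadthroughSummary(
            n_transcripts=len(estimates),
            n_covered=len(covered),
            mean_rate=float(arr.mean()),
            median_rate=float(np.median(arr)),
            fraction_zero=float((arr == 0).mean()),
        )
    else:
        summary = ReadthroughSummary(len(estimates), 0, float("nan"), float("nan"), float("nan"))
    return estimates, summary


def readthrough_density_ratio(
    rpfs: Sequence[RPFRecord],
    call: PrimaryStopCall,
    min_downstream: int = DEFAULT_MIN_DOWNSTREAM,
    window: int = 30,
) -> float:
    """Alternative readthrough measure: 3'-end density ratio over equal windows.

    Density of footprint 3' ends in ``[stop3 + min_downstream, stop3 +
    min_downstream + window)`` over density in the equal-width reference
    window ending at the termination signature (offset +12), which captures
    terminating ends.  Returns NaN when the reference window is empty.
    """
    s3 = call.stop_start + 2
    up = down = 0
    for r in rpfs:
        if r.transcript_id != call.transcript_id:
            continue
        o = r.end3 - s3
        if 12 - window < o <= 12:
            up += 1
        elif min_downstream <= o < min_downstream + window:
            down += 1
    return down / up if up else float("nan")


def coverage_track(rpfs: Sequence[RPFRecord], transcript: TranscriptRecord | int) -> np.ndarray:
    """Per-base coverage from all bases of retained footprints."""
    length = transcript if isinstance(transcript, int) else len(transcript.seq)
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in rpfs:
        if r.start < length:
            diff[max(r.start, 0)] += 1
            diff[min(r.end, length)] -= 1
    return np.cumsum(diff[:-1])


def write_metaprofile_tsv(profiles: Sequence[MetaProfile], path: str | Path, rpf_length: str = "all") -> None:
    with open(path, "w") as fh:
        fh.write("offset\tcount\tclass\trpf_length\n")
        for p in profiles:
            for off, n in zip(p.offsets, p.counts):
                fh.write(f"{off}\t{n}\t{p.anchor_class}\t{rpf_length}\n")


def write_readthrough_tsv(estimates: Sequence[ReadthroughEstimate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tn_stop_rpfs\tn_downstream_rpfs\trate\tcovered\n")
        for e in estimates:
            fh.write(
                f"{e.transcript_id}\t{e.n_stop_rpfs}\t{e.n_downstream_rpfs}\t{e.rate:.6g}\t{int(e.covered)}\n"
            )
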