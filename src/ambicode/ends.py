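"""Poly(A)-anchored transcript-end analysis.

For genetic codes in which "stop" triplets are also sense codons,
termination is diagnosed from transcript geometry rather than from the
table: the *primary stop* is the most 5' in-frame candidate stop codon
within the 60-nt window upstream of the poly(A) site, 3'UTR length is
measured from the primary stop excluding the stop codon and the tail, and
codon composition is profiled position-by-position toward the poly(A) site.
Near the tail the final "codon" may be completed with 0, 1, or 2 tail
adenosines to keep the reading frame.

Positional offsets ``d`` are 3-nt bins counting backward from the poly(A)
site: the final (possibly tail-completed) codon is ``d = -3``, the one
before it ``d = -6``, and so on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codes import CODON_INDEX, CODONS, TranscriptRecord

DEFAULT_STOP_SET = frozenset({"TAA", "TAG", "TGA"})
PRIMARY_STOP_WINDOW = 60  # nt upstream of the poly(A) site searched for stops


@dataclass
class PolyACall:
    transcript_id: str
    polya_site: int  # 0-based index of the first tail A
    tail_length: int
    supporting_reads: int = 0


@dataclass
class PrimaryStopCall:
    transcript_id: str
    stop_codon: str
    stop_start: int  # 0-based first base of the stop codon
    utr_length: int  # nt between stop codon end and poly(A) site
    downstream_stops: list[int] = field(default_factory=list)


def detect_polya(
    seq: str,
    min_tail: int = 8,
    max_mismatch: int = 1,
    transcript_id: str = "",
) -> PolyACall | None:
    """Detect a terminal poly(A) tail.

    Scans backward from the 3' end accepting up to ``max_mismatch`` non-A
    bases inside the run, then trims any non-A prefix so the call starts on
    an A.  Returns ``None`` when the trimmed run is shorter than
    ``min_tail``.
    """
    if min_tail < 5:
        raise ValueError("min_tail must be >= 5")
    seq = seq.upper()
    i = len(seq) - 1
    mismatches = 0
    start = len(seq)
    while i >= 0:
        if seq[i] == "A":
            start = i
        else:
            mismatches += 1
            if mismatches > max_mismatch:
                break
        i -= 1
    # trim mismatch prefix: the tail must begin with an A
    while start < len(seq) and seq[start] != "A":
        start += 1
    tail_length = len(seq) - start
    if tail_length < min_tail:
        return None
    return PolyACall(transcript_id, polya_site=start, tail_length=tail_length)


def find_primary_stop(
    transcript: TranscriptRecord,
    polya: PolyACall,
    stop_set: frozenset[str] | set[str] = DEFAULT_STOP_SET,
    window: int = PRIMARY_STOP_WINDOW,
) -> PrimaryStopCall | None:
    """Find the putative primary stop in the window upstream of the tail.

    The primary stop is the most 5' in-frame ``stop_set`` codon whose first
    base lies within ``window`` nt of the poly(A) site; later in-frame
    stop-set codons fully contained before the tail are reported as
    ``downstream_stops``.  Returns ``None`` when the window holds no
    stop-set codon (the transcript is then a 3'UTR-less candidate only if a
    stop sits immediately at the tail, which does yield a call with
    ``utr_length`` 0).
    """
    if transcript.frame is None:
        raise ValueError(
            f"{transcript.id}: reading frame unknown; run frame inference or "
            "supply CDS annotation first"
        )
    if not stop_set:
        raise ValueError("stop_set must be nonempty")
    seq = transcript.seq.upper()
    p = polya.polya_site
    lo = max(transcript.frame, p - window)
    # in-frame positions congruent to frame mod 3; positions overlapping or
    # just past the called poly(A) site are allowed (codons completed with
    # tail A's): a UAA stop whose adenosines merge into the called tail, or
    # one preceded by templated A's swallowed by the tail call, is still a
    # stop, although which adenosines are templated is then ambiguous
    run = 0
    while p + run < len(seq) and seq[p + run] == "A":
        run += 1
    first = lo + ((transcript.frame - lo) % 3)
    hits = []
    for s in range(first, min(p + run + 3, len(seq)), 3):
        codon = seq[s : s + 3]
        if len(codon) < 3:
            codon = codon + "A" * (3 - len(codon))
        if codon in stop_set:
            hits.append((s, codon))
    if not hits:
        return None
    stop_start, stop_codon = hits[0]
    return PrimaryStopCall(
        transcript_id=transcript.id,
        stop_codon=stop_codon,
        stop_start=stop_start,
        utr_length=max(0, p - (stop_start + 3)),
        downstream_stops=[s for s, _ in hits[1:]],
    )


def primary_stops_from_annotation(
    transcripts: Iterable[TranscriptRecord],
) -> list[PrimaryStopCall]:
    """Primary-stop calls taken directly from CDS annotations.

    The annotated CDS includes its stop codon, so the primary stop is the
    final annotated codon; UTR length is measured to the annotated poly(A)
    site when present, else to the sequence end.  Preferred over
    :func:`find_primary_stop` whenever trusted annotations exist, since the
    sequence-only caller can be preempted by an upstream in-frame sense
    "stop" codon under ambiguous codes.
    """
    calls = []
    for tr in transcripts:
        if not tr.has_cds:
            continue
        stop_start = tr.cds_end - 3
        p = tr.polya_site if tr.polya_site is not None else len(tr.seq)
        calls.append(
            PrimaryStopCall(
                transcript_id=tr.id,
                stop_codon=tr.seq[stop_start : tr.cds_end],
                stop_start=stop_start,
                utr_length=max(0, p - tr.cds_end),
            )
        )
    return calls


@dataclass
class UtrSummary:
    n: int
    median: float
    q1: float
    q3: float
    fraction_zero: float
    histogram: dict[int, int]


def utr_length_distribution(calls: Sequence[PrimaryStopCall]) -> UtrSummary:
    """Median/quartiles and 1-nt histogram of 3'UTR lengths."""
    if not calls:
        raise ValueError("no primary-stop calls supplied")
    lengths = np.array([c.utr_length for c in calls])
    hist = Counter(int(x) for x in lengths)
    return UtrSummary(
        n=len(lengths),
        median=float(np.median(lengths)),
        q1=float(np.percentile(lengths, 25)),
        q3=float(np.percentile(lengths, 75)),
        fraction_zero=float((lengths == 0).mean()),
        histogram=dict(sorted(hist.items())),
    )


@dataclass
class PositionalCodonCounts:
    """Codon counts per 3-nt bin upstream of the poly(A) site.

    ``counts`` is a DataFrame indexed by ``d`` (-3, -6, ...) with one column
    per codon; ``tail_completion_used[b]`` counts final codons that borrowed
    ``b`` tail nucleotides.
    """

    counts: pd.DataFrame
    n_transcripts: int
    tail_completion_used: dict[int, int]

    def total_by_bin(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _backward_codons(tr: TranscriptRecord, polya_site: int, window: int):
    """Yield (d, codon, borrowed) walking in-frame codons back from the tail."""
    frame = tr.frame
    start_bound = tr.cds_start if tr.cds_start is not None else frame
    span = polya_site - start_bound
    if span < 1:
        return
    borrow = (3 - span % 3) % 3
    d = -3
    pos = polya_site - (3 - borrow) if borrow else polya_site - 3
    first = True
    while pos >= start_bound and -d <= window:
        if first and borrow:
            # complete the final codon with tail adenosines (whether or not
            # the assembled sequence retains the tail downstream of polya)
            codon = tr.seq[pos:polya_site] + "A" * borrow
        else:
            codon = tr.seq[pos : pos + 3]
        yield d, codon.upper(), borrow if first else 0
        first = False
        d -= 3
        pos -= 3


def positional_codon_counts(
    items: Iterable[tuple[TranscriptRecord, PolyACall]],
    window: int = 240,
    query_codons: Iterable[str] | None = None,
) -> PositionalCodonCounts:
    """Count in-frame codons per 3-nt bin walking back from the poly(A) site.

    The final codon may borrow 0/1/2 tail A's to complete a triplet;
    transcripts shorter than the window contribute only their covered bins.
    ``query_codons`` restricts the *columns retained*, never the totals used
    elsewhere (all 64 are always counted).
    """
    n_bins = window // 3
    bins = [-3 * (k + 1) for k in range(n_bins)]
    mat = np.zeros((n_bins, 64), dtype=np.int64)
    completion: Counter[int] = Counter()
    n_transcripts = 0
    for tr, polya in items:
        n_transcripts += 1
        for d, codon, borrowed in _backward_codons(tr, polya.polya_site, window):
            idx = CODON_INDEX.get(codon)
            if idx is None:
                continue
            mat[(-d // 3) - 1, idx] += 1
            if d == -3:
                completion[borrowed] += 1
    df = pd.DataFrame(mat, index=pd.Index(bins, name="d"), columns=list(CODONS))
    if query_codons is not None:
        df = df.loc[:, [c for c in CODONS if c in set(query_codons)]]
    return PositionalCodonCounts(df, n_transcripts, dict(completion))


@dataclass
class DepletionReport:
    codon: str
    proximal_count: int
    proximal_total: int
    distal_count: int
    distal_total: int
    proximal_rate: float
    distal_rate: float
    ratio: float
    p_value: float


def _bin_mask(index: pd.Index, lo: int, hi: int) -> np.ndarray:
    return (index.values >= lo) & (index.values < hi)


def stop_depletion_test(
    counts: PositionalCodonCounts,
    codon: str,
    proximal: tuple[int, int] = (-90, -42),
    distal: tuple[int, int] | None = None,
) -> DepletionReport:
    """Proximal-vs-distal depletion contrast for one codon.

    Computes the codon's frequency (codon count / all-codon count) in the
    proximal window (default the coding-side −90..−42 region, upstream of
    the −39-nt boundary where UTR "codons" and stops take over) and in a
    distal reference (default: everything at ``d < -240`` present in the
    table), then a two-sided binomial test of the proximal count against the
    distal frequency.
    """
    if codon not in CODON_INDEX:
        raise ValueError(f"invalid codon {codon!r}")
    df = counts.counts
    idx = df.index
    prox_mask = _bin_mask(idx, proximal[0], proximal[1])
    if distal is None:
        dist_mask = idx.values < -240
    else:
        dist_mask = _bin_mask(idx, distal[0], distal[1])
    if not prox_mask.any() or not dist_mask.any():
        raise ValueError("empty proximal or distal range for depletion test")
    if (prox_mask & dist_mask).any():
        raise ValueError("proximal and distal ranges must be disjoint")
    totals = df.sum(axis=1).to_numpy()
    col = df[codon].to_numpy()
    px, pn = int(col[prox_mask].sum()), int(totals[prox_mask].sum())
    dx, dn = int(col[dist_mask].sum()), int(totals[dist_mask].sum())
    if pn == 0 or dn == 0:
        raise ValueError("no codon observations in proximal or distal range")
    prate, drate = px / pn, dx / dn
    ratio = prate / drate if drate > 0 else float("nan")
    p_value = (
        float(stats.binomtest(px, pn, drate, alternative="two-sided").pvalue)
        if drate > 0
        else 1.0
    )
    return DepletionReport(codon, px, pn, dx, dn, prate, drate, ratio, p_value)


@dataclass
class BaseFrequencyProfile:
    """Per-nt A/C/G/T frequencies upstream of the poly(A) site.

    ``frequencies`` is indexed by nt offset (−1 is the base just before the
    tail) with columns A/C/G/T; ``flatness`` is the maximum absolute
    deviation of each base from its mean frequency across the stated stable
    region.
    """

    frequencies: pd.DataFrame
    coverage: pd.Series
    flatness: dict[str, float]
    stable_region: tuple[int, int]


def base_frequency_profile(
    items: Iterable[tuple[TranscriptRecord, PolyACall]],
    window: int = 240,
    stable_region: tuple[int, int] = (-90, -42),
) -> BaseFrequencyProfile:
    bases = "ACGT"
    counts = np.zeros((window, 4), dtype=np.int64)
    for tr, polya in items:
        p = polya.polya_site
        lo = max(0, p - window)
        segment = tr.seq[lo:p].upper()
        for offset_from_p, base in zip(range(-(p - lo), 0), segment):
            j = bases.find(base)
            if j >= 0:
                counts[window + offset_from_p, j] += 1
    offsets = np.arange(-window, 0)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        freqs = np.where(totals[:, None] > 0, counts / np.maximum(totals, 1)[:, None], np.nan)
    df = pd.DataFrame(freqs, index=pd.Index(offsets, name="offset"), columns=list(bases))
    region = df.loc[(df.index >= stable_region[0]) & (df.index < stable_region[1])]
    flatness = {
        b: float(np.nanmax(np.abs(region[b] - np.nanmean(region[b])))) if len(region) else float("nan")
        for b in bases
    }
    return BaseFrequencyProfile(df, pd.Series(totals, index=df.index), flatness, stable_region)


def write_positional_counts_tsv(counts: PositionalCodonCounts, path: str | Path) -> None:
    long = counts.counts.stack()
    long = long[long > 0]
    out = long.reset_index()
    out.columns = ["d", "codon", "count"]
    out.to_csv(path, sep="\t", index=False)


def write_primary_stop_calls_tsv(calls: Sequence[PrimaryStopCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tstop_codon\tstop_start\tutr_length\tn_downstream_stops\n")
        for c in calls:
            fh.write(
                f"{c.transcript_id}\t{c.stop_codon}\t{c.stop_start}\t{c.utr_length}\t{len(c.downstream_stops)}\n"
            )
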