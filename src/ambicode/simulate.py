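"""Ground-truth simulator for every stage of the pipeline.

Emulates the statistical structure of a poly(A)-selected ciliate
transcriptome with a (possibly ambiguous) genetic code, together with the
two derived data layers the pipeline consumes: profile-alignment records
and ribosome footprints.

Each transcript is laid out as::

    leader | ATG | family codons | stop | 3'UTR | poly(A) tail

* coding sequences follow a protein family's consensus, with per-column
  conservation controlling substitution;
* reassigned "stop" codons (e.g. TAA/TAG=Q, TGA=W) appear as sense codons
  at a configured low usage, optionally suppressed by a depletion factor in
  a window upstream of the poly(A) site;
* 3'UTRs are AU-rich and very short (zero-inflated, median ~22 nt), with
  in-frame downstream stops roughly every six codons;
* footprints are 25–32 nt; terminating footprints place 3' ends 11/12 nt
  past the stop codon's last base, readthrough footprints extend >=13 nt
  beyond and terminate at the next downstream stop.

A single integer seed drives all stages through deterministically spawned
substreams, so the same config always yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.special import ndtri

from .codes import (
    AMINO_ACIDS,
    BUILTIN_CODES,
    CODON_INDEX,
    CODONS,
    GeneticCodeTable,
    STOP,
    TranscriptRecord,
    get_code,
)
from .inference import RECORD_COLUMNS
from .riboseq import RPFRecord

_NUCS = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for the simulator (all stages).

    Defaults emulate the heterotrich/karyorelict setting: an ambiguous
    genetic code, reassigned-codon sense usage at the top of the observed
    0.05–0.15% range, median-22-nt AU-rich 3'UTRs including 0-length ones,
    25–32 nt footprints with 11/12-nt termination offsets.
    """

    seed: int = 0
    code: str = "ambiguous-cmag"
    # protein families (enough that positional windows see mostly distinct
    # profile columns, as in a transcriptome-scale domain screen)
    n_families: int = 200
    family_length: int = 160  # codons between the start and stop codon
    conserved_fraction: float = 0.8
    conservation_conserved: tuple[float, float] = (0.55, 0.95)
    conservation_other: tuple[float, float] = (0.2, 0.45)
    # transcriptome
    n_transcripts: int = 2000
    stop_sense_usage: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.0015, "TAG": 0.0015, "TGA": 0.0015}
    )
    utr_median: float = 22.0
    utr_sigma: float = 0.18
    utr_zero_fraction: float = 0.08
    utr_at_fraction: float = 0.7
    downstream_stop_prob: float = 1.0 / 6.0  # ~5 codons between consecutive stops
    tail_mean: float = 30.0
    tail_min: int = 15
    stop_probs: dict[str, float] = field(
        default_factory=lambda: {"TAA": 0.6, "TAG": 0.2, "TGA": 0.2}
    )
    depletion_factor: float = 1.0  # 1.0 = no proximal suppression
    depletion_window: tuple[int, int] = (-90, -42)
    leader_max: int = 11
    # alignment records
    evalue_above_fraction: float = 0.1
    # footprints
    rpf_length_probs: dict[int, float] = field(
        default_factory=lambda: {25: 0.04, 26: 0.05, 27: 0.08, 28: 0.18, 29: 0.15, 30: 0.30, 31: 0.12, 32: 0.08}
    )
    frame3_bias: float = 0.8
    term_signal_prob: float = 0.9
    readthrough_rate: float = 0.0
    readthrough_zero_fraction: float = 0.0
    stop_depth_mean: float = 40.0
    elong_depth_mean: float = 30.0
    seq_error_rate: float = 0.001

    def code_table(self) -> GeneticCodeTable:
        return get_code(self.code) if isinstance(self.code, str) else self.code

    def validate(self) -> None:
        for name in (
            "conserved_fraction",
            "utr_zero_fraction",
            "utr_at_fraction",
            "downstream_stop_prob",
            "depletion_factor",
            "evalue_above_fraction",
            "frame3_bias",
            "term_signal_prob",
            "readthrough_rate",
            "readthrough_zero_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0 <= u < 0.05 for u in self.stop_sense_usage.values()):
            raise ValueError("stop_sense_usage entries must be small proportions")
        cds_nt = 3 * (self.family_length + 2)
        if -self.depletion_window[0] > cds_nt:
            raise ValueError("depletion window extends beyond the simulated CDS")
        if self.depletion_window[0] >= self.depletion_window[1]:
            raise ValueError("depletion window must be an increasing (lo, hi) pair")
        if abs(sum(self.rpf_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("rpf_length_probs must sum to 1")

    def _streams(self) -> list[np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(3)
        return [np.random.default_rng(c) for c in children]


@dataclass
class GroundTruth:
    """Everything the simulator knows; consistent with the emitted files."""

    code_name: str
    family_consensus: list[str]  # amino-acid strings, one per family
    column_conservation: list[list[float]]
    transcript_ids: list[str]
    family_of: list[int]
    cds_start: list[int]
    cds_end: list[int]  # includes the stop codon
    stop_start: list[int]
    stop_codon: list[str]
    utr_length: list[int]
    tail_length: list[int]
    polya_site: list[int]
    readthrough_rate: list[float]
    column_rotation: list[int] = field(default_factory=list)  # per-transcript family-column offset
    rpf_classes: list[str] = field(default_factory=list)  # parallel to emitted reads

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _codon_weights(code: GeneticCodeTable, usage: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Per-amino-acid codon sampling weights.

    Standard codons of an amino acid get weight 1; a reassigned codon with
    overall target usage u (given 20 equifrequent amino acids) gets
    w = 20 u k / (1 - 20 T), where k is the number of standard codons of its
    amino acid and T the summed targets within that amino acid.
    """
    std = BUILTIN_CODES["standard"]
    reassigned = {
        c: u for c, u in usage.items() if std.mapping[c] == STOP and code.mapping[c] != STOP
    }
    weights: dict[str, np.ndarray] = {}
    for aa in AMINO_ACIDS:
        codons = code.codons_for(aa)
        w = np.ones(len(codons))
        re_here = [c for c in codons if c in reassigned]
        if re_here:
            k = len(codons) - len(re_here)
            T = sum(reassigned[c] for c in re_here)
            for c in re_here:
                w[codons.index(c)] = 20.0 * reassigned[c] * k / max(1.0 - 20.0 * T, 1e-9)
        weights[aa] = w / w.sum()
    return weights


def _random_au_rich(rng: np.random.Generator, n: int, at_fraction: float) -> str:
    at = at_fraction / 2.0
    gc = (1.0 - at_fraction) / 2.0
    idx = rng.choice(4, size=n, p=[at, gc, gc, at])
    return "".join(_NUCS[i] for i in idx)


def _draw_utr_lengths(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    z = cfg.utr_zero_fraction
    # continuous-median calibration so the zero-inflated mixture has the
    # configured median despite the point mass at 0
    target_q = (0.5 - z) / (1.0 - z)
    mu = np.log(cfg.utr_median) - cfg.utr_sigma * ndtri(target_q)
    lengths = np.maximum(1, np.rint(rng.lognormal(mu, cfg.utr_sigma, size=n))).astype(int)
    zero = rng.random(n) < z
    lengths[zero] = 0
    return lengths


def _stop_choices(code: GeneticCodeTable, stop_probs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    available = [c for c in ("TAA", "TAG", "TGA") if c in code.termination_set]
    if not available:
        raise ValueError(f"code {code.name!r} has no terminating codon")
    p = np.array([stop_probs.get(c, 0.0) for c in available], dtype=float)
    if p.sum() <= 0:
        p = np.ones(len(available))
    return available, p / p.sum()


def simulate_transcriptome(cfg: SimConfig) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Simulate the transcriptome; returns records plus ground truth."""
    cfg.validate()
    rng = cfg._streams()[0]
    code = cfg.code_table()
    n, F = cfg.n_transcripts, cfg.family_length

    # families: consensus amino acids and per-column conservation
    cons_aa = rng.integers(0, 20, size=(cfg.n_families, F))
    conserved = rng.random((cfg.n_families, F)) < cfg.conserved_fraction
    lo_c, hi_c = cfg.conservation_conserved
    lo_o, hi_o = cfg.conservation_other
    conservation = np.where(
        conserved,
        rng.uniform(lo_c, hi_c, size=(cfg.n_families, F)),
        rng.uniform(lo_o, hi_o, size=(cfg.n_families, F)),
    )

    fam = np.arange(n) % cfg.n_families  # balanced family coverage
    # per-transcript cyclic offset of the family columns: transcript-end
    # windows then sample every profile column uniformly, as they would
    # across genes of varying length, instead of pinning the same conserved
    # columns near every poly(A) site
    rot = rng.integers(0, F, size=n)
    col_of = (np.arange(F)[None, :] + rot[:, None]) % F  # (n, F) family column ids
    rows = np.arange(n)[:, None]
    col_cons = conservation[fam][rows, col_of]  # (n, F)
    col_consensus = cons_aa[fam][rows, col_of]

    # amino acids: consensus kept with per-column conservation probability,
    # otherwise substituted uniformly among the other 19
    keep = rng.random((n, F)) < col_cons
    subs = rng.integers(0, 19, size=(n, F))
    subs = subs + (subs >= col_consensus)  # skip the consensus symbol
    aa = np.where(keep, col_consensus, subs)

    # structural draws
    leaders = rng.integers(0, cfg.leader_max + 1, size=n)
    utr_len = _draw_utr_lengths(rng, cfg, n)
    tails = np.maximum(cfg.tail_min, rng.poisson(cfg.tail_mean, size=n))
    stop_opts, stop_p = _stop_choices(code, cfg.stop_probs)
    stops = rng.choice(len(stop_opts), size=n, p=stop_p)

    # codons for every (transcript, column)
    weights = _codon_weights(code, cfg.stop_sense_usage)
    aa_codon_idx = {
        a: np.array([CODON_INDEX[c] for c in code.codons_for(a)]) for a in AMINO_ACIDS
    }
    codon_idx = np.zeros((n, F), dtype=np.int64)
    for j, a in enumerate(AMINO_ACIDS):
        mask = aa == j
        m = int(mask.sum())
        if m:
            codon_idx[mask] = aa_codon_idx[a][rng.choice(len(aa_codon_idx[a]), size=m, p=weights[a])]

    # proximal suppression of sense-"stop" codons
    sense_stops = [
        c for c in cfg.stop_sense_usage if code.mapping[c] != STOP
    ]
    if sense_stops and cfg.depletion_factor < 1.0:
        sense_idx = np.array([CODON_INDEX[c] for c in sense_stops])
        # first-base offset of column k relative to the poly(A) site
        offs = (leaders[:, None] + 3 + 3 * np.arange(F)[None, :]) - (
            leaders[:, None] + 3 + 3 * F + 3 + utr_len[:, None]
        )
        in_window = (offs >= cfg.depletion_window[0]) & (offs < cfg.depletion_window[1])
        hit = in_window & np.isin(codon_idx, sense_idx) & (
            rng.random((n, F)) >= cfg.depletion_factor
        )
        std_codon_idx = {
            a: np.array(
                [CODON_INDEX[c] for c in code.codons_for(a) if c not in sense_stops]
            )
            for a in AMINO_ACIDS
        }
        for j, a in enumerate(AMINO_ACIDS):
            mask = hit & (aa == j)
            m = int(mask.sum())
            if m and len(std_codon_idx[a]):
                codon_idx[mask] = std_codon_idx[a][rng.integers(0, len(std_codon_idx[a]), size=m)]

    codon_arr = np.array(CODONS)
    transcripts: list[TranscriptRecord] = []
    truth = GroundTruth(
        code_name=code.name,
        family_consensus=["".join(AMINO_ACIDS[i] for i in row) for row in cons_aa],
        column_conservation=[[float(x) for x in row] for row in conservation],
        transcript_ids=[],
        family_of=fam.tolist(),
        cds_start=[],
        cds_end=[],
        stop_start=[],
        stop_codon=[],
        utr_length=utr_len.tolist(),
        tail_length=tails.tolist(),
        polya_site=[],
        readthrough_rate=[],
        column_rotation=rot.tolist(),
    )
    term_set = code.termination_set
    for i in range(n):
        leader = _random_au_rich(rng, int(leaders[i]), cfg.utr_at_fraction)
        body = "".join(codon_arr[codon_idx[i]])
        stop = stop_opts[stops[i]]
        utr = _make_utr(rng, cfg, int(utr_len[i]), stop_opts, stop_p)
        tail = "A" * int(tails[i])
        seq = leader + "ATG" + body + stop + utr + tail
        cds_start = int(leaders[i])
        cds_end = cds_start + 3 + 3 * F + 3
        tid = f"tx{i:05d}"
        transcripts.append(
            TranscriptRecord(
                id=tid,
                seq=seq,
                cds_start=cds_start,
                cds_end=cds_end,
                polya_site=len(seq) - int(tails[i]),
            )
        )
        truth.transcript_ids.append(tid)
        truth.cds_start.append(cds_start)
        truth.cds_end.append(cds_end)
        truth.stop_start.append(cds_end - 3)
        truth.stop_codon.append(stop)
        truth.polya_site.append(len(seq) - int(tails[i]))
    return transcripts, truth


def _make_utr(
    rng: np.random.Generator,
    cfg: SimConfig,
    length: int,
    stop_opts: list[str],
    stop_p: np.ndarray,
) -> str:
    if length == 0:
        return ""
    n_codons = (length + 2) // 3
    parts = []
    for _ in range(n_codons):
        if rng.random() < cfg.downstream_stop_prob:
            parts.append(stop_opts[int(rng.choice(len(stop_opts), p=stop_p))])
        else:
            parts.append(_random_au_rich(rng, 3, cfg.utr_at_fraction))
    utr = "".join(parts)[:length]
    # draw the final (up to two) bases from U/C/G: the annotated poly(A)
    # site is then recoverable from sequence alone, emulating transcripts
    # whose untemplated tails are unambiguous against the reference
    at = cfg.utr_at_fraction
    p_ucg = np.array([at, (1 - at) / 2, (1 - at) / 2])
    n_fix = min(2, length)
    tail_safe = "".join("TCG"[i] for i in rng.choice(3, size=n_fix, p=p_ucg))
    return utr[: length - n_fix] + tail_safe


def simulate_alignment_records(
    cfg: SimConfig,
    truth: GroundTruth,
    transcripts: Sequence[TranscriptRecord],
) -> pd.DataFrame:
    """One profile-alignment record per family column per transcript.

    Consensus amino acid and conservation come from the family; the matched
    codon is read from the transcript CDS, so substituted residues carry a
    codon that disagrees with the consensus (the noise the filter and the
    matrix tolerate).  A configured fraction of conditional e-values falls
    above the 1e-10 threshold to exercise the filter.
    """
    rng = cfg._streams()[1]
    F = cfg.family_length
    n = len(transcripts)
    fam = np.asarray(truth.family_of)
    cons_mat = np.asarray(truth.column_conservation)  # (n_families, F)

    tid = np.repeat([tr.id for tr in transcripts], F)
    profile = np.repeat([f"fam{f:03d}" for f in fam], F)
    rot = np.asarray(truth.column_rotation if truth.column_rotation else [0] * n)
    col_of = (np.arange(F)[None, :] + rot[:, None]) % F
    rows = np.arange(n)[:, None]
    column = col_of.reshape(-1)
    consensus_by_family = np.array(
        [np.frombuffer(s.encode(), dtype="S1") for s in truth.family_consensus]
    ).astype("U1")
    consensus = consensus_by_family[fam][rows, col_of].reshape(-1)
    conservation = cons_mat[fam][rows, col_of].reshape(-1)

    bodies = "".join(
        tr.seq[tr.cds_start + 3 : tr.cds_start + 3 + 3 * F] for tr in transcripts
    )
    codons = (
        np.frombuffer(bodies.encode(), dtype="S1").reshape(n * F, 3).view("S3").reshape(-1).astype("U3")
    )

    above = rng.random(n * F) < cfg.evalue_above_fraction
    log_lo, log_hi = -30.0, -11.0
    ev = 10.0 ** rng.uniform(log_lo, log_hi, size=n * F)
    ev_above = 10.0 ** rng.uniform(-9.0, -2.0, size=n * F)
    ev = np.where(above, ev_above, ev)

    frames = np.array([f"+{(tr.cds_start % 3) + 1}" for tr in transcripts])
    return pd.DataFrame(
        {
            "profile_id": profile,
            "transcript_id": tid,
            "frame": np.repeat(frames, F),
            "column_index": column,
            "consensus_aa": consensus,
            "column_conservation": conservation,
            "matched_codon": codons,
            "conditional_evalue": ev,
        },
        columns=list(RECORD_COLUMNS),
    )


@dataclass
class SimulatedRPF:
    read_id: str
    transcript_id: str
    start: int
    end: int
    length: int
    mismatches: int
    true_class: str  # terminating | elongating | readthrough

    def as_record(self) -> RPFRecord:
        return RPFRecord(
            self.read_id, self.transcript_id, self.start, self.end, self.length, self.mismatches
        )


def _next_inframe_stop(seq: str, stop_start: int, polya: int, term_set: frozenset[str]) -> int | None:
    """First in-frame terminating codon strictly downstream of the primary stop
    and fully templated before the tail; None if there is none."""
    for p in range(stop_start + 3, polya - 2, 3):
        if seq[p : p + 3] in term_set:
            return p
    return None


def simulate_rpfs(
    cfg: SimConfig,
    truth: GroundTruth,
    transcripts: Sequence[TranscriptRecord],
) -> list[SimulatedRPF]:
    """Simulate footprints: elongating, terminating, and readthrough classes."""
    rng = cfg._streams()[2]
    code = cfg.code_table()
    term_set = code.termination_set
    lengths = np.array(sorted(cfg.rpf_length_probs))
    length_p = np.array([cfg.rpf_length_probs[l] for l in lengths], dtype=float)
    length_p = length_p / length_p.sum()

    reads: list[SimulatedRPF] = []
    truth.readthrough_rate = []
    truth.rpf_classes = []
    counter = 0
    for i, tr in enumerate(transcripts):
        s3 = truth.stop_start[i] + 2
        polya = truth.polya_site[i]
        seq_len = len(tr.seq)
        ds = _next_inframe_stop(tr.seq, truth.stop_start[i], polya, term_set)
        r_t = 0.0 if rng.random() < cfg.readthrough_zero_fraction else cfg.readthrough_rate
        truth.readthrough_rate.append(float(r_t))

        n_stop = rng.poisson(cfg.stop_depth_mean)
        n_elong = rng.poisson(cfg.elong_depth_mean)

        for _ in range(n_stop):
            is_rt = rng.random() < r_t
            if is_rt:
                anchor3 = ds + 2 if ds is not None else polya + 9
                end3 = anchor3 + (11 if rng.random() < 0.5 else 12)
                cls = "readthrough"
            else:
                if rng.random() < cfg.term_signal_prob:
                    end3 = s3 + (11 if rng.random() < 0.5 else 12)
                else:
                    # imprecise protection: queued/paused ribosomes protect less,
                    # never more, than the terminating geometry (an end beyond
                    # +12 would mean the ribosome translated past the stop)
                    end3 = s3 + int(rng.integers(-30, 11))
                cls = "terminating"
            reads.append(_make_read(rng, cfg, tr, end3, seq_len, lengths, length_p, cls, counter))
            truth.rpf_classes.append(cls)
            counter += 1

        F = (truth.cds_end[i] - truth.cds_start[i]) // 3 - 2
        for _ in range(n_elong):
            k = int(rng.integers(0, F + 1))
            end3 = truth.cds_start[i] + 3 * k + 2  # third base of codon k (frame 3)
            if rng.random() >= cfg.frame3_bias:
                end3 -= int(rng.integers(1, 3))
            reads.append(
                _make_read(rng, cfg, tr, end3, seq_len, lengths, length_p, "elongating", counter)
            )
            truth.rpf_classes.append("elongating")
            counter += 1
    return reads


def _make_read(
    rng: np.random.Generator,
    cfg: SimConfig,
    tr: TranscriptRecord,
    end3: int,
    seq_len: int,
    lengths: np.ndarray,
    length_p: np.ndarray,
    cls: str,
    counter: int,
) -> SimulatedRPF:
    L = int(lengths[rng.choice(len(lengths), p=length_p)])
    end3 = min(max(end3, L - 1), seq_len - 1)
    start = end3 - L + 1
    n_mm = int(rng.binomial(L, cfg.seq_error_rate))
    return SimulatedRPF(
        read_id=f"rpf{counter:07d}",
        transcript_id=tr.id,
        start=start,
        end=end3 + 1,
        length=L,
        mismatches=n_mm,
        true_class=cls,
    )


def write_sam(
    reads: Sequence[SimulatedRPF],
    transcripts: Sequence[TranscriptRecord],
    path: str | Path,
    rng: np.random.Generator | None = None,
) -> None:
    """Write simulated footprints as SAM against the transcript references.

    Read sequences are taken from the reference with ``mismatches`` random
    substitutions (positions drawn from ``rng``, or deterministically spaced
    when no generator is given); the edit distance is stored in the NM tag.
    """
    by_id = {tr.id: tr for tr in transcripts}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": tr.id, "LN": len(tr.seq)} for tr in transcripts],
    }
    ref_index = {tr.id: k for k, tr in enumerate(transcripts)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            ref = by_id[r.transcript_id].seq
            seq = list(ref[r.start : r.end])
            if r.mismatches:
                if rng is not None:
                    pos = rng.choice(r.length, size=min(r.mismatches, r.length), replace=False)
                else:
                    step = max(1, r.length // (r.mismatches + 1))
                    pos = range(step - 1, r.length, step)
                    pos = list(pos)[: r.mismatches]
                for p in pos:
                    orig = seq[p]
                    seq[p] = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[orig]
            a = pysam.AlignedSegment()
            a.query_name = r.read_id
            a.query_sequence = "".join(seq)
            a.flag = 0
            a.reference_id = ref_index[r.transcript_id]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigarstring = f"{r.length}M"
            a.set_tag("NM", r.mismatches)
            out.write(a)


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete small test bundle: FASTA, record TSV, SAM, truth JSON."""
    from .codes import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = simulate_transcriptome(cfg)
    records = simulate_alignment_records(cfg, truth, transcripts)
    reads = simulate_rpfs(cfg, truth, transcripts)
    paths = {
        "fasta": outdir / "transcripts.fasta",
        "records": outdir / "alignment_records.tsv",
        "sam": outdir / "rpfs.sam",
        "truth": outdir / "ground_truth.json",
    }
    write_fasta(transcripts, paths["fasta"])
    records.to_csv(paths["records"], sep="\t", index=False)
    write_sam(reads, transcripts, paths["sam"])
    truth.to_json(paths["truth"])
    return paths
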