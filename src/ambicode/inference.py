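"""Genetic-code prediction from profile-alignment records.

The method: translate transcripts in all six frames with the standard code
(stops recorded as "X"), align protein-family profiles against the
translations, and for well-conserved profile columns record the aligned
(consensus amino acid, underlying codon) pair.  Records are filtered at a
conditional e-value < 1e-10 and column conservation >= 50%; the surviving
pairs are accumulated into a 64x20 count matrix ``m[i, j]`` (codon i, amino
acid j).  For each codon the maximal-share amino acid is its predicted
meaning; a reassigned stop codon shows up as a codon whose column is
dominated by a sense amino acid (e.g. TAG by Q, TGA by W).

Two normalizations of ``m`` are kept: *per amino acid* (each column scaled
by its total — the form exported for sequence logos) and *per codon* (each
row scaled by its total — the shares used for calling, since per-amino-acid
scaling distorts comparisons for codons of abundant amino acids).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .codes import AA_INDEX, AMINO_ACIDS, CODON_INDEX, CODONS, GeneticCodeTable, STOP

RECORD_COLUMNS = (
    "profile_id",
    "transcript_id",
    "frame",
    "column_index",
    "consensus_aa",
    "column_conservation",
    "matched_codon",
    "conditional_evalue",
)

UNASSIGNED = "UNASSIGNED"

DEFAULT_EVALUE_MAX = 1e-10
DEFAULT_CONSERVATION_MIN = 0.5


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    rejects: dict[str, int] = field(default_factory=dict)


def filter_records(
    records: pd.DataFrame,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    conservation_min: float = DEFAULT_CONSERVATION_MIN,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the two alignment filters plus codon sanity checks.

    A record is retained iff ``conditional_evalue < evalue_max`` (strict),
    ``column_conservation >= conservation_min`` (inclusive), and the matched
    codon is a valid N-free triplet.  Rejects are counted by reason, never
    silently dropped.
    """
    if evalue_max <= 0 or conservation_min <= 0:
        raise ValueError("thresholds must be positive")
    ev = pd.to_numeric(records["conditional_evalue"], errors="coerce")
    cons = pd.to_numeric(records["column_conservation"], errors="coerce")
    codon_ok = records["matched_codon"].isin(CODONS)

    malformed = ev.isna() | cons.isna() | (ev < 0) | (cons < 0) | (cons > 1)
    bad_codon = ~codon_ok & ~malformed
    fail_ev = ~malformed & codon_ok & ~(ev < evalue_max)
    fail_cons = ~malformed & codon_ok & (ev < evalue_max) & ~(cons >= conservation_min)
    keep = ~malformed & codon_ok & (ev < evalue_max) & (cons >= conservation_min)

    report = FilterReport(
        n_input=len(records),
        n_retained=int(keep.sum()),
        rejects={
            "malformed": int(malformed.sum()),
            "codon_invalid_or_N": int(bad_codon.sum()),
            "evalue": int(fail_ev.sum()),
            "conservation": int(fail_cons.sum()),
        },
    )
    return records.loc[keep].reset_index(drop=True), report


@dataclass
class CodonAminoMatrix:
    """The 64x20 aligned-pair count matrix and its normalized form.

    ``counts[i, j]`` is the number of filtered records pairing codon
    ``CODONS[i]`` with consensus amino acid ``AMINO_ACIDS[j]``.
    """

    counts: np.ndarray
    normalized: np.ndarray | None = None
    normalization_mode: str | None = None
    n_rejected_aa: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def codon_support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def accumulate_matrix(records: pd.DataFrame) -> CodonAminoMatrix:
    """Accumulate filtered records into the 64x20 count matrix.

    Records whose consensus amino acid is not one of the 20 standard symbols
    (e.g. "X" from a stop-containing frame) are rejected and counted.
    """
    codon_idx = records["matched_codon"].map(CODON_INDEX)
    aa_idx = records["consensus_aa"].map(AA_INDEX)
    ok = codon_idx.notna() & aa_idx.notna()
    flat = codon_idx[ok].astype(int).to_numpy() * 20 + aa_idx[ok].astype(int).to_numpy()
    counts = np.bincount(flat, minlength=64 * 20).reshape(64, 20)
    return CodonAminoMatrix(counts=counts, n_rejected_aa=int((~ok).sum()))


def normalize_matrix(matrix: CodonAminoMatrix, mode: str = "per_amino_acid") -> CodonAminoMatrix:
    """Normalize the count matrix.

    ``per_amino_acid`` divides each amino-acid column by its total
    (M = m_ij / sum_i m_ij, the logo form); ``per_codon`` divides each codon
    row by its total (the shares used for code calls).  Zero marginals give
    zero rows/columns, never NaN.
    """
    counts = matrix.counts.astype(float)
    if mode == "per_amino_acid":
        denom = counts.sum(axis=0, keepdims=True)
    elif mode == "per_codon":
        denom = counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(denom > 0, counts / np.where(denom > 0, denom, 1.0), 0.0)
    return CodonAminoMatrix(
        counts=matrix.counts,
        normalized=norm,
        normalization_mode=mode,
        n_rejected_aa=matrix.n_rejected_aa,
    )


@dataclass
class CodonCall:
    codon: str
    call: str  # amino-acid symbol or UNASSIGNED
    support: int
    top_fraction: float
    runner_up: str | None
    runner_up_fraction: float


@dataclass
class GeneticCodePrediction:
    calls: list[CodonCall]
    min_support: int
    ambiguity_margin: float

    def as_dict(self) -> dict[str, CodonCall]:
        return {c.codon: c for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": [c.codon for c in self.calls],
                "call": [c.call for c in self.calls],
                "support": [c.support for c in self.calls],
                "top_fraction": [c.top_fraction for c in self.calls],
                "runner_up": [c.runner_up or "" for c in self.calls],
                "runner_up_fraction": [c.runner_up_fraction for c in self.calls],
            }
        )


def predict_code(
    matrix: CodonAminoMatrix,
    min_support: int = 10,
    ambiguity_margin: float = 0.1,
) -> GeneticCodePrediction:
    """Call one amino acid per codon from per-codon shares.

    A codon is called as its maximal-share amino acid when its total support
    is at least ``min_support`` and the top share exceeds the runner-up by at
    least ``ambiguity_margin``; otherwise it is UNASSIGNED (ties included).
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not 0 <= ambiguity_margin < 1:
        raise ValueError("ambiguity_margin must be in [0, 1)")
    counts = matrix.counts
    support = counts.sum(axis=1)
    calls: list[CodonCall] = []
    for i, codon in enumerate(CODONS):
        tot = int(support[i])
        if tot == 0:
            calls.append(CodonCall(codon, UNASSIGNED, 0, 0.0, None, 0.0))
            continue
        shares = counts[i] / tot
        order = np.argsort(shares, kind="stable")[::-1]
        top, second = order[0], order[1]
        top_f, second_f = float(shares[top]), float(shares[second])
        call = AMINO_ACIDS[top]
        if tot < min_support or (top_f - second_f) < ambiguity_margin:
            call = UNASSIGNED
        calls.append(
            CodonCall(codon, call, tot, top_f, AMINO_ACIDS[second], second_f)
        )
    return GeneticCodePrediction(calls, min_support, ambiguity_margin)


def compare_to_code(prediction: GeneticCodePrediction, code: GeneticCodeTable) -> list[str]:
    """Codons where the prediction disagrees with a reference table.

    A sense codon must be called as its table amino acid; a codon that is a
    stop in the reference (never observed as sense) must be UNASSIGNED.
    """
    mismatches = []
    for call in prediction.calls:
        true = code.mapping[call.codon]
        expected = UNASSIGNED if true == STOP else true
        if call.call != expected:
            mismatches.append(call.codon)
    return mismatches


def export_logo_matrix(matrix: CodonAminoMatrix, path: str | Path) -> None:
    """Write the normalized matrix as TSV: 64 codon rows (TCAG-major order),
    header row of amino-acid symbols.  Suitable input for a logo renderer."""
    if matrix.normalized is None:
        raise ValueError("normalize_matrix must be applied before export")
    df = pd.DataFrame(matrix.normalized, index=list(CODONS), columns=list(AMINO_ACIDS))
    df.index.name = "codon"
    df.to_csv(path, sep="\t", float_format="%.12g")


def load_logo_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="codon")


def read_records_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"matched_codon": str, "consensus_aa": str})
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record TSV missing columns: {sorted(missing)}")
    return df


def write_records_tsv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, list(RECORD_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_prediction(prediction: GeneticCodePrediction, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    df = prediction.to_frame()
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if json_path is not None:
        import json

        payload = {
            "min_support": prediction.min_support,
            "ambiguity_margin": prediction.ambiguity_margin,
            "calls": df.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def records_from_pyhmmer(
    hmms,
    transcripts,
    column_conservation: dict[str, "np.ndarray"] | None = None,
) -> pd.DataFrame:
    """Ingestion adapter: build alignment records with pyhmmer.

    Searches each profile HMM against the six-frame standard-code
    translations (stops as "X") of ``transcripts`` and emits one record per
    aligned match-state residue, with the codon read back from the
    transcript.  Column conservation is taken from
    ``column_conservation[hmm_name][column]`` when supplied, else from the
    profile's maximal match-state emission probability — a proxy for the
    modal-residue frequency of the seed alignment column.

    Requires the optional :mod:`pyhmmer` dependency.
    """
    import pyhmmer
    from .codes import BUILTIN_CODES, revcomp, six_frame_translate

    std = BUILTIN_CODES["standard"]
    alphabet = pyhmmer.easel.Alphabet.amino()

    frame_keys = ("+1", "+2", "+3", "-1", "-2", "-3")
    digital: list[pyhmmer.easel.DigitalSequence] = []
    frames_by_name: dict[str, tuple[str, str, int]] = {}
    for tr in transcripts:
        frames = six_frame_translate(tr.seq, std, stops_as_x=True)
        for key in frame_keys:
            if key not in frames:
                continue
            name = f"{tr.id}|{key}"
            seq = pyhmmer.easel.TextSequence(name=name.encode(), sequence=frames[key])
            digital.append(seq.digitize(alphabet))
            frames_by_name[name] = (tr.id, key, len(tr.seq))
    tr_seq = {tr.id: tr.seq for tr in transcripts}

    def _name(x) -> str:
        return x.decode() if isinstance(x, bytes) else str(x)

    rows = []
    for hits in pyhmmer.hmmsearch(hmms, digital):
        hmm_name = _name(hits.query.name)
        query = hits.query
        cons_vec = None
        if column_conservation is not None and hmm_name in column_conservation:
            cons_vec = np.asarray(column_conservation[hmm_name], dtype=float)
        else:
            # match_emissions row 0 is the begin state; columns are 1-based
            em = np.asarray(getattr(query, "match_emissions", None))
            if em is not None and em.ndim == 2 and em.shape[0] > 1:
                cons_vec = em[1:].max(axis=1)
        for hit in hits:
            for dom in hit.domains:
                ali = dom.alignment
                name = _name(hit.name)
                tr_id, frame_key, tr_len = frames_by_name[name]
                hmm_col = ali.hmm_from  # 1-based profile column
                aa_pos = ali.target_from - 1  # 0-based residue index in the frame
                for hmm_char, tgt_char in zip(ali.hmm_sequence, ali.target_sequence):
                    is_match = hmm_char != "."
                    is_residue = tgt_char != "-"
                    if is_match and is_residue:
                        strand, k = frame_key[0], int(frame_key[1]) - 1
                        nt_start = k + 3 * aa_pos
                        if strand == "+":
                            codon = tr_seq[tr_id][nt_start : nt_start + 3]
                        else:
                            codon = revcomp(tr_seq[tr_id])[nt_start : nt_start + 3]
                        cons = (
                            float(cons_vec[hmm_col - 1])
                            if cons_vec is not None and hmm_col - 1 < len(cons_vec)
                            else float("nan")
                        )
                        rows.append(
                            (
                                hmm_name,
                                tr_id,
                                frame_key,
                                hmm_col,
                                hmm_char.upper(),
                                cons,
                                codon.upper(),
                                float(dom.c_evalue),
                            )
                        )
                    if is_match:
                        hmm_col += 1
                    if is_residue:
                        aa_pos += 1
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))
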