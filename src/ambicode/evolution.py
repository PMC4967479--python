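"""Evolutionary-signal utilities: pairwise NG86 dN/dS, stop-codon-usage
summaries, and 4-fold-degenerate-site base composition.

The dN/dS implementation is Nei–Gojobori (1986) pathway counting with
Jukes–Cantor correction, evaluated under an arbitrary
:class:`~ambicode.codes.GeneticCodeTable` so that synonymy is
reassignment-aware (a TGA=W code scores TGG↔TGA as synonymous).  A ratio
well below 1 on an alignment of orthologs indicates purifying selection,
the signal used to argue that genes with in-frame reassigned "stops" are
functional rather than pseudogenes.

Stop-mutation convention: single-nucleotide changes that create a stop
codon under the supplied table are excluded from site denominators, and
mutational pathways passing through stop codons are excluded from
difference averaging (all pathways are used if every one is blocked).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import permutations
from math import log
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .codes import CODONS, GeneticCodeTable, STOP, TranscriptRecord

_NUCS = "ACGT"


@dataclass
class DndsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float
    dS: float
    ratio: float
    undefined: bool
    n_codons: int


class CodonAlignmentError(ValueError):
    pass


def _check_alignment(seq1: str, seq2: str, code: GeneticCodeTable) -> int:
    if len(seq1) != len(seq2):
        raise CodonAlignmentError("aligned sequences must have equal length")
    if len(seq1) == 0 or len(seq1) % 3 != 0:
        raise CodonAlignmentError("alignment length must be a nonzero multiple of 3")
    for seq in (seq1, seq2):
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon not in CODONS:
                raise CodonAlignmentError(f"invalid codon {codon!r} (gaps must be removed upstream)")
            if code.mapping[codon] == STOP:
                raise CodonAlignmentError(f"internal stop codon {codon!r} under code {code.name!r}")
    return len(seq1) // 3


def _codon_sites(codon: str, code: GeneticCodeTable) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon.

    Each position contributes one site, split by the synonymous fraction of
    its non-stop single-nucleotide changes.
    """
    aa = code.mapping[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            alt_aa = code.mapping[alt]
            if alt_aa == STOP:
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        s += syn / valid if valid else 0.0
    return s, 3.0 - s


def _pair_differences(c1: str, c2: str, code: GeneticCodeTable) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences for a codon pair."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    blocked_results = []
    for order in permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            a1, a2 = code.mapping[cur], code.mapping[nxt]
            if a2 == STOP or a1 == STOP:
                blocked = True
            if a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_results if blocked else results).append((sd, nd))
    chosen = results if results else blocked_results
    sd = sum(r[0] for r in chosen) / len(chosen)
    nd = sum(r[1] for r in chosen) / len(chosen)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    return -0.75 * log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(seq1: str, seq2: str, code: GeneticCodeTable | None = None) -> DndsResult:
    """Pairwise NG86 dN/dS for two gapless in-frame codon sequences.

    Site counts are averaged over the two sequences; differences are
    averaged over mutational pathways; proportions are Jukes–Cantor
    corrected.  The ratio is flagged undefined when dS is 0 (or either
    correction saturates); all components are still returned.
    """
    if code is None:
        from .codes import BUILTIN_CODES

        code = BUILTIN_CODES["standard"]
    seq1, seq2 = seq1.upper(), seq2.upper()
    n_codons = _check_alignment(seq1, seq2, code)
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        s1, n1 = _codon_sites(c1, code)
        s2, n2 = _codon_sites(c2, code)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pair_differences(c1, c2, code)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    undefined = not (dS == dS and dN == dN) or dS == 0.0
    ratio = dN / dS if not undefined else float("nan")
    return DndsResult(N, S, Nd, Sd, pN, pS, dN, dS, ratio, undefined, n_codons)


def read_codon_pair_fasta(path) -> tuple[str, str]:
    """Read a two-sequence aligned FASTA and strip gap-containing codon
    columns, returning the gapless in-frame pair for :func:`ng86_dnds`."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise CodonAlignmentError(f"expected exactly 2 aligned sequences, got {len(records)}")
    s1, s2 = (str(r.seq).upper() for r in records)
    if len(s1) != len(s2) or len(s1) % 3 != 0:
        raise CodonAlignmentError("aligned sequences must have equal length divisible by 3")
    kept1, kept2 = [], []
    for i in range(0, len(s1), 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        kept1.append(c1)
        kept2.append(c2)
    return "".join(kept1), "".join(kept2)


@dataclass
class StopUsageSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    total: int


def stop_codon_usage(
    stop_codons: Iterable[str],
    min_stops: int = 50,
) -> StopUsageSummary | None:
    """TAA/TAG/TGA usage among identified primary stops.

    Accepts an iterable of stop codons (e.g. ``call.stop_codon`` from
    primary-stop calls).  Returns ``None`` when fewer than ``min_stops``
    stops were identified (species excluded from usage comparisons).
    """
    counts = Counter(c.upper() for c in stop_codons)
    bad = set(counts) - {"TAA", "TAG", "TGA"}
    if bad:
        raise ValueError(f"non-stop triplets in input: {sorted(bad)}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no stop codons supplied")
    if total < min_stops:
        return None
    full = {c: counts.get(c, 0) for c in ("TAA", "TAG", "TGA")}
    return StopUsageSummary(full, {c: n / total for c, n in full.items()}, total)


def fourfold_codon_prefixes(code: GeneticCodeTable) -> frozenset[str]:
    """Dinucleotide prefixes whose third position is 4-fold degenerate.

    A third position is 4-fold iff all four substitutions are synonymous
    (and sense) under the supplied code.
    """
    prefixes = set()
    for a in _NUCS:
        for b in _NUCS:
            aas = {code.mapping[a + b + c] for c in _NUCS}
            if len(aas) == 1 and STOP not in aas:
                prefixes.add(a + b)
    return frozenset(prefixes)


@dataclass
class FourfoldComposition:
    fractions: dict[str, float]  # base -> fraction at 4-fold third positions
    n_sites: int


def fourfold_composition(
    transcripts: Iterable[TranscriptRecord],
    code: GeneticCodeTable,
) -> FourfoldComposition:
    """A/C/G/T fractions at 4-fold-degenerate third codon positions.

    Third positions are counted across all annotated CDSs (stop codons and
    N-containing codons never qualify).  Raises when no 4-fold site exists.
    """
    prefixes = fourfold_codon_prefixes(code)
    counts = Counter()
    for tr in transcripts:
        if not tr.has_cds:
            continue
        cds = tr.cds_seq
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if len(codon) == 3 and codon[:2] in prefixes and codon[2] in _NUCS:
                counts[codon[2]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no 4-fold-degenerate sites in the supplied CDSs")
    return FourfoldComposition({b: counts.get(b, 0) / total for b in _NUCS}, total)


@dataclass
class UsageRegression:
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int


def taa_usage_vs_a_regression(
    a_fractions: Sequence[float],
    taa_usages: Sequence[float],
) -> UsageRegression:
    """Linear fit of per-species TAA stop usage against 4-fold-site A fraction.

    The positive relationship across species reflects neutral AT bias
    driving UAA stop preference; slope is tested two-sided against zero.
    """
    if len(a_fractions) != len(taa_usages) or len(a_fractions) < 3:
        raise ValueError("need >= 3 paired species values")
    fit = stats.linregress(np.asarray(a_fractions, float), np.asarray(taa_usages, float))
    return UsageRegression(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(a_fractions),
    )
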