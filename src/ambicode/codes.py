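"""Genetic-code tables, translation, and codon-usage accounting.

Ciliate nuclear genetic codes differ from the standard code by stop-codon
reassignment (UAR=Q, UGA=W, UGA=C, UAR=Y), and two heterotrich/karyorelict
codes are *ambiguous*: every one of the 64 codons can be read as a standard
amino acid, and the same triplets also terminate translation near transcript
ends.  :class:`GeneticCodeTable` therefore distinguishes the codon→symbol
mapping from an ``ambiguous_set`` of context-dependent codons.

Conventions used throughout the package:

* codons are DNA triplets (``TGA`` not ``UGA``); reports may print RNA-style,
* coordinates are 0-based, half-open,
* the stop marker is ``"*"``; ``stops_as_x`` is an explicit translation mode
  (stops recorded as ``"X"``, i.e. "any amino acid"), not a table property,
* codons containing ``N`` translate to ``"X"`` and are excluded from
  codon-usage denominators.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

#: The 64 DNA codons in TCAG-major order (the order used for logo export).
CODONS: tuple[str, ...] = tuple(a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG")
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

_STANDARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class InvalidSequenceError(ValueError):
    """Raised for empty or non-DNA input where a DNA sequence is required."""


@dataclass(frozen=True)
class GeneticCodeTable:
    """A 64-codon → amino-acid/stop mapping, standard or variant.

    Parameters
    ----------
    name:
        Short label (e.g. ``"standard"``, ``"ambiguous-cmag"``).
    mapping:
        Codon → one-letter amino acid or ``"*"`` (stop), for all 64 codons.
    ambiguous_set:
        Codons that are context-dependent: read as sense within coding
        sequence but recognized as stops near the poly(A) tail.  Must map to
        sense symbols in ``mapping``.
    """

    name: str
    mapping: Mapping[str, str]
    ambiguous_set: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.mapping) != set(CODONS):
            raise ValueError("mapping must have exactly the 64 DNA codons as keys")
        bad = {v for v in self.mapping.values() if v != STOP and v not in AA_INDEX}
        if bad:
            raise ValueError(f"invalid amino-acid symbols in mapping: {sorted(bad)}")
        object.__setattr__(self, "mapping", dict(self.mapping))
        object.__setattr__(self, "ambiguous_set", frozenset(self.ambiguous_set))
        not_sense = [c for c in self.ambiguous_set if self.mapping[c] == STOP]
        if not_sense:
            raise ValueError(f"ambiguous_set codons must be sense: {sorted(not_sense)}")

    @property
    def stop_set(self) -> frozenset[str]:
        """Codons that are unconditional stops under this table."""
        return frozenset(c for c, v in self.mapping.items() if v == STOP)

    @property
    def termination_set(self) -> frozenset[str]:
        """All codons that can terminate translation: stops plus ambiguous codons."""
        return self.stop_set | self.ambiguous_set

    def codons_for(self, aa: str) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.mapping[c] == aa)

    def is_stop(self, codon: str) -> bool:
        return self.mapping[codon] == STOP

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "mapping": {c: self.mapping[c] for c in CODONS},
            "ambiguous_set": sorted(self.ambiguous_set),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneticCodeTable":
        payload = json.loads(Path(path).read_text())
        return cls(
            name=payload["name"],
            mapping=payload["mapping"],
            ambiguous_set=frozenset(payload.get("ambiguous_set", ())),
        )


def _variant(name: str, reassign: Mapping[str, str], ambiguous: Iterable[str] = ()) -> GeneticCodeTable:
    mapping = dict(_STANDARD)
    mapping.update(reassign)
    return GeneticCodeTable(name=name, mapping=mapping, ambiguous_set=frozenset(ambiguous))


#: Built-in code tables: the standard code and the ciliate variants
#: (UAR=Q as in oligohymenophoreans/spirotrichs, UGA=W as in Blepharisma,
#: UGA=C as in Euplotes, UAR=Y as in Mesodiniidae) plus the fully ambiguous
#: heterotrich/karyorelict code in which all 64 codons are sense and all
#: three standard stops terminate context-dependently.
BUILTIN_CODES: dict[str, GeneticCodeTable] = {
    "standard": GeneticCodeTable("standard", _STANDARD),
    "uar-q": _variant("uar-q", {"TAA": "Q", "TAG": "Q"}),
    "uga-w": _variant("uga-w", {"TGA": "W"}),
    "uga-c": _variant("uga-c", {"TGA": "C"}),
    "uar-y": _variant("uar-y", {"TAA": "Y", "TAG": "Y"}),
    "ambiguous-cmag": _variant(
        "ambiguous-cmag",
        {"TAA": "Q", "TAG": "Q", "TGA": "W"},
        ambiguous=("TAA", "TAG", "TGA"),
    ),
}


def get_code(name: str) -> GeneticCodeTable:
    try:
        return BUILTIN_CODES[name]
    except KeyError:
        raise KeyError(f"unknown genetic code {name!r}; known: {sorted(BUILTIN_CODES)}") from None


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str) -> None:
    if not seq or len(seq) < 3:
        raise InvalidSequenceError("sequence must have length >= 3")
    if set(seq) - set("ACGTN"):
        raise InvalidSequenceError(
            f"non-DNA characters in sequence: {sorted(set(seq) - set('ACGTN'))}"
        )


def translate(seq: str, code: GeneticCodeTable, stops_as_x: bool = False) -> str:
    """Translate a DNA sequence codon by codon under ``code``.

    Codons containing ``N`` yield ``"X"``.  Stop codons yield ``"X"`` when
    ``stops_as_x`` is set (the six-frame database convention, where a stop is
    recorded as "any amino acid"), else the ``"*"`` marker.
    """
    seq = seq.upper()
    _check_dna(seq)
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = code.mapping[codon]
        if aa == STOP and stops_as_x:
            aa = "X"
        out.append(aa)
    return "".join(out)


def six_frame_translate(seq: str, code: GeneticCodeTable, stops_as_x: bool = True) -> dict[str, str]:
    """Translate all six frames; keys ``+1 +2 +3 -1 -2 -3``.

    Frame ``+k`` is ``translate(seq[k-1:])``; frame ``-k`` is the same on the
    reverse complement.
    """
    seq = seq.upper()
    _check_dna(seq)
    rc = revcomp(seq)
    frames: dict[str, str] = {}
    for k in range(3):
        if len(seq) - k >= 3:
            frames[f"+{k + 1}"] = translate(seq[k:], code, stops_as_x=stops_as_x)
            frames[f"-{k + 1}"] = translate(rc[k:], code, stops_as_x=stops_as_x)
    return frames


@dataclass
class TranscriptRecord:
    """One transcript with optional CDS / poly(A) annotation.

    ``cds_start``/``cds_end`` are 0-based half-open and include the stop
    codon when one is annotated; ``polya_site`` is the index of the first
    untemplated tail adenosine.  ``frame`` is ``cds_start % 3`` when the CDS
    is known.
    """

    id: str
    seq: str
    frame: int | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    polya_site: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.cds_start is not None and self.cds_end is not None:
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError(f"{self.id}: CDS span not a multiple of 3")
            if self.frame is None:
                self.frame = self.cds_start % 3
        if self.polya_site is not None and self.polya_site > len(self.seq):
            raise ValueError(f"{self.id}: polya_site beyond sequence end")
        if (
            self.cds_end is not None
            and self.polya_site is not None
            and self.cds_end > self.polya_site
        ):
            raise ValueError(f"{self.id}: CDS extends past the poly(A) site")

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_end is not None

    @property
    def cds_seq(self) -> str:
        if not self.has_cds:
            raise ValueError(f"{self.id}: no CDS annotation")
        return self.seq[self.cds_start : self.cds_end]


@dataclass
class CodonUsageSummary:
    """Per-codon counts and fractions over in-frame CDS codons."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int
    n_skipped: int = 0

    def fraction(self, codon: str) -> float:
        return self.fractions.get(codon, 0.0)


def codon_usage(transcripts: Iterable[TranscriptRecord]) -> CodonUsageSummary:
    """Count every in-frame codon strictly inside each annotated CDS.

    Transcripts without CDS bounds are skipped (tallied in ``n_skipped``);
    N-containing codons are excluded from the denominator.
    """
    counts: Counter[str] = Counter()
    n_skipped = 0
    for tr in transcripts:
        if not tr.has_cds:
            n_skipped += 1
            continue
        cds = tr.cds_seq
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon in CODON_INDEX:
                counts[codon] += 1
    total = sum(counts.values())
    fractions = {c: n / total for c, n in counts.items()} if total else {}
    return CodonUsageSummary(dict(counts), fractions, total, n_skipped)


def write_codon_usage_tsv(summary: CodonUsageSummary, code: GeneticCodeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tamino_acid\tcount\tfraction\n")
        for codon in CODONS:
            fh.write(
                f"{codon}\t{code.mapping[codon]}\t{summary.counts.get(codon, 0)}\t"
                f"{summary.fractions.get(codon, 0.0):.6g}\n"
            )


def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts from FASTA; wrapped lines tolerated, description preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(TranscriptRecord(id=rec.id, seq=str(rec.seq), description=rec.description))
    return records


def write_fasta(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(tr.seq), id=tr.id, description=tr.description)
        for tr in transcripts
    ]
    SeqIO.write(recs, str(path), "fasta")
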