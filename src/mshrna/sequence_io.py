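"""Alphabet-safe nucleotide sequences, FASTA I/O and synthetic fixtures.

All coordinates in this package are 0-based, half-open. Sequences are
stored uppercase; input is accepted case-insensitively. Ambiguity codes
(including N) are rejected: design output must be synthesizable verbatim.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mshrna")

__all__ = [
    "Alphabet",
    "Topology",
    "NucleotideSequence",
    "SequenceError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "transcribe",
    "make_fixture_transcript",
    "write_tsv",
]


class SequenceError(ValueError):
    """Raised for alphabet violations, empty input and malformed records."""


class Alphabet(enum.Enum):
    DNA = "DNA"
    RNA = "RNA"


class Topology(enum.Enum):
    LINEAR = "LINEAR"
    CIRCULAR = "CIRCULAR"


_LETTERS = {Alphabet.DNA: frozenset("ACGT"), Alphabet.RNA: frozenset("ACGU")}
_COMPLEMENT = {
    Alphabet.DNA: str.maketrans("ACGT", "TGCA"),
    Alphabet.RNA: str.maketrans("ACGU", "UGCA"),
}


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified nucleotide sequence with explicit alphabet and topology.

    CIRCULAR topology is only produced by circularization (template
    construction); parsers always emit LINEAR records.
    """

    id: str
    residues: str
    alphabet: Alphabet
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record '{self.id}': residues must be non-empty")
        allowed = _LETTERS[self.alphabet]
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in allowed:
                raise SequenceError(
                    f"record '{self.id}': invalid alphabet — character {ch!r} at "
                    f"position {pos} is not a valid {self.alphabet.value} residue"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, key: slice) -> str:
        return self.residues[key]


def _revcomp_str(residues: str, alphabet: Alphabet) -> str:
    return residues.translate(_COMPLEMENT[alphabet])[::-1]


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement in the same alphabet (LINEAR only)."""
    if seq.topology is not Topology.LINEAR:
        raise SequenceError("reverse_complement requires LINEAR topology")
    return replace(seq, residues=_revcomp_str(seq.residues, seq.alphabet))


def transcribe(dna: NucleotideSequence) -> NucleotideSequence:
    """Transcribe a DNA *template* strand into RNA.

    The polymerase reads the template 3'->5', so the product is the reverse
    complement of the template with U opposite A. Length is preserved.
    """
    if dna.alphabet is Alphabet.RNA:
        raise SequenceError(f"record '{dna.id}': already RNA, nothing to transcribe")
    rna = _revcomp_str(dna.residues, Alphabet.DNA).replace("T", "U")
    return NucleotideSequence(
        id=f"{dna.id}_transcript", residues=rna, alphabet=Alphabet.RNA
    )


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[NucleotideSequence]:
    """Read a (multi-record) FASTA file into LINEAR NucleotideSequences.

    Residues are uppercased. T/U are normalized to the requested alphabet
    with a logged notice per converted record. Ambiguity codes (N or any
    IUPAC degeneracy) are rejected with the record name and 1-based position
    of the first offending character.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no records found in FASTA input")
    out: list[NucleotideSequence] = []
    for rec in records:
        raw = str(rec.seq).upper()
        for pos, ch in enumerate(raw, start=1):
            if ch == "N":
                raise SequenceError(
                    f"record '{rec.id}': ambiguous base 'N' at position {pos} — "
                    "design targets must be unambiguous"
                )
            if ch not in "ACGTU":
                raise SequenceError(
                    f"record '{rec.id}': invalid alphabet — character {ch!r} "
                    f"at position {pos}"
                )
        if alphabet is Alphabet.RNA:
            normalized = raw.replace("T", "U")
        else:
            normalized = raw.replace("U", "T")
        if normalized != raw:
            logger.info(
                "record '%s': normalized residues to %s alphabet",
                rec.id,
                alphabet.value,
            )
        out.append(
            NucleotideSequence(
                id=rec.id,
                residues=normalized,
                alphabet=alphabet,
                topology=Topology.LINEAR,
            )
        )
    return out


def write_fasta(path: str | Path, seqs: Iterable[NucleotideSequence]) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def make_fixture_transcript(
    length: int, gc_fraction: float, seed: int
) -> NucleotideSequence:
    """Deterministic pseudo-random RNA transcript for tests and demos.

    The realized GC fraction is within 0.05 of ``gc_fraction`` (exact up to
    rounding to a whole number of bases). Identical seed, identical output.
    """
    if length < 23:
        raise SequenceError(
            f"length {length} is too short for any siRNA candidate (minimum 23)"
        )
    if not 0.0 <= gc_fraction <= 1.0:
        raise SequenceError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_gc = int(round(length * gc_fraction))
    bases = np.empty(length, dtype="<U1")
    gc = rng.integers(0, 2, size=n_gc)
    au = rng.integers(0, 2, size=length - n_gc)
    bases[:n_gc] = np.where(gc == 0, "G", "C")
    bases[n_gc:] = np.where(au == 0, "A", "U")
    rng.shuffle(bases)
    return NucleotideSequence(
        id=f"fixture_L{length}_gc{gc_fraction:g}_s{seed}",
        residues="".join(bases),
        alphabet=Alphabet.RNA,
    )


def write_tsv(
    path: str | Path, header: Sequence[str], rows: Iterable[Sequence]
) -> None:
    """Shared TSV report writer: tab-separated, header row, no quoting."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(
            fh, delimiter="\t", quoting=csv.QUOTE_NONE, lineterminator="\n"
        )
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)
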