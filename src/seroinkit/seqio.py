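"""Sequence I/O and translation utilities.

Lightweight FASTA/FASTQ reading, six-frame translation with the standard
genetic code, and longest-ORF detection for going from silk-gland cDNAs to
deduced proteins.  Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X*")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid for the standard genetic code, stops as '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _STANDARD_TABLE.stop_codons})


class FastaFormatError(ValueError):
    """Malformed FASTA/FASTQ input; message names the offending line."""


@dataclass
class SeqRecordLite:
    """One sequence with its identifier and free-text description."""

    id: str
    sequence: str
    description: str = ""
    molecule: str = "dna"  # "dna" or "protein"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class OrfCall:
    """A Met-initiated, stop-terminated open reading frame.

    ``start``/``end`` are nucleotide offsets (half-open, stop codon
    included) on the strand implied by ``frame``: frames 0-2 index the
    input sequence, frames 3-5 its reverse complement.
    """

    start: int
    end: int
    frame: int
    protein: str


def _validate_sequence(seq: str, molecule: str, lineno: int) -> None:
    alphabet = DNA_ALPHABET if molecule == "dna" else PROTEIN_ALPHABET
    for ch in seq:
        if ch in "-.":
            raise FastaFormatError(f"line {lineno}: gap character {ch!r} not allowed")
        if ch not in alphabet:
            raise FastaFormatError(
                f"line {lineno}: illegal {molecule} character {ch!r}"
            )


def read_fasta(path: str | Path, molecule: str = "dna") -> list[SeqRecordLite]:
    """Read a (multi-record) FASTA file into :class:`SeqRecordLite` records.

    Sequences are uppercased and validated against the declared alphabet;
    gap characters are rejected.  Errors report the offending line number.
    """
    if molecule not in ("dna", "protein"):
        raise ValueError(f"molecule must be 'dna' or 'protein', got {molecule!r}")
    records: list[SeqRecordLite] = []
    seen: set[str] = set()
    current: Optional[SeqRecordLite] = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"line {lineno}: empty FASTA header")
                rec_id, _, desc = header.partition(" ")
                if rec_id in seen:
                    raise FastaFormatError(
                        f"line {lineno}: duplicate record id {rec_id!r}"
                    )
                seen.add(rec_id)
                current = SeqRecordLite(rec_id, "", desc, molecule)
                records.append(current)
            else:
                if current is None:
                    raise FastaFormatError(
                        f"line {lineno}: sequence data before first header"
                    )
                chunk = line.strip().upper()
                _validate_sequence(chunk, molecule, lineno)
                current.sequence += chunk
    for rec in records:
        if not rec.sequence:
            raise FastaFormatError(f"record {rec.id!r} has an empty sequence")
    return records


def write_fasta(records: Iterable[SeqRecordLite], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at ``wrap`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            handle.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap):
                handle.write(rec.sequence[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecordLite]:
    """Read FASTQ reads (qualities ignored) as DNA records."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(SeqRecordLite(rec.id, str(rec.seq), rec.description, "dna"))
    return records


def read_sequences(path: str | Path, molecule: str = "dna") -> list[SeqRecordLite]:
    """Read FASTA or FASTQ based on file suffix (.fq/.fastq -> FASTQ)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path, molecule)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cdna: str, frame: int = 0) -> str:
    """Translate ``cdna`` in one of six frames with the standard code.

    Frames 3-5 translate the reverse complement (frame - 3).  Stops are
    rendered ``*``; any codon containing an ambiguous base becomes ``X``;
    a trailing partial codon is dropped.
    """
    if not 0 <= frame <= 5:
        raise ValueError(f"frame must be in 0..5, got {frame}")
    seq = cdna.upper()
    if frame >= 3:
        seq = reverse_complement(seq)
        frame -= 3
    seq = seq[frame:]
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aas.append(CODON_TO_AA.get(seq[i : i + 3], "X"))
    return "".join(aas)


def six_frame_translations(cdna: str) -> list[str]:
    return [translate(cdna, f) for f in range(6)]


def longest_orf(cdna: str) -> Optional[OrfCall]:
    """Longest Met-initiated, stop-terminated ORF over all six frames.

    Ties are broken by lower frame index, then lower start offset.  The
    stop codon is included in the nucleotide span but not in the protein.
    Returns ``None`` when no ORF exists (e.g. 5'-incomplete cDNAs).
    """
    if len(cdna) < 6:
        raise ValueError("cDNA shorter than 6 nt cannot contain an ORF")
    best: Optional[OrfCall] = None
    for frame in range(6):
        offset = frame % 3
        prot = translate(cdna, frame)
        start_aa: Optional[int] = None
        for i, aa in enumerate(prot):
            if aa == "M" and start_aa is None:
                start_aa = i
            elif aa == "*" and start_aa is not None:
                candidate = OrfCall(
                    start=offset + 3 * start_aa,
                    end=offset + 3 * (i + 1),
                    frame=frame,
                    protein=prot[start_aa:i],
                )
                if best is None or len(candidate.protein) > len(best.protein):
                    best = candidate
                start_aa = None
    return best
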