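"""FASTA I/O, six-frame translation and the concatenated database text.

Database protein sequences are joined into one long text
``#D0#D1#...#DN-1#`` separated by ``#`` delimiters so that seed positions
are global integers; a bisect-based lookup recovers (sequence, local
offset).  DNA queries are translated in all six reading frames with the
standard codon table; stop codons become ``'*'`` and are treated as hard
mismatches downstream.  Coordinates are 0-based half-open internally and
converted to 1-based inclusive (strand-signed on DNA) only at output.
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

from .alphabet import DELIMITER_CHAR


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str
    kind: str  # "dna" | "protein"


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a DNA read, as protein."""

    read_id: str
    frame: int  # +1,+2,+3 forward; -1,-2,-3 reverse complement
    protein: str
    dna_length: int


@dataclass
class ConcatenatedDatabase:
    text: str  # "#D0#D1#...#DN-1#"
    offsets: list[int]  # start of each Di in text
    names: list[str]
    lengths: list[int]
    total_residues: int

    def locate(self, pos: int) -> tuple[int, int]:
        """Map a global text position to (sequence index, local offset)."""
        if not 0 <= pos < len(self.text) or self.text[pos] == DELIMITER_CHAR:
            raise IndexError(f"position {pos} is not inside a sequence")
        i = bisect_right(self.offsets, pos) - 1
        return i, pos - self.offsets[i]


_DNA_CHARS = set("ACGTUNRYSWKMBDHV")


def looks_like_dna(seq: str, threshold: float = 0.95) -> bool:
    """Heuristic record-type sniffing: nearly all characters in the DNA
    alphabet (protein sequences contain residues like E, L, F that are not
    nucleotide codes)."""
    if not seq:
        return False
    n = sum(c in "ACGTUN" for c in seq)
    return n / len(seq) >= threshold


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path, kind: str | None = None) -> list[SequenceRecord]:
    """Read FASTA records; ids are the first whitespace token of the header,
    sequences are uppercased.  ``kind`` of None sniffs dna/protein from the
    first record."""
    with _open_maybe_gzip(path) as fh:
        raw = list(SeqIO.parse(fh, "fasta"))
    if not raw:
        raise InputError(f"no FASTA records in {path}")
    records = []
    for rec in raw:
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"record {rec.id!r} has an empty sequence")
        if not rec.id:
            raise InputError("record with empty id")
        k = kind or ("dna" if looks_like_dna(seq) else "protein")
        records.append(SequenceRecord(rec.id, seq, k))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def six_frame_translate(record: SequenceRecord) -> list[TranslatedFrame]:
    """Translate a DNA read in all six frames with the standard codon table.

    Stops are '*'; codons containing N (or other ambiguity) give 'X'.
    Frames −1..−3 are frames +1..+3 of the reverse complement.
    """
    if record.kind != "dna":
        raise InputError(f"six_frame_translate needs a DNA record, got {record.kind}")
    dna = record.seq.replace("U", "T")
    rc = str(Seq(dna).reverse_complement())
    frames = []
    for strand_sign, strand_seq in ((1, dna), (-1, rc)):
        for off in range(3):
            sub = strand_seq[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            protein = str(Seq(sub).translate(table=1)) if sub else ""
            frames.append(
                TranslatedFrame(record.id, strand_sign * (off + 1), protein, len(dna))
            )
    return frames


def to_dna_coords(
    frame: TranslatedFrame, protein_start: int, protein_end: int
) -> tuple[int, int]:
    """Map a protein interval [start, end) on a frame to 1-based inclusive
    DNA coordinates on the original read; reversed (start > end) on minus
    frames, following the BLAST strand convention."""
    if not 0 <= protein_start < protein_end <= len(frame.protein):
        raise ValueError("protein interval out of range for frame")
    off = abs(frame.frame) - 1
    b0 = off + 3 * protein_start  # 0-based first base on the frame's strand
    b1 = off + 3 * protein_end - 1  # 0-based last base
    if frame.frame > 0:
        return b0 + 1, b1 + 1
    n = frame.dna_length
    return n - b0, n - b1


def build_concatenated_database(records) -> ConcatenatedDatabase:
    """Join protein records into the delimiter-separated database text."""
    if not records:
        raise InputError("database must contain at least one sequence")
    parts = [DELIMITER_CHAR]
    offsets, names, lengths = [], [], []
    pos = 1
    for rec in records:
        offsets.append(pos)
        names.append(rec.id)
        lengths.append(len(rec.seq))
        parts.append(rec.seq)
        parts.append(DELIMITER_CHAR)
        pos += len(rec.seq) + 1
    text = "".join(parts)
    return ConcatenatedDatabase(text, offsets, names, lengths, sum(lengths))
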