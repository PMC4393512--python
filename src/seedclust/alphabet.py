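"""Reduced amino acid alphabet: grouping, encoding and seed scoring.

Seeding and clustering operate on a 10-letter reduced alphabet in which
residues with similar substitution behaviour are merged into groups.  A
group's match score is the largest substitution-matrix self-score among its
members, so a window's seed score is the sum of group scores over its
positions.  Final (un)gapped alignment always uses the full 20-letter
alphabet; the reduction only governs seeding, clustering and filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: the 20 standard residues, in the conventional substitution-matrix order
STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: default 10-group partition derived from BLOSUM62
DEFAULT_GROUPS: tuple[frozenset[str], ...] = tuple(
    frozenset(g)
    for g in ("A", "KR", "EDNQ", "C", "G", "H", "ILVM", "FYW", "P", "ST")
)

# sentinel codes appended after the group codes
DELIM = 126  # the '#' database delimiter
UNKNOWN = 127  # anything outside the 20 standard residues (X, B, Z, *, ...)

DELIMITER_CHAR = "#"


class AlphabetError(ValueError):
    """Raised when a grouping does not partition the standard residues."""


def load_matrix(name_or_path: str = "BLOSUM62") -> substitution_matrices.Array:
    """Load a substitution matrix by name (Biopython's set) or from an
    NCBI-layout whitespace-delimited file path."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        return substitution_matrices.read(name_or_path)


@dataclass(frozen=True)
class ReducedAlphabet:
    """A partition of the 20 standard residues into scored groups."""

    groups: tuple[frozenset[str], ...]
    group_of: dict[str, int]
    match_score: tuple[int, ...]
    source_matrix_name: str
    # residue byte -> symbol code, for fast vectorized encoding
    _encode_table: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class ReducedSequence:
    """A sequence encoded as group symbols plus DELIM/UNKNOWN sentinels."""

    symbols: np.ndarray  # uint8, values in {0..n_groups-1, DELIM, UNKNOWN}

    def __len__(self) -> int:
        return len(self.symbols)


def build_reduced_alphabet(
    groups=DEFAULT_GROUPS,
    matrix=None,
    matrix_name: str = "BLOSUM62",
) -> ReducedAlphabet:
    """Build a :class:`ReducedAlphabet` from a residue partition and a
    substitution matrix.

    Each group's match score is the maximum diagonal (self-score) entry of
    the matrix over the group's members.  Raises :class:`AlphabetError` if
    the groups overlap or do not cover the 20 standard residues.
    """
    groups = tuple(frozenset(g) for g in groups)
    if matrix is None:
        matrix = load_matrix(matrix_name)
    seen: set[str] = set()
    for g in groups:
        if g & seen:
            raise AlphabetError(f"overlapping groups: {sorted(g & seen)}")
        seen |= g
    if seen != set(STANDARD_RESIDUES):
        missing = set(STANDARD_RESIDUES) - seen
        extra = seen - set(STANDARD_RESIDUES)
        raise AlphabetError(
            f"groups must partition the 20 standard residues "
            f"(missing={sorted(missing)}, extra={sorted(extra)})"
        )

    group_of = {r: gi for gi, g in enumerate(groups) for r in g}
    match_score = tuple(int(max(matrix[r][r] for r in g)) for g in groups)

    table = np.full(128, UNKNOWN, dtype=np.uint8)
    for r, gi in group_of.items():
        table[ord(r)] = gi
    table[ord(DELIMITER_CHAR)] = DELIM
    return ReducedAlphabet(groups, group_of, match_score, matrix_name, table)


def reduce_sequence(seq: str, alphabet: ReducedAlphabet) -> ReducedSequence:
    """Encode a residue string into reduced-alphabet symbols.

    '#' maps to DELIM; any residue outside the 20 standard ones (ambiguity
    codes, stop '*', ...) maps to UNKNOWN.  Length is preserved.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return ReducedSequence(alphabet._encode_table[raw & 0x7F])


def symbol_scores(alphabet: ReducedAlphabet) -> np.ndarray:
    """Per-symbol score lookup (int32, length 128); sentinels get a large
    negative value so windows containing them can never qualify as seeds."""
    scores = np.full(128, -(2**20), dtype=np.int64)
    scores[: alphabet.n_groups] = alphabet.match_score
    return scores


def seed_score(window: ReducedSequence | np.ndarray, alphabet: ReducedAlphabet) -> int:
    """Sum of group match scores over a window.

    Raises ``ValueError`` if the window contains DELIM or UNKNOWN — such
    windows are never valid seeds.
    """
    sym = window.symbols if isinstance(window, ReducedSequence) else window
    if sym.size and sym.max() >= len(alphabet.groups):
        raise ValueError("window contains delimiter or unknown symbols")
    return int(symbol_scores(alphabet)[sym].sum())
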