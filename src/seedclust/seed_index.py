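"""Seed selection and perfect hashing of 6–8 residue reduced windows.

A seed window starts at a position and takes the smallest length in
[min_len, max_len] whose reduced-alphabet group scores sum above the
threshold ``t_seed`` — high-information windows get short seeds, low-
information ones need longer seeds or none at all.  Windows are encoded
injectively into an integer key (a perfect hash over the ≤ 10-symbol
alphabet), so equal keys mean identical reduced windows of identical
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import ReducedAlphabet, ReducedSequence, symbol_scores

MIN_SEED_LEN = 6
MAX_SEED_LEN = 8

# base-10 positional code with per-length offsets keeps the encoding
# injective across lengths: offset(6)=0, offset(7)=10^6, offset(8)=10^6+10^7
_LENGTH_OFFSET = {6: 0, 7: 10**6, 8: 10**6 + 10**7}
_POW10 = 10 ** np.arange(MAX_SEED_LEN, dtype=np.int64)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SeedParams:
    t_seed: int = 39
    min_len: int = MIN_SEED_LEN
    max_len: int = MAX_SEED_LEN
    strict: bool = True  # score must *exceed* t_seed; False allows equality

    def __post_init__(self):
        if not MIN_SEED_LEN <= self.min_len <= self.max_len <= MAX_SEED_LEN:
            raise ConfigError(
                f"seed lengths must satisfy {MIN_SEED_LEN} <= min <= max <= "
                f"{MAX_SEED_LEN} (perfect-hash range), got "
                f"[{self.min_len}, {self.max_len}]"
            )


@dataclass(frozen=True)
class SeedEntry:
    hash: int
    pos: int
    length: int


@dataclass
class QueryHashTable:
    """hash -> [(frame index, start position), ...], frames as indexed in
    the frame list the table was built from."""

    buckets: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def sorted_hashes(self) -> list[int]:
        return sorted(self.buckets)


def perfect_hash(window: np.ndarray) -> int:
    """Injective integer key of a reduced window of length 6–8."""
    n = len(window)
    if n not in _LENGTH_OFFSET:
        raise ValueError(f"seed window length must be 6-8, got {n}")
    if window.max() > 9:
        raise ValueError("seed window contains non-group symbols")
    return _LENGTH_OFFSET[n] + int((window.astype(np.int64) * _POW10[:n]).sum())


def hash_length(h: int) -> int:
    """Recover the window length from a perfect-hash key."""
    if h < _LENGTH_OFFSET[7]:
        return 6
    if h < _LENGTH_OFFSET[8]:
        return 7
    return 8


def select_seed(
    reduced: ReducedSequence,
    pos: int,
    params: SeedParams,
    alphabet: ReducedAlphabet,
) -> int | None:
    """Smallest qualifying seed length at ``pos``, or None.

    A length qualifies when the window fits in the sequence, contains no
    delimiter/unknown symbol, and its score exceeds (or, in non-strict
    mode, reaches) ``t_seed``.
    """
    sym = reduced.symbols
    scores = symbol_scores(alphabet)
    ngroups = alphabet.n_groups
    for length in range(params.min_len, params.max_len + 1):
        if pos + length > len(sym):
            return None
        window = sym[pos : pos + length]
        if window.max() >= ngroups:
            return None  # sentinel inside: longer windows contain it too
        s = int(scores[window].sum())
        if s > params.t_seed or (not params.strict and s == params.t_seed):
            return length
    return None


def _window_scores(sym: np.ndarray, scores: np.ndarray, length: int, ngroups: int):
    """Vectorized per-start window score and validity for one length."""
    n = len(sym)
    if n < length:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    ok = sym < ngroups
    cum = np.concatenate(([0], np.cumsum(np.where(ok, scores[sym], 0))))
    bad = np.concatenate(([0], np.cumsum(~ok)))
    win = cum[length:] - cum[:-length]
    valid = (bad[length:] - bad[:-length]) == 0
    return win, valid


def _enumerate_seeds(
    sym: np.ndarray, alphabet: ReducedAlphabet, params: SeedParams
) -> list[SeedEntry]:
    scores = symbol_scores(alphabet)
    ngroups = alphabet.n_groups
    n = len(sym)
    chosen_len = np.zeros(n, dtype=np.int8)
    for length in range(params.min_len, params.max_len + 1):
        win, valid = _window_scores(sym, scores, length, ngroups)
        if params.strict:
            qual = valid & (win > params.t_seed)
        else:
            qual = valid & (win >= params.t_seed)
        starts = np.nonzero(qual)[0]
        free = starts[chosen_len[starts] == 0]
        chosen_len[free] = length

    entries = []
    pows = _POW10
    for pos in np.nonzero(chosen_len)[0]:
        length = int(chosen_len[pos])
        window = sym[pos : pos + length]
        h = _LENGTH_OFFSET[length] + int((window.astype(np.int64) * pows[:length]).sum())
        entries.append(SeedEntry(h, int(pos), length))
    return entries


def enumerate_db_seeds(db_reduced: ReducedSequence, alphabet, params) -> list[SeedEntry]:
    """All seed entries of the concatenated database text, in position order.

    One entry per position: the smallest qualifying length (windows one
    residue shorter either fail the threshold or hit a sentinel).
    """
    return _enumerate_seeds(db_reduced.symbols, alphabet, params)


def build_query_hash_table(
    reduced_frames: list[ReducedSequence], alphabet, params
) -> QueryHashTable:
    """Group all query-frame seed positions by perfect-hash key."""
    table = QueryHashTable()
    for fi, rf in enumerate(reduced_frames):
        for entry in _enumerate_seeds(rf.symbols, alphabet, params):
            table.buckets.setdefault(entry.hash, []).append((fi, entry.pos))
    return table
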