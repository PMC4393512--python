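"""Ungapped X-drop extension, chain filtering, gapped X-drop extension and
Karlin–Altschul statistics.

Extension always scores in the original 20-letter alphabet (BLOSUM62 by
default) even though seeding used the reduced one.  The ungapped stage
extends a seed along its diagonal in both directions, stopping a
direction once the running score falls more than ``x_drop_ungapped``
below the best seen, and keeps the best-scoring prefix/suffix pair.
Hits above ``t_ungapped`` are gapped-extended with an X-drop-pruned
affine-gap dynamic program anchored inside the hit, and reported with
bit scores and E-values:

    bits = (lambda * S - ln K) / ln 2,      E = K * m * n * exp(-lambda * S)

Defaults approximate the classic BLASTX parameterization (gap open 11,
extend 1, ungapped lambda/K 0.3176/0.134, gapped 0.267/0.041); they are
stated approximations of those defaults, all overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import load_matrix

# alignment alphabet: 20 standard + ambiguity + stop + delimiter
ALIGN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*#"
DELIM_CODE = ALIGN_ALPHABET.index("#")
_X_CODE = ALIGN_ALPHABET.index("X")
NEG = -(2**20)  # effectively -inf for integer DP


def raw_from_bits(bits: float, lam: float) -> int:
    """Raw-score equivalent of a score *difference* expressed in bits."""
    return math.ceil(bits * math.log(2) / lam)


def raw_cutoff_from_bits(bits: float, lam: float, k: float) -> int:
    """Raw score whose bit score reaches ``bits``."""
    return math.ceil((bits * math.log(2) + math.log(k)) / lam)


def build_score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Integer score matrix over ALIGN_ALPHABET.  The stop symbol '*' is a
    hard mismatch against everything (including itself) and the database
    delimiter scores NEG so no alignment can cross it."""
    src = load_matrix(name)
    n = len(ALIGN_ALPHABET)
    sm = np.full((n, n), NEG, dtype=np.int64)
    for i, a in enumerate(ALIGN_ALPHABET[:-1]):  # '#' stays NEG
        for j, b in enumerate(ALIGN_ALPHABET[:-1]):
            sm[i, j] = int(src[a][b])
    stop = ALIGN_ALPHABET.index("*")
    sm[stop, :-1] = -4
    sm[:-1, stop] = -4
    return sm


_ENCODE = np.full(128, _X_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALIGN_ALPHABET):
    _ENCODE[ord(_c)] = _i


def encode_protein(seq: str) -> np.ndarray:
    """Encode residues as ALIGN_ALPHABET indices; unknowns become X."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw & 0x7F]


@dataclass(frozen=True)
class ExtendParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_ungapped: float = 0.3176
    k_ungapped: float = 0.134
    lambda_gapped: float = 0.267
    k_gapped: float = 0.041
    # raw-score thresholds; defaults are the bit-expressed BLAST-style
    # cutoffs (7 / 15 / 22 bits) converted with the lambdas above
    x_drop_ungapped: int = raw_from_bits(7, 0.3176)  # 16
    x_drop_gapped: int = raw_from_bits(15, 0.267)  # 39
    t_ungapped: int = raw_cutoff_from_bits(22, 0.3176, 0.134)  # 42
    evalue_cutoff: float = 10.0


@dataclass(frozen=True)
class UngappedHit:
    query_frame_id: int
    q_start: int
    q_end: int
    db_start: int
    db_end: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.db_start - self.q_start


@dataclass
class GappedAlignment:
    """A gapped local alignment in frame-protein / database-text coords."""

    query_frame_id: int
    q_start: int
    q_end: int  # 0-based half-open, frame protein
    db_start: int
    db_end: int  # 0-based half-open, concatenated text
    raw_score: int
    aligned_length: int
    identities: int
    mismatches: int
    gaps: int  # gapped columns
    gap_openings: int
    bit_score: float = 0.0
    e_value: float = math.inf


def _extend_one_way(qv: np.ndarray, dv: np.ndarray, sm: np.ndarray, x_drop: float):
    """Best-prefix diagonal extension over paired slices (already oriented
    in the direction of extension, delimiter-free on the database side).
    Returns (gain, steps)."""
    n = min(len(qv), len(dv))
    if n == 0:
        return 0, 0
    s = sm[qv[:n], dv[:n]]
    c = np.cumsum(s)
    run_max = np.maximum.accumulate(c)
    dropped = (run_max - c) > x_drop
    if dropped.any():
        n = int(np.argmax(dropped))  # first violating index; keep cells before it
        if n == 0:
            return 0, 0
        c = c[:n]
    best = int(c.max())
    if best <= 0:
        return 0, 0
    return best, int(np.argmax(c)) + 1


def ungapped_extend(
    q: np.ndarray,
    d: np.ndarray,
    seed,
    params: ExtendParams,
    sm: np.ndarray,
) -> UngappedHit:
    """Extend a seed along its diagonal with the X-drop cutoff; the
    returned segment is the seed plus the best-scoring left/right
    extensions and never crosses a delimiter."""
    qs, qe = seed.q_pos, seed.q_pos + seed.length
    ds, de = seed.db_pos, seed.db_pos + seed.length
    seed_sc = int(sm[q[qs:qe], d[ds:de]].sum())

    # right: bound db slice at the next delimiter
    lim = min(len(q) - qe, len(d) - de)
    dv = d[de : de + lim]
    hash_at = np.nonzero(dv == DELIM_CODE)[0]
    if hash_at.size:
        lim = int(hash_at[0])
    gain_r, ext_r = _extend_one_way(q[qe : qe + lim], d[de : de + lim], sm, params.x_drop_ungapped)

    # left: reversed slices, bound at the previous delimiter
    lim = min(qs, ds)
    dv = d[ds - lim : ds][::-1]
    hash_at = np.nonzero(dv == DELIM_CODE)[0]
    if hash_at.size:
        lim = int(hash_at[0])
    gain_l, ext_l = _extend_one_way(
        q[qs - lim : qs][::-1], d[ds - lim : ds][::-1], sm, params.x_drop_ungapped
    )

    return UngappedHit(
        seed.query_frame_id,
        qs - ext_l,
        qe + ext_r,
        ds - ext_l,
        de + ext_r,
        seed_sc + gain_l + gain_r,
    )


def chain_filter(hits: list[UngappedHit]) -> list[UngappedHit]:
    """Merge overlapping hits on the same (frame, diagonal), keeping the
    highest-scoring one; output sorted by score descending."""
    groups: dict[tuple[int, int], list[UngappedHit]] = {}
    for h in hits:
        groups.setdefault((h.query_frame_id, h.diagonal), []).append(h)
    kept: list[UngappedHit] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda h: (h.q_start, h.q_end))
        current = group[0]
        for h in group[1:]:
            if h.q_start < current.q_end:  # overlap on the shared diagonal
                if h.score > current.score:
                    current = h
            else:
                kept.append(current)
                current = h
        kept.append(current)
    kept.sort(key=lambda h: (-h.score, h.query_frame_id, h.q_start))
    return kept


@njit(cache=False)
def _xdrop_kernel(qv, dv, go, ge, x_drop, sm):  # pragma: no cover - jitted
    m, n = len(qv), len(dv)
    H = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in query (consume dv)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)  # gap in subject (consume qv)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 from E, 2 from F
    eptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 = gap-extend step
    fptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[0, 0] = 0
    best, bi, bj = 0, 0, 0
    for j in range(1, n + 1):
        E[0, j] = max(H[0, j - 1] - go, E[0, j - 1] - ge)
        eptr[0, j] = 1 if E[0, j - 1] - ge > H[0, j - 1] - go else 0
        H[0, j] = E[0, j]
        ptr[0, j] = 1
        if H[0, j] < best - x_drop:
            H[0, j] = NEG
            E[0, j] = NEG
    for i in range(1, m + 1):
        F[i, 0] = max(H[i - 1, 0] - go, F[i - 1, 0] - ge)
        fptr[i, 0] = 1 if F[i - 1, 0] - ge > H[i - 1, 0] - go else 0
        H[i, 0] = F[i, 0]
        ptr[i, 0] = 2
        if H[i, 0] < best - x_drop:
            H[i, 0] = NEG
            F[i, 0] = NEG
        row_alive = H[i, 0] > NEG
        qc = qv[i - 1]
        for j in range(1, n + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            eptr[i, j] = 1 if E[i, j - 1] - ge > H[i, j - 1] - go else 0
            f = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            fptr[i, j] = 1 if F[i - 1, j] - ge > H[i - 1, j] - go else 0
            h = H[i - 1, j - 1] + sm[qc, dv[j - 1]]
            p = np.int8(0)
            if e > h:
                h, p = e, np.int8(1)
            if f > h:
                h, p = f, np.int8(2)
            if h < best - x_drop or h <= NEG // 2:
                continue  # pruned cell stays NEG
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
            ptr[i, j] = p
            row_alive = True
            if h > best:
                best, bi, bj = h, i, j
        if not row_alive:
            break
    return best, bi, bj, ptr, eptr, fptr


def _xdrop_dp(
    qv: np.ndarray,
    dv: np.ndarray,
    params: ExtendParams,
    sm: np.ndarray,
    x_drop: float,
):
    """Affine-gap X-drop extension DP from origin over qv vs dv.

    Scores alignments of prefixes qv[:i], dv[:j] that start at (0, 0);
    cells falling more than ``x_drop`` below the running best are pruned.
    Returns (best score, best i, best j, ops) where ops is the traceback
    ('M' diagonal, 'D' deletion in query / gap in dv, 'I' insertion).
    """
    best, bi, bj, ptr, eptr, fptr = _xdrop_kernel(
        np.ascontiguousarray(qv),
        np.ascontiguousarray(dv),
        params.gap_open + params.gap_extend,
        params.gap_extend,
        2**40 if math.isinf(x_drop) else int(x_drop),
        sm,
    )
    # traceback from (bi, bj)
    ops: list[str] = []
    i, j, state = bi, bj, 0  # state 0=H, 1=E, 2=F
    while i > 0 or j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                ops.append("M")
                i, j = i - 1, j - 1
            else:
                state = p
        elif state == 1:
            ops.append("I")  # consumes dv[j-1]
            state = 1 if eptr[i, j] else 0
            j -= 1
        else:
            ops.append("D")  # consumes qv[i-1]
            state = 2 if fptr[i, j] else 0
            i -= 1
    ops.reverse()
    return int(best), bi, bj, ops


def _anchor_position(q: np.ndarray, d: np.ndarray, hit: UngappedHit, sm: np.ndarray):
    """Highest-scoring single column of the hit (leftmost on ties)."""
    qs, qe = hit.q_start, hit.q_end
    col = sm[q[qs:qe], d[hit.db_start : hit.db_end]]
    k = int(np.argmax(col))
    return qs + k, hit.db_start + k


def _stats_from_ops(ops, qv, dv) -> tuple[int, int, int, int]:
    """(identities, mismatches, gap columns, gap openings) along ops."""
    ident = mism = gaps = openings = 0
    i = j = 0
    prev_gap = False
    for op in ops:
        if op == "M":
            if qv[i] == dv[j]:
                ident += 1
            else:
                mism += 1
            i += 1
            j += 1
            prev_gap = False
        else:
            gaps += 1
            if not prev_gap:
                openings += 1
            prev_gap = True
            if op == "D":
                i += 1
            else:
                j += 1
    return ident, mism, gaps, openings


def gapped_extend(
    q: np.ndarray,
    d: np.ndarray,
    hit: UngappedHit,
    params: ExtendParams,
    sm: np.ndarray,
    x_drop: float | None = None,
) -> GappedAlignment | None:
    """Score-limited gapped extension anchored inside an ungapped hit.

    Extends independently left and right of the anchor column with the
    X-drop DP; the database side is bounded by the enclosing delimiters.
    Returns None when the total score is not positive.
    """
    if x_drop is None:
        x_drop = params.x_drop_gapped
    qa, da = _anchor_position(q, d, hit, sm)

    # database segment boundaries (delimiters)
    left_lim = da
    hash_at = np.nonzero(d[:da][::-1] == DELIM_CODE)[0]
    if hash_at.size:
        left_lim = int(hash_at[0])
    right_lim = len(d) - da
    hash_at = np.nonzero(d[da:] == DELIM_CODE)[0]
    if hash_at.size:
        right_lim = int(hash_at[0])

    # right extension includes the anchor column
    r_q, r_d = q[qa:], d[da : da + right_lim]
    sc_r, ri, rj, ops_r = _xdrop_dp(r_q, r_d, params, sm, x_drop)
    # left extension over reversed prefixes
    l_q, l_d = q[:qa][::-1], d[da - left_lim : da][::-1]
    sc_l, li, lj, ops_l = _xdrop_dp(l_q, l_d, params, sm, x_drop)

    total = sc_l + sc_r
    if total <= 0:
        return None
    ops = list(reversed(ops_l)) + ops_r
    qv = q[qa - li : qa + ri]
    dv = d[da - lj : da + rj]
    ident, mism, gaps, openings = _stats_from_ops(ops, qv, dv)
    return GappedAlignment(
        hit.query_frame_id,
        qa - li,
        qa + ri,
        da - lj,
        da + rj,
        total,
        len(ops),
        ident,
        mism,
        gaps,
        openings,
    )


def compute_statistics(
    raw_score: int, query_length: int, db_total_residues: int, params: ExtendParams
) -> tuple[float, float]:
    """Karlin–Altschul bit score and E-value (gapped lambda/K), with
    n = residues in the *full* database so chunking cannot change them."""
    lam, k = params.lambda_gapped, params.k_gapped
    bits = (lam * raw_score - math.log(k)) / math.log(2)
    e = k * query_length * db_total_residues * math.exp(-lam * raw_score)
    return bits, e
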