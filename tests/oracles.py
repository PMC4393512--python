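"""Independent brute-force oracles used to check the search implementation.

Everything here is deliberately naive (exhaustive enumeration, plain
quadratic dynamic programming) and shares no code with the package's
extension routines.
"""

from __future__ import annotations

import numpy as np

NEG = float("-inf")


def brute_force_seed_positions(symbols, scores, t_seed, min_len, max_len, n_groups,
                               strict=True):
    """Per-position smallest qualifying seed length by direct enumeration."""
    out = {}
    for pos in range(len(symbols)):
        for length in range(min_len, max_len + 1):
            if pos + length > len(symbols):
                break
            window = symbols[pos : pos + length]
            if max(window) >= n_groups:
                break
            s = sum(int(scores[c]) for c in window)
            if s > t_seed or (not strict and s == t_seed):
                out[pos] = length
                break
    return out


def best_diagonal_segment(q, d, qs, qe, ds, de, sm, delim_code):
    """Max score over all diagonal segments containing [qs,qe)/[ds,de),
    staying inside both sequences and never crossing the delimiter."""
    best = None
    a = 0
    while qs - a - 1 >= 0 and ds - a - 1 >= 0 and d[ds - a - 1] != delim_code:
        a += 1
    b = 0
    while qe + b < len(q) and de + b < len(d) and d[de + b] != delim_code:
        b += 1
    for left in range(a + 1):
        for right in range(b + 1):
            s = sum(
                int(sm[q[i], d[j]])
                for i, j in zip(range(qs - left, qe + right), range(ds - left, de + right))
            )
            if best is None or s > best:
                best = s
    return best


def smith_waterman(q, d, sm, gap_open, gap_extend):
    """Plain quadratic affine-gap local alignment; returns the best score.

    Gap of length k costs gap_open + k * gap_extend.
    """
    m, n = len(q), len(d)
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sm[q[i - 1], d[j - 1]], E[i, j], F[i, j])
            best = max(best, H[i, j])
    return int(best)


def _prefix_dp_best(q, d, sm, gap_open, gap_extend):
    """Best score over alignments of prefixes of q and d anchored at (0,0)
    (free end); plain full DP, no pruning."""
    m, n = len(q), len(d)
    go = gap_open + gap_extend
    ge = gap_extend
    H = np.full((m + 1, n + 1), NEG)
    E = np.full((m + 1, n + 1), NEG)
    F = np.full((m + 1, n + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = max(H[0, j - 1] - go, E[0, j - 1] - ge)
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = max(H[i - 1, 0] - go, F[i - 1, 0] - ge)
        H[i, 0] = F[i, 0]
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
            H[i, j] = max(H[i - 1, j - 1] + sm[q[i - 1], d[j - 1]], E[i, j], F[i, j])
    return int(max(0, H.max()))


def anchored_alignment_score(q, d, qa, da, sm, gap_open, gap_extend):
    """Best local alignment score constrained to pass through the anchor
    column (q[qa], d[da]): independent left/right prefix DP around it."""
    right = _prefix_dp_best(q[qa:], d[da:], sm, gap_open, gap_extend)
    left = _prefix_dp_best(q[:qa][::-1], d[:da][::-1], sm, gap_open, gap_extend)
    return left + right


def true_member_distances(q_window, member_windows):
    """Exact Hamming distances from a query window to each member window."""
    return [int((q_window != w).sum()) for w in member_windows]
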