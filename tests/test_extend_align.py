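"""Ungapped/gapped extension against exhaustive oracles, chain filtering
and alignment statistics."""

import math

import numpy as np
import pytest

from oracles import (
    anchored_alignment_score,
    best_diagonal_segment,
    smith_waterman,
)
from seedclust.extend_align import (
    DELIM_CODE,
    ExtendParams,
    UngappedHit,
    chain_filter,
    compute_statistics,
    encode_protein,
    gapped_extend,
    ungapped_extend,
)
from seedclust.search_filter import Seed

INF = float("inf")


def _protein(rng, n):
    from seedclust.alphabet import STANDARD_RESIDUES

    return "".join(rng.choice(list(STANDARD_RESIDUES), size=n))


def _mutate(rng, s, n_mut):
    from seedclust.alphabet import STANDARD_RESIDUES

    out = list(s)
    for i in rng.choice(len(s), size=n_mut, replace=False):
        out[i] = str(rng.choice(list(STANDARD_RESIDUES)))
    return "".join(out)


def test_ungapped_identical_context(score_matrix, extend_params, rng):
    """Identical 30-residue context flanked by delimiters: the hit covers
    the whole segment and scores the sum of diagonal entries."""
    s = _protein(rng, 30)
    q = encode_protein(s)
    d = encode_protein(f"#{s}#")
    seed = Seed(0, 10, 11, 7)
    hit = ungapped_extend(q, d, seed, extend_params, score_matrix)
    assert (hit.q_start, hit.q_end) == (0, 30)
    assert (hit.db_start, hit.db_end) == (1, 31)
    assert hit.score == int(score_matrix[q, q].sum())


def test_ungapped_stops_at_delimiter(score_matrix, extend_params):
    s = "HDGLNPA"
    q = encode_protein(s)
    d = encode_protein(f"#{s}#")
    hit = ungapped_extend(q, d, Seed(0, 0, 1, 7), extend_params, score_matrix)
    assert (hit.db_start, hit.db_end) == (1, 8)
    assert hit.score == int(score_matrix[q, q].sum())


def test_ungapped_matches_exhaustive_oracle(score_matrix, rng):
    """With infinite X-drop the returned score equals the brute-force best
    diagonal sub-segment containing the seed."""
    params = ExtendParams(x_drop_ungapped=10**9)
    for _ in range(40):
        qs = _protein(rng, 60)
        ds = "#" + _mutate(rng, qs, int(rng.integers(0, 30))) + "#"
        q, d = encode_protein(qs), encode_protein(ds)
        pos = int(rng.integers(0, 54))
        seed = Seed(0, pos, pos + 1, 6)
        hit = ungapped_extend(q, d, seed, params, score_matrix)
        oracle = best_diagonal_segment(
            q, d, pos, pos + 6, pos + 1, pos + 7, score_matrix, DELIM_CODE
        )
        assert hit.score == oracle
        # reported segment rescored from coordinates matches the score
        reseg = int(score_matrix[q[hit.q_start : hit.q_end],
                                 d[hit.db_start : hit.db_end]].sum())
        assert reseg == hit.score


def test_ungapped_score_at_least_seed(score_matrix, extend_params, rng):
    qs = _protein(rng, 40)
    ds = "#" + _protein(rng, 40) + "#"
    q, d = encode_protein(qs), encode_protein(ds)
    for pos in range(0, 30, 5):
        seed = Seed(0, pos, pos + 1, 6)
        seed_score = int(score_matrix[q[pos : pos + 6], d[pos + 1 : pos + 7]].sum())
        hit = ungapped_extend(q, d, seed, extend_params, score_matrix)
        assert hit.score >= seed_score
        assert hit.q_end - hit.q_start == hit.db_end - hit.db_start


def _hit(qs, qe, dbs, dbe, score, frame=0):
    return UngappedHit(frame, qs, qe, dbs, dbe, score)


def test_chain_filter_rules():
    a = _hit(0, 10, 5, 15, 50)
    assert chain_filter([a, a]) == [a]  # exact duplicate
    b = _hit(5, 15, 10, 20, 40)  # same diagonal, overlapping, lower score
    assert chain_filter([a, b]) == [a]
    c = _hit(0, 10, 6, 16, 40)  # different diagonal
    assert set(chain_filter([a, c])) == {a, c}
    d = _hit(20, 30, 25, 35, 40)  # same diagonal, disjoint
    assert set(chain_filter([a, d])) == {a, d}
    e = _hit(0, 10, 5, 15, 50, frame=1)  # other frame is never merged
    assert set(chain_filter([a, e])) == {a, e}


def test_chain_filter_keeps_group_best(rng):
    hits = [_hit(i, i + 10, i + 3, i + 13, int(rng.integers(10, 99))) for i in range(8)]
    best = max(h.score for h in hits)
    out = chain_filter(hits)
    assert max(h.score for h in out) == best
    assert out == sorted(out, key=lambda h: -h.score)


def test_gapped_identical_matches_smith_waterman(score_matrix, rng):
    """Identical sequences, infinite X-drop: score and endpoints equal the
    full local-alignment optimum."""
    s = _protein(rng, 20)
    q = encode_protein(s)
    d = encode_protein(f"#{s}#")
    hit = _hit(5, 15, 6, 16, int(score_matrix[q[5:15], q[5:15]].sum()))
    aln = gapped_extend(q, d, hit, ExtendParams(), score_matrix, x_drop=INF)
    sw = smith_waterman(q, d, score_matrix, 11, 1)
    assert aln.raw_score == sw == int(score_matrix[q, q].sum())
    assert (aln.q_start, aln.q_end) == (0, 20)
    assert aln.identities == 20 and aln.gaps == 0


def test_gapped_single_deletion(score_matrix, rng):
    """Subject = query minus one residue: exactly one length-1 gap opening,
    score equal to the local-alignment oracle."""
    s = _protein(rng, 30)
    subject = s[:14] + s[15:]
    q, d = encode_protein(s), encode_protein(f"#{subject}#")
    hit = _hit(0, 10, 1, 11, int(score_matrix[q[:10], q[:10]].sum()))
    aln = gapped_extend(q, d, hit, ExtendParams(), score_matrix, x_drop=INF)
    sw = smith_waterman(q, d, score_matrix, 11, 1)
    # cross-check the plain-DP oracle against an established aligner
    from Bio.Align import PairwiseAligner, substitution_matrices

    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=substitution_matrices.load("BLOSUM62"),
        open_gap_score=-12,
        extend_gap_score=-1,
    )
    assert sw == int(aligner.score(s, subject))
    assert aln.raw_score == sw
    assert aln.gap_openings == 1 and aln.gaps == 1
    assert aln.identities + aln.mismatches + aln.gaps == aln.aligned_length


def test_gapped_matches_anchored_oracle(score_matrix, rng):
    """Infinite X-drop: the extension equals an independent anchored DP
    (best alignment through the anchor column) on random related pairs."""
    from seedclust.extend_align import _anchor_position

    params = ExtendParams()
    for _ in range(25):
        s = _protein(rng, 50)
        subject = _mutate(rng, s, int(rng.integers(0, 15)))
        q, d = encode_protein(s), encode_protein(f"#{subject}#")
        pos = int(rng.integers(0, 40))
        hit = _hit(pos, pos + 10, pos + 1, pos + 11,
                   int(score_matrix[q[pos : pos + 10], d[pos + 1 : pos + 11]].sum()))
        aln = gapped_extend(q, d, hit, params, score_matrix, x_drop=INF)
        qa, da = _anchor_position(q, d, hit, score_matrix)
        oracle = anchored_alignment_score(q, d, qa, da, score_matrix, 11, 1)
        if oracle <= 0:
            assert aln is None or aln.raw_score <= 0
        else:
            assert aln is not None and aln.raw_score == oracle
            assert aln.raw_score <= smith_waterman(q, d, score_matrix, 11, 1)


def test_gapped_none_on_all_mismatch(score_matrix):
    q = encode_protein("WWWWWWWWWW")
    d = encode_protein("#GGGGGGGGGG#")
    hit = _hit(2, 8, 3, 9, int(score_matrix[q[2:8], d[3:9]].sum()))
    assert hit.score < 0
    assert gapped_extend(q, d, hit, ExtendParams(), score_matrix, x_drop=INF) is None


def test_statistics_closed_form():
    params = ExtendParams()
    bits, e = compute_statistics(100, 50, 10**6, params)
    assert bits == pytest.approx((0.267 * 100 - math.log(0.041)) / math.log(2))
    assert e == pytest.approx(0.041 * 50 * 10**6 * math.exp(-0.267 * 100))
    # doubling the database doubles E
    _, e2 = compute_statistics(100, 50, 2 * 10**6, params)
    assert e2 == pytest.approx(2 * e)
    # E decreases strictly with score
    assert compute_statistics(101, 50, 10**6, params)[1] < e
    # E halves when the raw score increases by ln2/lambda
    _, e3 = compute_statistics(100 + math.log(2) / 0.267, 50, 10**6, params)
    assert e3 == pytest.approx(e / 2)


def test_default_raw_thresholds():
    """BLAST-style bit cutoffs converted to raw scores with the ungapped
    and gapped Karlin-Altschul parameters."""
    p = ExtendParams()
    assert p.x_drop_ungapped == math.ceil(7 * math.log(2) / 0.3176)
    assert p.x_drop_gapped == math.ceil(15 * math.log(2) / 0.267)
    assert p.t_ungapped == math.ceil((22 * math.log(2) + math.log(0.134)) / 0.3176)
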