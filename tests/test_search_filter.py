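"""Seed search over the tables and losslessness of the triangle-inequality
similarity filter."""

import numpy as np
import pytest

from oracles import true_member_distances
from seedclust.alphabet import build_reduced_alphabet, reduce_sequence
from seedclust.cluster_index import (
    ClusterParams,
    cluster_subsequences,
    hamming_distance,
    make_cluster_window,
)
from seedclust.search_filter import (
    SearchCounters,
    direct_seed_search,
    lower_bound_distance,
    query_cluster_window,
    seed_search,
)
from seedclust.seed_index import SeedParams, build_query_hash_table, enumerate_db_seeds


@pytest.mark.parametrize("d_qr,d_rm,expected", [(3, 1, 2), (2, 2, 0), (0, 1, -1)])
def test_lower_bound_arithmetic(d_qr, d_rm, expected):
    assert lower_bound_distance(d_qr, d_rm) == expected


def _random_db_text(rng, n_fam, members, length, mutations):
    from seedclust.alphabet import STANDARD_RESIDUES

    chars = np.array(list(STANDARD_RESIDUES))
    parts = ["#"]
    for _ in range(n_fam):
        anc = rng.choice(chars, size=length)
        for _ in range(members):
            m = anc.copy()
            idx = rng.choice(length, size=mutations, replace=False)
            m[idx] = rng.choice(chars, size=mutations)
            parts.append("".join(m) + "#")
    return "".join(parts)


def _setup(rng, alphabet, n_fam=5, members=4, length=60, mutations=2, n_queries=6):
    from conftest import random_protein

    sp, cp = SeedParams(), ClusterParams()
    text = _random_db_text(rng, n_fam, members, length, mutations)
    db_reduced = reduce_sequence(text, alphabet)
    entries = enumerate_db_seeds(db_reduced, alphabet, sp)
    tables = cluster_subsequences(entries, db_reduced, cp)
    # queries: mutated copies of database segments plus random sequences
    queries = []
    for i in range(n_queries):
        if i % 2 == 0:
            start = int(rng.integers(1, len(text) - 41))
            q = text[start : start + 40].replace("#", "A")
        else:
            q = random_protein(rng, 40)
        queries.append(reduce_sequence(q, alphabet))
    qtable = build_query_hash_table(queries, alphabet, sp)
    return db_reduced, entries, tables, queries, qtable, sp, cp


def test_member_emission_follows_bound(alphabet):
    """A member is emitted iff d(Q,R) - d(R,M) <= t_distance; a member at
    bound -1 always passes, one at bound 3 > 2 is skipped."""
    # database: representative context and a member context at distance 1,
    # plus a faraway window with the same seed
    core = "HDGLNPA"
    s_rep = "AAAAA" + core + "AAAAA"
    s_mem = "AAAAC" + core + "AAAAA"  # window distance 1 from rep
    text = f"#{s_rep}#{s_mem}#"
    db_reduced = reduce_sequence(text, alphabet)
    sp, cp = SeedParams(), ClusterParams()
    entries = enumerate_db_seeds(db_reduced, alphabet, sp)
    tables = cluster_subsequences(entries, db_reduced, cp)
    core_hash = [e.hash for e in entries if text[e.pos] == "H"][0]
    assert core_hash in tables.b_r

    # query identical to the representative: d_qr = 0, bound -1 <= 2
    q_pass = reduce_sequence(s_rep, alphabet)
    qtable = build_query_hash_table([q_pass], alphabet, sp)
    got = list(seed_search(qtable, tables, db_reduced, [q_pass], cp))
    provs = {prov for s, prov in got if s.db_pos in (6, 24)}  # the two H positions
    assert provs == {"representative", "member"}

    # query with distant flanks: d_qr = 5, bound 4 > 2 -> member skipped
    q_skip = reduce_sequence("WWWWW" + core + "WWWWW", alphabet)
    qtable = build_query_hash_table([q_skip], alphabet, sp)
    counters = SearchCounters()
    got = list(seed_search(qtable, tables, db_reduced, [q_skip], cp, counters))
    provs = {prov for s, prov in got if s.db_pos in (6, 24)}
    assert provs == {"representative"}
    assert counters.n_similarity_filterings >= 1


def test_short_frame_bypasses_filtering(alphabet):
    """When the query cluster window overruns the frame, all members pass."""
    core = "HDGLNPA"
    text = f"#AAAAA{core}AAAAA#AAAAC{core}AAAAA#"
    db_reduced = reduce_sequence(text, alphabet)
    sp, cp = SeedParams(), ClusterParams()
    tables = cluster_subsequences(
        enumerate_db_seeds(db_reduced, alphabet, sp), db_reduced, cp
    )
    q = reduce_sequence(core + "AA", alphabet)  # seed at pos 0, no window
    assert query_cluster_window(q, 0, cp.l) is None
    counters = SearchCounters()
    got = list(seed_search(build_query_hash_table([q], alphabet, sp), tables,
                           db_reduced, [q], cp, counters))
    assert {prov for _, prov in got} == {"representative", "member"}
    assert counters.n_similarity_filterings == 0


def test_filter_lossless_against_brute_force(alphabet, rng):
    """No member whose true window distance to the query is <= t_distance
    is ever skipped (triangle inequality), over random instances."""
    db_reduced, entries, tables, queries, qtable, sp, cp = _setup(rng, alphabet)
    emitted = set()
    for s, prov in seed_search(qtable, tables, db_reduced, queries, cp):
        if prov == "member":
            emitted.add((s.query_frame_id, s.q_pos, s.db_pos))
    checked = 0
    for h, qlist in qtable.buckets.items():
        for cid, rpos in tables.b_r.get(h, ()):
            member_pos = [m for m, _ in tables.b_m[cid]]
            windows = [make_cluster_window(db_reduced, m, cp.l) for m in member_pos]
            for fi, q_pos in qlist:
                qwin = query_cluster_window(queries[fi], q_pos, cp.l)
                if qwin is None:
                    continue
                for mpos, true_d in zip(
                    member_pos, true_member_distances(qwin, windows)
                ):
                    checked += 1
                    if true_d <= cp.t_distance:
                        assert (fi, q_pos, mpos) in emitted
    assert checked > 50  # the instance actually exercised the filter


def test_degenerate_threshold_emits_every_seed(alphabet, rng):
    """With t_distance = L the filter passes everything: the clustered seed
    set equals the direct hash-join seed set."""
    db_reduced, entries, tables, queries, qtable, sp, _ = _setup(rng, alphabet)
    cp = ClusterParams(10, 1, 10)
    clustered = {
        (s.query_frame_id, s.q_pos, s.db_pos, s.length)
        for s, _ in seed_search(qtable, tables, db_reduced, queries, cp)
    }
    buckets = {}
    for e in entries:
        buckets.setdefault(e.hash, []).append(e.pos)
    direct = {
        (s.query_frame_id, s.q_pos, s.db_pos, s.length)
        for s, _ in direct_seed_search(qtable, buckets)
    }
    assert clustered == direct


def test_counters_track_distance_computations_and_checks(alphabet, rng):
    db_reduced, entries, tables, queries, qtable, sp, cp = _setup(rng, alphabet)
    counters = SearchCounters()
    expected_checks = 0
    expected_filterings = 0
    for h, qlist in qtable.buckets.items():
        for cid, rpos in tables.b_r.get(h, ()):
            n_members = len(tables.b_m[cid])
            for fi, q_pos in qlist:
                if query_cluster_window(queries[fi], q_pos, cp.l) is not None:
                    expected_filterings += 1
                    expected_checks += n_members  # no bound test without a window
    list(seed_search(qtable, tables, db_reduced, queries, cp, counters))
    assert counters.n_member_bound_checks == expected_checks
    assert counters.n_similarity_filterings == expected_filterings
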