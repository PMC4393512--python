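"""Seed search over the hash tables with triangle-inequality filtering.

For every hash shared between the query table and the database tables,
seeds are emitted in three ways: directly for singleton positions (B_e);
for cluster representatives (B_r), after computing the query-to-
representative window distance once; and for cluster members (B_m) only
when the triangle-inequality lower bound

    d(C_Q, M) >= d(C_Q, R) - d(R, M)

does not exceed ``t_distance``.  Because Hamming distance obeys the
triangle inequality, no member whose true distance is within the
threshold is ever skipped — the filter is lossless with respect to the
true-distance criterion and only prunes provably distant candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .alphabet import DELIM, ReducedSequence
from .cluster_index import (
    ClusterParams,
    ClusterTables,
    hamming_distance,
    make_cluster_window,
)
from .seed_index import ConfigError, QueryHashTable, hash_length


@dataclass(frozen=True)
class Seed:
    query_frame_id: int  # index into the frame list
    q_pos: int
    db_pos: int
    length: int


@dataclass
class SearchCounters:
    """Instrumentation for the cost model of the search.

    ``n_similarity_filterings`` counts query-to-representative Hamming
    distance computations — the step whose cost is comparable to an
    ungapped extension, and hence the one added to
    ``n_ungapped_extensions`` when judging the benefit of clustering.
    The per-member lower-bound test is a constant-time subtraction and
    is tallied separately as ``n_member_bound_checks``.
    """

    n_seeds_examined: int = 0
    n_similarity_filterings: int = 0
    n_ungapped_extensions: int = 0
    n_gapped_extensions: int = 0
    n_member_bound_checks: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def lower_bound_distance(d_qr: int, d_rm: int) -> int:
    """Triangle-inequality lower bound on d(query window, member window).

    May be negative, in which case it passes any non-negative threshold.
    """
    return d_qr - d_rm


def query_cluster_window(
    frame_reduced: ReducedSequence, q_pos: int, l: int
) -> np.ndarray | None:
    """Query-side clustering window, built exactly like the database one:
    length ``l`` centred on the seed start; None when it overruns the
    frame (filtering is then bypassed for that seed)."""
    half = l // 2
    sym = frame_reduced.symbols
    if q_pos - half < 0 or q_pos + half > len(sym):
        return None
    window = sym[q_pos - half : q_pos + half]
    if (window == DELIM).any():  # frames carry no delimiter, but be safe
        return None
    return window


def seed_search(
    query_table: QueryHashTable,
    tables: ClusterTables,
    db_reduced: ReducedSequence,
    query_reduced_frames: list[ReducedSequence],
    params: ClusterParams,
    counters: SearchCounters | None = None,
) -> Iterator[tuple[Seed, str]]:
    """Yield (seed, provenance) pairs; provenance is one of
    ``"direct"``, ``"representative"``, ``"member"``.

    Hashes are visited in sorted order and query positions grouped per
    hash (the cache-locality batching of the original design); the
    emitted seed *set* is independent of that order.
    """
    if counters is None:
        counters = SearchCounters()
    rep_index: dict[int, list[tuple[int, int]]] = tables.b_r
    for h in query_table.sorted_hashes():
        direct = tables.b_e.get(h, ())
        reps = rep_index.get(h, ())
        if not direct and not reps:
            continue
        length = hash_length(h)
        for fi, q_pos in query_table.buckets[h]:
            counters.n_seeds_examined += len(direct)
            for db_pos in direct:
                yield Seed(fi, q_pos, db_pos, length), "direct"
            if not reps:
                continue
            q_window = query_cluster_window(
                query_reduced_frames[fi], q_pos, params.l
            )
            for cid, rpos in reps:
                counters.n_seeds_examined += 1
                yield Seed(fi, q_pos, rpos, length), "representative"
                members = tables.b_m[cid]
                if q_window is None:
                    # no query window: filtering impossible, pass all members
                    for mpos, _ in members:
                        counters.n_seeds_examined += 1
                        yield Seed(fi, q_pos, mpos, length), "member"
                    continue
                r_window = make_cluster_window(db_reduced, rpos, params.l)
                counters.n_similarity_filterings += 1
                d_qr = hamming_distance(q_window, r_window)
                for mpos, d_rm in members:
                    counters.n_seeds_examined += 1
                    counters.n_member_bound_checks += 1
                    if lower_bound_distance(d_qr, d_rm) <= params.t_distance:
                        yield Seed(fi, q_pos, mpos, length), "member"


def direct_seed_search(
    query_table: QueryHashTable,
    db_seed_buckets: dict[int, list[int]],
    counters: SearchCounters | None = None,
) -> Iterator[tuple[Seed, str]]:
    """Unclustered flow: join the query table against *all* database seed
    positions; every seed goes straight to ungapped extension."""
    if counters is None:
        counters = SearchCounters()
    for h in query_table.sorted_hashes():
        db_positions = db_seed_buckets.get(h)
        if not db_positions:
            continue
        length = hash_length(h)
        for fi, q_pos in query_table.buckets[h]:
            counters.n_seeds_examined += len(db_positions)
            for db_pos in db_positions:
                yield Seed(fi, q_pos, db_pos, length), "direct"
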