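"""Greedy clustering of database cluster windows and the B_e/B_r/B_m tables.

Around every database seed start a length-L window (the clustering window)
is cut from the reduced text.  Within each seed-hash bucket these windows
are clustered greedily under Hamming distance, CD-HIT style: the first
window founds a cluster; each later window joins the earliest-created
representative within ``t_cluster``, else founds its own cluster.  The
result is stored as three tables used by the seed search:

- ``b_e`` — hash -> positions whose cluster is a singleton or whose window
  is unusable (delimiter / text boundary); these seeds are always extended.
- ``b_r`` — hash -> (cluster id, representative position).
- ``b_m`` — cluster id -> (member position, Hamming distance to the
  representative); the stored distance feeds the triangle-inequality
  lower bound during filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import DELIM, ReducedSequence
from .seed_index import ConfigError, SeedEntry


@dataclass(frozen=True)
class ClusterParams:
    l: int = 10
    t_cluster: int = 1  # 0.1 * L
    t_distance: int = 2  # 0.2 * L

    def __post_init__(self):
        if self.l % 2:
            raise ConfigError(f"cluster window length L must be even, got {self.l}")
        if not 0 <= self.t_cluster <= self.t_distance <= self.l:
            raise ConfigError(
                "thresholds must satisfy 0 <= t_cluster <= t_distance <= L, got "
                f"t_cluster={self.t_cluster} t_distance={self.t_distance} L={self.l}"
            )

    @classmethod
    def from_length(cls, l: int, cluster_frac: float = 0.1, distance_frac: float = 0.2):
        """Thresholds as the conventional fractions of L (rounded)."""
        return cls(l, int(round(cluster_frac * l)), int(round(distance_frac * l)))


@dataclass
class ClusterTables:
    b_e: dict[int, list[int]] = field(default_factory=dict)
    b_r: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    b_m: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def positions(self) -> list[int]:
        """Every seed position stored across the three tables."""
        out = [p for ps in self.b_e.values() for p in ps]
        out += [p for rs in self.b_r.values() for _, p in rs]
        out += [p for ms in self.b_m.values() for p, _ in ms]
        return out


def make_cluster_window(
    db_reduced: ReducedSequence, i: int, l: int
) -> np.ndarray | None:
    """Length-``l`` reduced window centred on seed start ``i``
    (positions [i - l/2, i + l/2)), or None if it overruns the text or
    contains a delimiter (it would straddle two database sequences)."""
    half = l // 2
    sym = db_reduced.symbols
    if i - half < 0 or i + half > len(sym):
        return None
    window = sym[i - half : i + half]
    if (window == DELIM).any():
        return None
    return window


def hamming_distance(a: np.ndarray, b: np.ndarray) -> int:
    if len(a) != len(b):
        raise ValueError(f"windows differ in length: {len(a)} vs {len(b)}")
    return int((a != b).sum())


def cluster_subsequences(
    entries: list[SeedEntry],
    db_reduced: ReducedSequence,
    params: ClusterParams,
) -> ClusterTables:
    """Greedy single-pass clustering within each seed-hash bucket.

    Positions are visited in ascending order; a position joins the first
    representative (in creation order) at Hamming distance <= t_cluster,
    otherwise it becomes a new representative.  Clusters that end the pass
    with no members collapse into ``b_e``.
    """
    buckets: dict[int, list[int]] = {}
    for e in entries:
        buckets.setdefault(e.hash, []).append(e.pos)

    tables = ClusterTables()
    next_cid = 0
    for h in sorted(buckets):
        positions = sorted(buckets[h])
        reps: list[tuple[int, np.ndarray]] = []  # (pos, window), creation order
        members: list[list[tuple[int, int]]] = []
        no_window: list[int] = []
        for pos in positions:
            window = make_cluster_window(db_reduced, pos, params.l)
            if window is None:
                no_window.append(pos)
                continue
            for ri, (rpos, rwin) in enumerate(reps):
                d = hamming_distance(window, rwin)
                if d <= params.t_cluster:
                    members[ri].append((pos, d))
                    break
            else:
                reps.append((pos, window))
                members.append([])

        singles = list(no_window)
        for (rpos, _), mem in zip(reps, members):
            if not mem:
                singles.append(rpos)
            else:
                tables.b_r.setdefault(h, []).append((next_cid, rpos))
                tables.b_m[next_cid] = mem
                next_cid += 1
        if singles:
            tables.b_e[h] = sorted(singles)
    return tables
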