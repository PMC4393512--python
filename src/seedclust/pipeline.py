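"""End-to-end orchestration: index building with database chunking, the
clustered and unclustered search flows, chunk-result merging and BLAST
tabular output.

The database is split greedily (file order) into chunks of at most
``chunk_size`` residues; each chunk is indexed and searched
independently and per-chunk results are merged keeping, per
(query, subject) pair, the best alignment.  E-values always use the
total residue count of the *full* database recorded in the manifest, so
chunking never changes reported statistics — chunked and unchunked
builds of the same database produce identical output.

Index layout (one directory): ``manifest.json`` plus one
``chunk_NNNN.json`` per chunk holding the chunk's sequences, seed
entries and cluster tables.  The format is versioned JSON
(INDEX_FORMAT/INDEX_VERSION); loaders refuse unknown versions.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .alphabet import build_reduced_alphabet, reduce_sequence
from .cluster_index import ClusterParams, ClusterTables, cluster_subsequences
from .extend_align import (
    ExtendParams,
    GappedAlignment,
    build_score_matrix,
    chain_filter,
    compute_statistics,
    encode_protein,
    gapped_extend,
    ungapped_extend,
)
from .search_filter import SearchCounters, direct_seed_search, seed_search
from .seed_index import (
    ConfigError,
    SeedEntry,
    SeedParams,
    build_query_hash_table,
    enumerate_db_seeds,
)
from .seqio import (
    ConcatenatedDatabase,
    InputError,
    TranslatedFrame,
    build_concatenated_database,
    read_fasta,
    six_frame_translate,
    to_dna_coords,
)

INDEX_FORMAT = "seedclust-index"
INDEX_VERSION = 1

#: index-affecting configuration keys that must match between makedb and search
INDEX_KEYS = ("t_seed", "strict", "min_len", "max_len", "l", "t_cluster", "matrix_name")


@dataclass
class SearchConfig:
    # seeding (index-affecting)
    t_seed: int = 39
    strict: bool = True
    min_len: int = 6
    max_len: int = 8
    # clustering
    l: int = 10
    t_cluster: int = 1
    t_distance: int = 2
    matrix_name: str = "BLOSUM62"
    clustering_enabled: bool = True
    # chunking: residues of sequence data per chunk
    chunk_size: int = 2**30
    # search-time
    evalue_cutoff: float = 10.0
    max_hsps: int = 1
    query_type: str = "auto"  # auto | dna | protein
    extend: ExtendParams = field(default_factory=ExtendParams)

    def seed_params(self) -> SeedParams:
        return SeedParams(self.t_seed, self.min_len, self.max_len, self.strict)

    def cluster_params(self) -> ClusterParams:
        return ClusterParams(self.l, self.t_cluster, self.t_distance)

    def effective_dict(self) -> dict:
        d = asdict(self)
        return d


def load_config_file(path) -> dict:
    """Flat ``key = value`` config file; '#' starts a comment."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"bad config line: {line!r}")
        key, val = (t.strip() for t in line.split("=", 1))
        out[key] = val
    return out


def apply_config_overrides(config: SearchConfig, overrides: dict) -> SearchConfig:
    for key, val in overrides.items():
        if hasattr(config, key):
            current = getattr(config, key)
            if isinstance(current, bool):
                val = str(val).lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                val = int(val)
            elif isinstance(current, float):
                val = float(val)
            setattr(config, key, val)
        elif hasattr(config.extend, key):
            current = getattr(config.extend, key)
            typ = type(current)
            config.extend = replace(config.extend, **{key: typ(val)})
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return config


# ---------------------------------------------------------------------------
# index construction and serialization


def _pack_chunks(records, chunk_size: int):
    """Greedy file-order packing by residue count; a single sequence may
    exceed chunk_size on its own."""
    chunks, current, current_res = [], [], 0
    for rec in records:
        if current and current_res + len(rec.seq) > chunk_size:
            chunks.append(current)
            current, current_res = [], 0
        current.append(rec)
        current_res += len(rec.seq)
    if current:
        chunks.append(current)
    return chunks


def _tables_to_json(tables: ClusterTables) -> dict:
    return {
        "b_e": {str(h): ps for h, ps in sorted(tables.b_e.items())},
        "b_r": {str(h): [list(t) for t in rs] for h, rs in sorted(tables.b_r.items())},
        "b_m": {str(c): [list(t) for t in ms] for c, ms in sorted(tables.b_m.items())},
    }


def _tables_from_json(obj: dict) -> ClusterTables:
    return ClusterTables(
        b_e={int(h): list(ps) for h, ps in obj["b_e"].items()},
        b_r={int(h): [tuple(t) for t in rs] for h, rs in obj["b_r"].items()},
        b_m={int(c): [tuple(t) for t in ms] for c, ms in obj["b_m"].items()},
    )


def makedb(fasta_path, out_dir, config: SearchConfig | None = None) -> dict:
    """Build a search index from a protein FASTA under ``out_dir``."""
    if config is None:
        config = SearchConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(fasta_path, kind="protein")
    seen = set()
    for rec in records:
        if rec.id in seen:
            raise InputError(f"duplicate database id {rec.id!r}")
        seen.add(rec.id)

    alphabet = build_reduced_alphabet(matrix_name=config.matrix_name)
    sp, cp = config.seed_params(), config.cluster_params()
    chunks = _pack_chunks(records, config.chunk_size)
    chunk_files = []
    for ci, chunk_records in enumerate(chunks):
        db = build_concatenated_database(chunk_records)
        reduced = reduce_sequence(db.text, alphabet)
        entries = enumerate_db_seeds(reduced, alphabet, sp)
        payload = {
            "names": db.names,
            "sequences": [r.seq for r in chunk_records],
            "seeds": [[e.hash, e.pos, e.length] for e in entries],
        }
        if config.clustering_enabled:
            tables = cluster_subsequences(entries, reduced, cp)
            _assert_partition(tables, entries)
            payload["cluster_tables"] = _tables_to_json(tables)
        name = f"chunk_{ci:04d}.json"
        (out_dir / name).write_text(json.dumps(payload))
        chunk_files.append(name)

    manifest = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "n_sequences": len(records),
        "total_residues": sum(len(r.seq) for r in records),
        "chunk_files": chunk_files,
        "clustering": config.clustering_enabled,
        "params": {k: getattr(config, k) for k in INDEX_KEYS},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _assert_partition(tables: ClusterTables, entries: list[SeedEntry]) -> None:
    stored = sorted(tables.positions())
    expect = sorted(e.pos for e in entries)
    if stored != expect:
        raise AssertionError("cluster tables do not partition the seed entries")


@dataclass
class LoadedChunk:
    db: ConcatenatedDatabase
    reduced: object
    encoded: np.ndarray
    seeds: list[SeedEntry]
    tables: ClusterTables | None


def load_manifest(index_dir) -> dict:
    path = Path(index_dir) / "manifest.json"
    if not path.exists():
        raise InputError(f"no index manifest in {index_dir}")
    manifest = json.loads(path.read_text())
    if manifest.get("format") != INDEX_FORMAT or manifest.get("version") != INDEX_VERSION:
        raise InputError("unrecognized index format/version")
    return manifest


def load_chunk(index_dir, name: str, alphabet) -> LoadedChunk:
    payload = json.loads((Path(index_dir) / name).read_text())
    from .seqio import SequenceRecord

    records = [
        SequenceRecord(i, s, "protein")
        for i, s in zip(payload["names"], payload["sequences"])
    ]
    db = build_concatenated_database(records)
    reduced = reduce_sequence(db.text, alphabet)
    seeds = [SeedEntry(h, p, ln) for h, p, ln in payload["seeds"]]
    tables = None
    if "cluster_tables" in payload:
        tables = _tables_from_json(payload["cluster_tables"])
    return LoadedChunk(db, reduced, encode_protein(db.text), seeds, tables)


# ---------------------------------------------------------------------------
# search


@dataclass(frozen=True)
class ResultRow:
    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def to_tsv(self) -> str:
        return "\t".join(
            [
                self.query_id,
                self.subject_id,
                f"{self.pident:.2f}",
                str(self.length),
                str(self.mismatches),
                str(self.gap_openings),
                str(self.q_start),
                str(self.q_end),
                str(self.s_start),
                str(self.s_end),
                format_evalue(self.e_value),
                f"{self.bit_score:.1f}",
            ]
        )


def format_evalue(e: float) -> str:
    if e == 0.0:
        return "0.0"
    if e < 1e-3:
        s = f"{e:.0e}"
        mant, exp = s.split("e")
        return f"{mant}e{int(exp)}"
    return f"{e:.3g}"


def _query_frames(records, query_type: str):
    """Expand query records into protein frames.  DNA reads give six
    frames; protein queries are a single frame 0."""
    frames: list[TranslatedFrame] = []
    read_order: list[str] = []
    for rec in records:
        kind = rec.kind if query_type == "auto" else query_type
        read_order.append(rec.id)
        if kind == "dna":
            frames.extend(six_frame_translate(rec))
        else:
            frames.append(TranslatedFrame(rec.id, 0, rec.seq, 0))
    return frames, read_order


def _check_compat(manifest: dict, config: SearchConfig) -> None:
    for key in INDEX_KEYS:
        if manifest["params"][key] != getattr(config, key):
            raise ConfigError(
                f"index/config mismatch on {key!r}: index has "
                f"{manifest['params'][key]!r}, search config has "
                f"{getattr(config, key)!r}"
            )
    if config.clustering_enabled and not manifest["clustering"]:
        raise ConfigError("index was built without cluster tables; rerun makedb "
                          "or search with clustering disabled")


def search(
    query_path,
    index_dir,
    config: SearchConfig | None = None,
    counters: SearchCounters | None = None,
):
    """Search queries against a built index.

    Returns (rows, counters, timings).  Rows follow the 12-column BLAST
    tabular convention, sorted per query by ascending E-value (ties:
    descending bit score, then subject id), queries in input order.
    """
    if config is None:
        config = SearchConfig()
    if counters is None:
        counters = SearchCounters()
    timings: dict[str, float] = {}

    manifest = load_manifest(index_dir)
    _check_compat(manifest, config)
    total_residues = manifest["total_residues"]

    t0 = time.perf_counter()
    records = read_fasta(query_path, kind=None if config.query_type == "auto" else config.query_type)
    frames, read_order = _query_frames(records, config.query_type)
    alphabet = build_reduced_alphabet(matrix_name=config.matrix_name)
    reduced_frames = [reduce_sequence(f.protein, alphabet) for f in frames]
    encoded_frames = [encode_protein(f.protein) for f in frames]
    qtable = build_query_hash_table(reduced_frames, alphabet, config.seed_params())
    timings["query_prep"] = time.perf_counter() - t0

    cp = config.cluster_params()
    sm = build_score_matrix(config.matrix_name)
    per_chunk: list[list[tuple[str, str, GappedAlignment]]] = []
    t_seed_search = t_ungapped = t_gapped = 0.0
    for name in manifest["chunk_files"]:
        chunk = load_chunk(index_dir, name, alphabet)
        t0 = time.perf_counter()
        if config.clustering_enabled:
            seeds = list(
                s
                for s, _prov in seed_search(
                    qtable, chunk.tables, chunk.reduced, reduced_frames, cp, counters
                )
            )
        else:
            buckets: dict[int, list[int]] = {}
            for e in chunk.seeds:
                buckets.setdefault(e.hash, []).append(e.pos)
            seeds = [s for s, _ in direct_seed_search(qtable, buckets, counters)]
        t_seed_search += time.perf_counter() - t0

        t0 = time.perf_counter()
        hits = []
        for seed in seeds:
            counters.n_ungapped_extensions += 1
            hits.append(
                ungapped_extend(
                    encoded_frames[seed.query_frame_id], chunk.encoded, seed,
                    config.extend, sm,
                )
            )
        hits = chain_filter(hits)
        t_ungapped += time.perf_counter() - t0

        t0 = time.perf_counter()
        rows: list[tuple[str, str, GappedAlignment]] = []
        for hit in hits:
            if hit.score <= config.extend.t_ungapped:
                continue
            counters.n_gapped_extensions += 1
            aln = gapped_extend(
                encoded_frames[hit.query_frame_id], chunk.encoded, hit,
                config.extend, sm,
            )
            if aln is None:
                continue
            frame = frames[aln.query_frame_id]
            aln.bit_score, aln.e_value = compute_statistics(
                aln.raw_score, len(frame.protein), total_residues, config.extend
            )
            si, local = chunk.db.locate(aln.db_start)
            s_start = local + 1  # 1-based inclusive
            s_end = aln.db_end - chunk.db.offsets[si]
            rows.append((frame.read_id, chunk.db.names[si], aln, s_start, s_end))
        per_chunk.append(rows)
        t_gapped += time.perf_counter() - t0

    timings.update(seed_search=t_seed_search, ungapped=t_ungapped, gapped=t_gapped)
    merged = merge_chunk_results(per_chunk, config.max_hsps)
    out_rows = _format_rows(merged, frames, read_order, config)
    return out_rows, counters, timings


def _aln_sort_key(item):
    read_id, subject_id, aln = item[0], item[1], item[2]
    return (aln.e_value, -aln.bit_score, subject_id, aln.query_frame_id, aln.q_start)


def merge_chunk_results(
    per_chunk: list[list[tuple[str, str, GappedAlignment]]], max_hsps: int = 1
) -> dict[tuple[str, str], list[tuple[str, str, GappedAlignment]]]:
    """Merge per-chunk alignments keeping, per (query, subject) pair, the
    ``max_hsps`` best by E-value (each subject lives in exactly one chunk,
    so a pair never spans chunks)."""
    best: dict[tuple[str, str], list] = {}
    for rows in per_chunk:
        for item in rows:
            key = (item[0], item[1])
            best.setdefault(key, []).append(item)
    for key, items in best.items():
        items.sort(key=_aln_sort_key)
        dedup, seen = [], set()
        for item in items:
            aln = item[2]
            sig = (aln.query_frame_id, aln.q_start, aln.q_end, aln.db_start, aln.db_end)
            if sig in seen:
                continue
            seen.add(sig)
            dedup.append(item)
        best[key] = dedup[:max_hsps]
    return best


def _format_rows(merged, frames, read_order, config) -> list[ResultRow]:
    rows: list[ResultRow] = []
    for (read_id, subject_id), items in merged.items():
        for _rid, _sid, aln, s_start, s_end in items:
            if aln.e_value > config.evalue_cutoff:
                continue
            frame = frames[aln.query_frame_id]
            if frame.frame == 0:
                q_start, q_end = aln.q_start + 1, aln.q_end
            else:
                q_start, q_end = to_dna_coords(frame, aln.q_start, aln.q_end)
            pident = 100.0 * aln.identities / aln.aligned_length if aln.aligned_length else 0.0
            rows.append(
                ResultRow(
                    read_id, subject_id, round(pident, 2), aln.aligned_length,
                    aln.mismatches, aln.gap_openings, q_start, q_end,
                    s_start, s_end, aln.e_value, round(aln.bit_score, 1),
                )
            )
    order = {rid: i for i, rid in enumerate(read_order)}
    rows.sort(
        key=lambda r: (
            order[r.query_id], r.e_value, -r.bit_score, r.subject_id, r.s_start,
        )
    )
    return rows


def write_tabular(rows: list[ResultRow], path) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(row.to_tsv() + "\n")


def write_stats(counters: SearchCounters, timings: dict, config: SearchConfig, path) -> None:
    payload = {
        "counters": counters.as_dict(),
        "timings_seconds": {k: round(v, 6) for k, v in timings.items()},
        "config": config.effective_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
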