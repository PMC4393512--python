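# seedclust

Translated protein homology search accelerated by database subsequence
clustering and triangle-inequality seed filtering.

`seedclust` is a BLASTX-like seed-and-extend search tool aimed at the
metagenomic annotation setting: large volumes of short DNA reads
(100–1000 bp) searched against a large, highly redundant protein reference
database. Reads are translated in all six frames and aligned to database
proteins; the expensive part of such searches is not the final gapped
alignment but the enormous number of candidate seeds that must be
ungapped-extended. `seedclust` attacks that bottleneck in two ways:

1. **Long, score-thresholded seeds in a reduced amino acid alphabet.**
   Both query and database are re-encoded in a 10-group alphabet
   (A, {K,R}, {E,D,N,Q}, C, G, H, {I,L,V,M}, {F,Y,W}, P, {S,T}) derived
   from BLOSUM62. Each group scores the maximum BLOSUM62 self-score of its
   members, and a seed window starting at a position takes the smallest
   length in 6–8 residues whose summed group score exceeds *T*seed
   (default 39). For example, `HDGLNP` scores 8+6+6+5+6+7 = 38 and is
   rejected, while `HDGLNPA` scores 42 and seeds at length 7. Windows are
   hashed with a perfect (injective) hash, so a seed is simply an exact
   hash match between a query window and a database window.

2. **Clustering database subsequences and pruning seeds by the triangle
   inequality.** Around every database seed start *i*, a window
   *C*ᵢ = *D*[*i*−*L*/2, *i*+*L*/2] (default *L* = 10) is clustered
   greedily under Hamming distance *d* within each seed-hash bucket: a
   window joins the first representative *R* with *d*(*C*, *R*) ≤
   *T*cluster (default 0.1 *L*), else founds a new cluster. At search
   time the distance *d*(*C*Q, *R*) to each representative is computed
   once; for every member *M* with stored distance *d*(*R*, *M*), the
   triangle inequality gives the lower bound

   *d*(*C*Q, *M*) ≥ *d*(*C*Q, *R*) − *d*(*R*, *M*)

   and the member's seed is extended only when that bound is ≤
   *T*distance (default 0.2 *L*). The bound is lossless: no member whose
   true distance is within the threshold is ever skipped.

Surviving seeds are ungapped-extended along their diagonal with a BLAST-style
X-drop cutoff, merged by chain filtering, and — when the ungapped score
exceeds *T*ungapped — gapped-extended with a score-limited (X-drop) affine-gap
dynamic program. Alignments are scored with BLOSUM62 (gap open 11, extend 1)
in the original 20-letter alphabet and reported with Karlin–Altschul
statistics, bits = (λ·S − ln K)/ln 2 and E = K·m·n·e^(−λS), in the 12-column
BLAST tabular format. The database can be split into chunks that are indexed
and searched independently; E-values always use the total database size, so
chunking never changes the output.

## Worked example

Generate a small redundant database (4 families × 3 members) and 10
error-free reads from it, then index and search:

```sh
seedclust-fixtures families --n-families 4 --members 3 --length 100 --seed 3 \
    -o fam.fasta --truth fam.tsv
seedclust-fixtures reads --db fam.fasta --n-reads 10 --seed 4 -o r.fasta
seedclust makedb -i fam.fasta -o idx
seedclust search -q r.fasta -d idx -o out.tsv --stats stats.json
head -3 out.tsv
```

```
read0	fam2_m2	100.00	50	0	0	1	150	49	98	6e-31	116.3
read0	fam2_m0	88.00	50	6	0	1	150	49	98	4e-25	97.1
read0	fam2_m1	88.00	50	6	0	1	150	49	98	6e-25	96.3
```

`read0` was simulated from `fam2_m2` and maps back to it at 100% identity
over the full 50-residue translation (query coordinates 1–150 are DNA
positions on the read; subject coordinates 49–98 are protein positions),
with the two other family members following at 88% identity and larger
E-values. `stats.json` records the instrumentation counters, e.g.

```
{'n_seeds_examined': 869, 'n_similarity_filterings': 242,
 'n_ungapped_extensions': 868, 'n_gapped_extensions': 30,
 'n_member_bound_checks': 356}
```

`n_similarity_filterings` counts query-to-representative distance
computations — the quantity to add to `n_ungapped_extensions` when judging
what clustering saves. Compare with `--no-clustering` (or an index built
with `seedclust makedb --no-clustering`) to see the unclustered flow, which
must produce identical rows when `--t-distance` is set to *L*.

## Layout

- `src/seedclust/alphabet.py` — reduced alphabet, encoding, seed scoring
- `src/seedclust/seqio.py` — FASTA, six-frame translation, concatenated database text
- `src/seedclust/seed_index.py` — seed selection, perfect hashing, hash tables
- `src/seedclust/cluster_index.py` — greedy window clustering, B_e/B_r/B_m tables
- `src/seedclust/search_filter.py` — seed search and triangle-inequality filtering
- `src/seedclust/extend_align.py` — ungapped/gapped X-drop extension, statistics
- `src/seedclust/pipeline.py` — chunked index build, search orchestration, output
- `src/seedclust/fixtures.py` — synthetic families/reads with truth tables
- `docs/methods.md` — models, parameters, numerical choices, limitations
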