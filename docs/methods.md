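# Methods

This note documents the models, parameter choices and numerical decisions
behind `seedclust`, and what the synthetic-data tests do and do not show.

## Search model

`seedclust` is a seed-and-extend translated homology search. DNA reads are
translated in six frames with the standard codon table (stop codons as
`*`, ambiguous codons as `X`) and each frame is searched as an independent
protein pseudo-query; protein queries are searched directly. Database
proteins are concatenated into one text `#D0#D1#...#DN-1#` whose `#`
delimiters no seed, cluster window, or extension may cross.

### Seeding in a reduced alphabet

Seeding operates in a 10-group reduction of the 20 standard residues
(A, {K,R}, {E,D,N,Q}, C, G, H, {I,L,V,M}, {F,Y,W}, P, {S,T}) derived from
BLOSUM62. A group's match score is the largest BLOSUM62 self-score among
its members (e.g. {F,Y,W} scores 11, from W). A seed window at position
*p* takes the smallest length in [6, 8] whose group scores sum strictly
above `t_seed` (default 39); one seed per start position. Strictness
follows from treating the threshold as an exclusion bound ("exceeds");
a config flag (`strict`) allows `>=` instead. Windows containing a
delimiter or any non-standard residue (`X`, `B`, `Z`, `*`, ...) never
seed — a conservative policy for ambiguity codes, chosen because nothing
else is defensible without knowing what the ambiguity hides. Length 6–8
keeps the perfect hash small: the hash is the base-10 positional code of
the group symbols plus a per-length offset (0, 10^6, 1.1×10^7), which is
injective over (length, window). Any injective encoding would do; this
one is trivially reversible, which the tests exploit. Hash tables are
ordinary sorted associative maps, not dense arrays.

### Clustering and similarity filtering

Around every database seed start *i* the clustering window is the
length-`L` window centred on *i* (`L` = 10, even by construction since the
window spans *i*−*L*/2 to *i*+*L*/2). Windows that would cross a delimiter
or run past the text ends are not clustered; their seeds always extend
(conservative: costs extensions, never sensitivity). Within each seed-hash
bucket, positions are visited in ascending order and clustered greedily:
the first window founds a cluster; a later window joins the
earliest-created representative within Hamming distance `t_cluster`
(default 0.1·L = 1), else founds its own cluster. First-fit tie-breaking
makes the build deterministic; the composition depends on visit order but
the radius bound (member-to-representative distance ≤ `t_cluster`) does
not, and that bound is what correctness rests on. Clusters that end the
pass with no members collapse into the singleton table. The result is
three tables: `b_e` (singletons — extended directly), `b_r`
(hash → representatives) and `b_m` (cluster → members with their exact
stored distance to the representative).

At search time, the query-side window is built exactly like the database
one (length `L` centred on the seed start). For each matching
representative the distance d(C_Q, R) is computed once; each member M is
then admitted iff d(C_Q, R) − d(R, M) ≤ `t_distance` (default 0.2·L = 2,
non-strict). By the triangle inequality this lower-bounds the true
d(C_Q, M), so no member within `t_distance` of the query window is ever
lost — the filter only prunes provably distant candidates. Storing each
member's exact distance (rather than bounding it by `t_cluster`) makes
the bound as tight as the inequality allows. When the query window
overruns the frame, filtering is bypassed and all members pass
(conservative pass-through). With `t_distance = L` the filter passes
everything and the clustered flow reproduces the unclustered output
byte-for-byte — a property the acceptance suite checks end-to-end.

### Cost accounting

The counters reflect a cost model in which computing one Hamming distance
over an `L`-residue window costs about as much as one short ungapped
extension, while the per-member lower-bound test is a constant-time
subtraction. `n_similarity_filterings` therefore counts
query-to-representative distance computations; `n_member_bound_checks`
counts the cheap per-member tests separately. The quantity
`n_similarity_filterings + n_ungapped_extensions` under clustering versus
`n_ungapped_extensions` without it measures what clustering buys. The
saving materialises when seed matches land in multi-member clusters whose
members are then pruned — the typical situation for metagenomic queries
against a redundant reference, where most seed matches are chance matches.
The acceptance test reproduces this regime with reads simulated from
novel sequences searched against a 20-family × 20-member database; with
reads drawn from the database itself nearly every member passes the
filter and clustering cannot save work (it adds the representative
distance computations), which is expected behaviour, not a defect.

### Extension and statistics

Alignment always scores in the original 20-letter alphabet with BLOSUM62.
`*` (stop) is a hard mismatch: −4 against everything, including itself,
so frames containing stops are searched whole rather than split into
ORFs, and alignments simply avoid crossing stops. Ungapped extension
proceeds independently left and right along the seed diagonal, keeping
the best prefix/suffix and stopping a direction when the running score
falls more than `x_drop_ungapped` below its best; with the cutoff
disabled this equals the exhaustive best containing sub-segment, which is
how it is tested. Overlapping hits on the same (frame, diagonal) are
chain-filtered keeping the highest-scoring one.

Hits scoring above `t_ungapped` are gapped-extended: the anchor is the
highest-scoring single column of the hit (leftmost on ties — a
deterministic choice the results are insensitive to at infinite X-drop),
and an affine-gap DP (gap of length k costs `gap_open` + k·`gap_extend`
= 11 + k) extends left and right, pruning cells more than `x_drop_gapped`
below the running best. With pruning disabled the result equals an
anchored local-alignment DP, and equals full Smith–Waterman whenever the
optimum passes through the anchor; both are asserted against independent
plain-DP oracles, themselves cross-checked against Biopython's
`PairwiseAligner` in local mode.
The DP inner loop is JIT-compiled with numba; everything else is
numpy/pure Python.

Raw thresholds default to BLAST-style bit cutoffs converted through the
Karlin–Altschul parameters: ungapped λ = 0.3176, K = 0.134, gapped
λ = 0.267, K = 0.041; `x_drop_ungapped` = ⌈7 bits·ln2/λu⌉ = 16,
`x_drop_gapped` = ⌈15 bits·ln2/λg⌉ = 39, `t_ungapped` = raw score of
22 bits = 42. These are stated approximations of classic BLASTX defaults,
all overridable in config. E-values use plain Karlin–Altschul
(E = K·m·n·e^(−λS), m = frame length, n = total database residues, no
composition-based or sum statistics) and bit scores
(λS − ln K)/ln 2. Reported per (read, subject) pair is the single best
alignment across all six frames (`--max-hsps` raises the limit);
rows are sorted per query by ascending E-value, ties broken by
descending bit score then subject id, so output is byte-deterministic.

### Chunking

`makedb` packs sequences greedily in file order into chunks of at most
`chunk_size` residues (a single oversized sequence stands alone), indexes
each chunk independently, and records the total residue count in the
manifest. Because E-values always use that total, and per-chunk results
are merged keeping the best alignment per (read, subject) — each subject
living in exactly one chunk — chunked and unchunked builds produce
identical output; only memory and cache behaviour differ. The index is
serialized as versioned JSON (`manifest.json` + `chunk_NNNN.json` with
sequences, seed entries and cluster tables); rebuilds are bit-for-bit
reproducible. Pre-sorting the database so similar sequences are adjacent
(e.g. with CD-HIT) improves cluster sizes and is recommended but not
performed; it affects speed, not correctness.

## Synthetic data

The generator emulates two things: reference-database redundancy
(families = an i.i.d.-uniform ancestor protein plus members with uniform
point substitutions — so a fraction 19/20 of substitution draws change
the residue — and optional single-residue indels) and shotgun reads
(windows reverse-translated with uniform codon choice, random strand,
uniform base errors). Truth tables record family membership and read
provenance, so top-hit accuracy is scored exactly against the generator
rather than by SSEARCH-style rescoring. Defaults (20 families × 20
members × 300 residues, 5% substitution, 150 bp error-free reads) are
desk-scale stand-ins for the redundancy of real protein references and
for short metagenomic reads.

What the passing tests show: the algorithmic contracts hold — lossless
filtering, clustered/unclustered equivalence at the degenerate threshold,
chunking invariance, oracle-exact extension, ≥95% self-mapping, and a
strict extension-work reduction under redundancy with novel queries.
What they do not show: sensitivity/speed on real data. Real proteomes
have biased residue composition, domain structure and low-complexity
regions (no masking is implemented here); real read errors are
quality- and position-dependent; and the measured work reduction depends
strongly on database redundancy and query novelty, so the ratio observed
on the synthetic setup does not transfer to any particular real database.

## Known limitations

- Single-threaded; index build is the slow path on large inputs.
- No composition-based statistics, no sum statistics for multiple HSPs,
  no low-complexity masking, no two-hit seeding, standard codon table only.
- The `t_ungapped` raw default approximates BLAST's; reported hits with
  very weak E-values (> 1e−3) are sensitive to that choice.
- Greedy clustering composition depends on database order; only the
  member-radius bound is order-invariant.
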