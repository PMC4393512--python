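"""Deterministic synthetic data: redundant protein families and DNA reads
with known provenance.

The family generator emulates the redundancy that makes database
subsequence clustering effective: each family is an i.i.d. ancestor
protein plus members derived by point substitutions (replacement drawn
uniformly over the 20 residues, so a fraction 19/20 of draws actually
change the residue) and single-residue indels.  The read generator
reverse-translates random database windows (uniform codon choice, random
strand) into DNA with optional base errors.  Truth tables record every
member's family and every read's source, position and strand, so top-hit
accuracy can be scored exactly.  Identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .alphabet import STANDARD_RESIDUES
from .seqio import SequenceRecord

_RESIDUES = np.array(list(STANDARD_RESIDUES))
_CODONS_OF = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_OF.setdefault(_aa, []).append(_codon)
_CODONS_OF = {aa: sorted(cs) for aa, cs in _CODONS_OF.items()}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class FamilySpec:
    n_families: int = 20
    members_per_family: int = 20
    seq_length: int = 300
    substitution_rate: float = 0.05
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_families, self.members_per_family, self.seq_length) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ValueError("rates must be in [0, 1]")


def generate_protein_families(
    spec: FamilySpec, residue_freqs: np.ndarray | None = None
) -> tuple[list[SequenceRecord], list[dict]]:
    """Generate ``n_families * members_per_family`` protein records plus a
    truth table (one dict per member: ids, family, edit counts).

    ``residue_freqs`` optionally biases ancestor composition (length-20
    vector over ARNDCQEGHILKMFPSTWYV); the default is uniform, which
    keeps analytic expectations simple.
    """
    rng = np.random.default_rng(spec.seed)
    if residue_freqs is not None:
        residue_freqs = np.asarray(residue_freqs, dtype=float)
        residue_freqs = residue_freqs / residue_freqs.sum()
    records, truth = [], []
    for f in range(spec.n_families):
        ancestor = rng.choice(_RESIDUES, size=spec.seq_length, p=residue_freqs)
        for m in range(spec.members_per_family):
            member = ancestor.copy()
            sub_mask = rng.random(len(member)) < spec.substitution_rate
            n_subs = int(sub_mask.sum())
            if n_subs:
                member[sub_mask] = rng.choice(_RESIDUES, size=n_subs)
            seq = list(member)
            n_indels = 0
            if spec.indel_rate > 0:
                indel_mask = rng.random(len(seq)) < spec.indel_rate
                for pos in np.nonzero(indel_mask)[0][::-1]:  # right-to-left
                    n_indels += 1
                    if rng.random() < 0.5 and len(seq) > 1:
                        del seq[pos]
                    else:
                        seq.insert(int(pos), str(rng.choice(_RESIDUES)))
            rec_id = f"fam{f}_m{m}"
            records.append(SequenceRecord(rec_id, "".join(seq), "protein"))
            truth.append(
                {
                    "id": rec_id,
                    "family": f,
                    "member": m,
                    "n_substitution_draws": n_subs,
                    "n_indels": n_indels,
                }
            )
    return records, truth


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """DNA encoding a protein, choosing uniformly among synonymous codons."""
    return "".join(rng.choice(_CODONS_OF[aa]) for aa in protein)


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def generate_reads(
    db_records: list[SequenceRecord],
    read_length: int = 150,
    n_reads: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Simulate DNA reads from random positions/strands of the database.

    Reads are reverse-translated protein windows of ``read_length // 3``
    residues (plus random padding bases if read_length is not a codon
    multiple); base errors are uniform substitutions to a different base.
    Sources shorter than the protein window are skipped.
    """
    if read_length < 30:
        raise ValueError("read_length must be >= 30")
    aa_len = read_length // 3
    rng = np.random.default_rng(seed)
    eligible = [r for r in db_records if len(r.seq) >= aa_len and "*" not in r.seq]
    if not eligible:
        raise ValueError("no database sequence long enough for the read length")
    bases = np.array(list("ACGT"))
    reads, truth = [], []
    for i in range(n_reads):
        src = eligible[int(rng.integers(len(eligible)))]
        start = int(rng.integers(len(src.seq) - aa_len + 1))
        window = src.seq[start : start + aa_len]
        dna = reverse_translate(window, rng)
        pad = read_length - len(dna)
        if pad:
            dna += "".join(rng.choice(bases, size=pad))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = revcomp(dna)
        if error_rate > 0:
            arr = np.array(list(dna))
            err_mask = rng.random(len(arr)) < error_rate
            for pos in np.nonzero(err_mask)[0]:
                choices = [b for b in "ACGT" if b != arr[pos]]
                arr[pos] = choices[int(rng.integers(3))]
            dna = "".join(arr)
        rid = f"read{i}"
        reads.append(SequenceRecord(rid, dna, "dna"))
        truth.append(
            {
                "read_id": rid,
                "source_id": src.id,
                "protein_start": start,
                "strand": strand,
            }
        )
    return reads, truth


def write_truth_table(truth: list[dict], path) -> None:
    """TSV dump of a truth table (columns from the first row's keys)."""
    if not truth:
        raise ValueError("empty truth table")
    cols = list(truth[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in truth:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
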