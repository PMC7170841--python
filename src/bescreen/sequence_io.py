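"""Reference sequences, gene models and strand/codon arithmetic.

Coordinates are 0-based half-open everywhere inside the package; any
human-readable report converts to 1-based inclusive at the edge.  A gene is
a list of CDS intervals given in *transcription* order, so for a minus-strand
gene the first interval is the one with the highest genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

CDS_CLASSES = frozenset({"essential", "high_effect", "no_effect"})
TARGET_CLASSES = CDS_CLASSES | {"intron", "putative_peptide"}

#: Deletion-fitness cutoffs used to derive a target class from a score:
#: below 0.75 → high_effect; within [0.999, 1.001] → no_effect.
HIGH_EFFECT_CUTOFF = 0.75
NO_EFFECT_BAND = (0.999, 1.001)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceIOError(ValueError):
    """Malformed reference input (FASTA or gene table)."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise SequenceIOError(f"non-ACGTN base(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds_seq: str) -> str:
    """Translate an in-frame CDS with the standard code; stops render as '*'."""
    cds_seq = cds_seq.upper()
    if len(cds_seq) % 3 != 0:
        raise SequenceIOError(f"CDS length {len(cds_seq)} is not a multiple of 3")
    bad = set(cds_seq) - set("ACGT")
    if bad:
        raise SequenceIOError(f"ambiguous base(s) in CDS: {sorted(bad)}")
    return str(Seq(cds_seq).translate())


@dataclass
class GeneModel:
    """A coding (or intronic/putative-peptide) locus targeted by the screen.

    ``fitness_score`` is the deletion-fitness of the gene averaged across
    media and replicates, on a scale where 1.0 means wild-type growth.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    target_class: str
    fitness_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SequenceIOError(f"{self.gene_id}: strand must be + or -")
        if self.target_class not in TARGET_CLASSES:
            raise SequenceIOError(
                f"{self.gene_id}: unknown target_class {self.target_class!r}"
            )
        ivs = [(int(s), int(e)) for s, e in self.cds_intervals]
        for s, e in ivs:
            if not 0 <= s < e:
                raise SequenceIOError(f"{self.gene_id}: bad interval ({s},{e})")
        genomic = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise SequenceIOError(f"{self.gene_id}: overlapping CDS intervals")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if ivs != expect:
            raise SequenceIOError(
                f"{self.gene_id}: intervals not in transcription order"
            )
        self.cds_intervals = ivs
        if self.target_class in CDS_CLASSES and self.cds_length % 3 != 0:
            raise SequenceIOError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all intervals."""
        return (min(s for s, _ in self.cds_intervals),
                max(e for _, e in self.cds_intervals))

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS on the coding strand."""
        parts = []
        for s, e in self.cds_intervals:
            piece = chrom_seq[s:e]
            parts.append(piece if self.strand == "+" else revcomp(piece))
        return "".join(parts)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """0-based CDS index of genomic position ``pos``, or None if outside."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None

    def contains(self, pos: int) -> bool:
        return self.genomic_to_cds(pos) is not None


def target_class_from_score(fitness_score: float) -> str:
    """Derive a fitness class from a deletion-fitness score."""
    lo, hi = NO_EFFECT_BAND
    if fitness_score < HIGH_EFFECT_CUTOFF:
        return "high_effect"
    if lo <= fitness_score <= hi:
        return "no_effect"
    raise SequenceIOError(
        f"fitness score {fitness_score} maps to no class "
        f"(needs < {HIGH_EFFECT_CUTOFF} or within {NO_EFFECT_BAND})"
    )


@dataclass
class ReferenceSet:
    sequences: dict[str, str] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = set(seq) - set("ACGTN")
            if bad:
                raise SequenceIOError(f"{chrom}: non-ACGTN base(s) {sorted(bad)}")
        for gene in self.genes:
            if gene.chrom not in self.sequences:
                raise SequenceIOError(f"{gene.gene_id}: unknown chrom {gene.chrom}")
            n = len(self.sequences[gene.chrom])
            for s, e in gene.cds_intervals:
                if e > n:
                    raise SequenceIOError(
                        f"{gene.gene_id}: interval ({s},{e}) outside "
                        f"{gene.chrom} (length {n})"
                    )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {identifier: uppercase sequence}.

    Duplicate identifiers and empty files are hard errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise SequenceIOError(f"duplicate FASTA identifier {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise SequenceIOError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


GENE_TABLE_COLUMNS = [
    "gene_id", "chrom", "strand", "starts", "ends", "target_class",
    "fitness_score",
]


def load_gene_table(path, sequences: dict[str, str]) -> list[GeneModel]:
    """Load the TSV gene annotation table (0-based half-open coordinates).

    ``starts``/``ends`` are comma-separated interval bounds in transcription
    order.  When ``target_class`` is empty it is derived from
    ``fitness_score``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in GENE_TABLE_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise SequenceIOError(f"gene table missing column(s) {missing}")
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.starts).split(",")]
        ends = [int(x) for x in str(row.ends).split(",")]
        if len(starts) != len(ends):
            raise SequenceIOError(f"{row.gene_id}: starts/ends length mismatch")
        score_txt = str(getattr(row, "fitness_score", "")).strip()
        score = float(score_txt) if score_txt else None
        tclass = str(getattr(row, "target_class", "")).strip()
        if not tclass:
            if score is None:
                raise SequenceIOError(
                    f"{row.gene_id}: neither target_class nor fitness_score given"
                )
            tclass = target_class_from_score(score)
        gene = GeneModel(
            gene_id=str(row.gene_id),
            chrom=str(row.chrom),
            strand=str(row.strand),
            cds_intervals=list(zip(starts, ends)),
            target_class=tclass,
            fitness_score=score,
        )
        genes.append(gene)
    ref = ReferenceSet(sequences=sequences, genes=genes)
    ref.validate()
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "starts": ",".join(str(s) for s, _ in g.cds_intervals),
            "ends": ",".join(str(e) for _, e in g.cds_intervals),
            "target_class": g.target_class,
            "fitness_score": "" if g.fitness_score is None else g.fitness_score,
        })
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def load_reference(fasta_path, gene_table_path) -> ReferenceSet:
    sequences = read_fasta(fasta_path)
    genes = load_gene_table(gene_table_path, sequences)
    return ReferenceSet(sequences=sequences, genes=genes)
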