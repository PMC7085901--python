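"""Exon-resolved gene models, transcript splicing and exhaustive junction libraries.

Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3 on
disk.  Exons are kept in transcript (5'->3') orientation: for a minus-strand
gene, exon 1 is the exon with the *largest* genomic coordinate and its
sequence is the reverse complement of the genomic slice.

A junction library contains, for every gene, one entry per *ordered* exon
pair (i < j) — consecutive and skipping pairs alike — so that any
exon-skipping event inside the annotated exon set leaves a diagnostic
junction-spanning read signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO


__all__ = [
    "GenomicInterval",
    "GeneModel",
    "TranscriptModel",
    "TranscriptSequence",
    "JunctionSpec",
    "JunctionLibrary",
    "read_genome",
    "read_gene_annotation",
    "write_gene_annotation",
    "write_genome",
    "splice",
    "enumerate_junctions",
    "canonical_junction_set",
    "extract_subgenome",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default junction flank: one base less than the read length, so that any
#: read overlapping a junction breakpoint at all is fully contained in the
#: junction sequence.  Reads overlapping by less than the counting step's
#: ``min_overlap`` still never support a junction — breakpoint coverage is
#: checked explicitly there — but they are not lost during read filtering.
DEFAULT_FLANK = 149


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval on a named sequence."""

    sequence_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.sequence_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def extract(self, genome: Mapping[str, str]) -> str:
        """Strand-aware sequence of this interval (revcomp on minus)."""
        if self.sequence_id not in genome:
            raise KeyError(f"sequence {self.sequence_id!r} absent from genome")
        raw = genome[self.sequence_id][self.start : self.end]
        return reverse_complement(raw) if self.strand == "-" else raw


@dataclass
class GeneModel:
    """A gene as an ordered list of exons in transcript orientation.

    ``intervals[0]`` is exon 1 (the 5'-most exon of the mRNA), regardless of
    genomic strand.
    """

    gene_id: str
    intervals: list[GenomicInterval]
    family_id: str = ""

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        strands = {iv.strand for iv in self.intervals}
        if len(strands) != 1:
            raise ValueError(f"gene {self.gene_id}: mixed strands")
        sorted_genomic = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(sorted_genomic, sorted_genomic[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expect = sorted_genomic if self.strand == "+" else sorted_genomic[::-1]
        if list(self.intervals) != expect:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcript orientation"
            )

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.intervals)

    @property
    def sequence_id(self) -> str:
        return self.intervals[0].sequence_id

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first to last exon (introns included)."""
        start = min(iv.start for iv in self.intervals)
        end = max(iv.end for iv in self.intervals)
        return GenomicInterval(self.sequence_id, start, end, self.strand)

    def exon_sequence(self, index: int, genome: Mapping[str, str]) -> str:
        """Sequence of exon ``index`` (1-based, transcript orientation)."""
        if not 1 <= index <= self.n_exons:
            raise IndexError(
                f"gene {self.gene_id}: exon index {index} out of range 1..{self.n_exons}"
            )
        return self.intervals[index - 1].extract(genome)

    def exon_length(self, index: int) -> int:
        return len(self.intervals[index - 1])


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as a strictly increasing subset of a gene's exon numbers."""

    transcript_id: str
    gene_id: str
    exon_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.exon_indices
        if not idx:
            raise ValueError(f"{self.transcript_id}: no exons")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"{self.transcript_id}: exon indices not increasing")

    @property
    def skipped_exons(self) -> tuple[int, ...]:
        """Exon numbers absent between the first and last retained exon."""
        full = set(range(self.exon_indices[0], self.exon_indices[-1] + 1))
        return tuple(sorted(full - set(self.exon_indices)))


@dataclass(frozen=True)
class TranscriptSequence:
    transcript_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.transcript_id}: non-nucleotide letters {bad}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class JunctionSpec:
    """One exon-pair junction: upstream-exon suffix joined to downstream-exon prefix."""

    gene_id: str
    upstream_exon: int
    downstream_exon: int
    sequence: str
    breakpoint_offset: int  # bases contributed by the upstream exon

    def __post_init__(self) -> None:
        if self.upstream_exon >= self.downstream_exon:
            raise ValueError("upstream exon must precede downstream exon")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.gene_id, self.upstream_exon, self.downstream_exon)

    @property
    def is_canonical(self) -> bool:
        return self.downstream_exon == self.upstream_exon + 1


@dataclass
class JunctionLibrary:
    junctions: list[JunctionSpec]
    flank: int

    def __post_init__(self) -> None:
        keys = [j.key for j in self.junctions]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (gene, upstream, downstream) junction keys")

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions)

    def for_gene(self, gene_id: str) -> list[JunctionSpec]:
        return [j for j in self.junctions if j.gene_id == gene_id]

    def write_fasta(self, path: str | Path) -> None:
        """Write as FASTA with headers ``geneID|up|down|offset``."""
        with open(path, "w") as fh:
            for j in self.junctions:
                fh.write(
                    f">{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}"
                    f"|{j.breakpoint_offset}\n{j.sequence}\n"
                )

    @classmethod
    def read_fasta(cls, path: str | Path, flank: int) -> "JunctionLibrary":
        juncs = []
        for rec in SeqIO.parse(str(path), "fasta"):
            gene, up, down, offset = rec.id.split("|")
            juncs.append(
                JunctionSpec(gene, int(up), int(down), str(rec.seq), int(offset))
            )
        return cls(juncs, flank)


# ---------------------------------------------------------------------------
# I/O


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict (uppercased)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def write_genome(genome: Mapping[str, str], fasta_path: str | Path, width: int = 70) -> None:
    with open(fasta_path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gene_annotation(
    gff_path: str | Path,
    fasta_path: str | Path | None = None,
    family_prefix: str = "",
    *,
    genome: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Load gene models from GFF3, keeping genes whose id starts with ``family_prefix``.

    Exon features are grouped by their parent gene, sorted genomically, and
    re-ordered into transcript orientation for minus-strand genes.  Genes with
    no exon features are skipped with a warning.  A referenced sequence id
    missing from the companion FASTA is fatal.
    """
    if genome is None and fasta_path is not None:
        genome = read_genome(fasta_path)
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        if family_prefix and not gene_id.startswith(family_prefix):
            continue
        exons = list(db.children(gene, featuretype="exon"))
        if not exons:
            warnings.warn(f"gene {gene_id}: no exon features, skipped")
            continue
        if genome is not None and gene.seqid not in genome:
            raise KeyError(
                f"gene {gene_id}: sequence {gene.seqid!r} missing from genome FASTA"
            )
        ivs = sorted(
            (
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in exons
            ),
            key=lambda iv: iv.start,
        )
        if gene.strand == "-":
            ivs = ivs[::-1]
        family = gene.attributes.get("gene_family", [family_prefix])[0]
        models.append(GeneModel(gene_id, ivs, family_id=family))
    return models


def write_gene_annotation(
    genes: Iterable[GeneModel], gff_path: str | Path, source: str = "spliceoform"
) -> None:
    """Write gene + exon features as GFF3 (1-based inclusive)."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            attrs = f"ID={g.gene_id}"
            if g.family_id:
                attrs += f";gene_family={g.family_id}"
            fh.write(
                f"{g.sequence_id}\t{source}\tgene\t{span.start + 1}\t{span.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for num, iv in enumerate(g.intervals, start=1):
                fh.write(
                    f"{iv.sequence_id}\t{source}\texon\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\tID={g.gene_id}.exon{num};"
                    f"Parent={g.gene_id};exon_number={num}\n"
                )


# ---------------------------------------------------------------------------
# Core operations


def splice(
    gene: GeneModel,
    exon_indices: Sequence[int],
    genome: Mapping[str, str],
    transcript_id: str | None = None,
) -> TranscriptSequence:
    """Concatenate the named exons (1-based, strictly increasing) into an mRNA."""
    if not exon_indices:
        raise ValueError(f"gene {gene.gene_id}: no exons requested")
    if any(b <= a for a, b in zip(exon_indices, exon_indices[1:])):
        raise ValueError(
            f"gene {gene.gene_id}: exon indices must be strictly increasing"
        )
    parts = [gene.exon_sequence(i, genome) for i in exon_indices]
    if transcript_id is None:
        transcript_id = f"{gene.gene_id}_ex{'-'.join(map(str, exon_indices))}"
    return TranscriptSequence(transcript_id, "".join(parts))


def canonical_junction_set(gene: GeneModel) -> set[tuple[int, int]]:
    """The consecutive exon pairs {(i, i+1)} present in the full-length mRNA."""
    return {(i, i + 1) for i in range(1, gene.n_exons)}


def enumerate_junctions(
    genes: Iterable[GeneModel],
    flank: int,
    genome: Mapping[str, str],
) -> JunctionLibrary:
    """Build the all-combinations junction library.

    For every ordered exon pair (i < j) of every gene the junction sequence is
    the last ``flank`` bases of exon i followed by the first ``flank`` bases of
    exon j, clipped at exon boundaries for short exons.  A gene with n exons
    therefore contributes n(n-1)/2 junctions.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    juncs: list[JunctionSpec] = []
    for gene in genes:
        exon_seqs = [gene.exon_sequence(i, genome) for i in range(1, gene.n_exons + 1)]
        for i in range(1, gene.n_exons + 1):
            for j in range(i + 1, gene.n_exons + 1):
                up = exon_seqs[i - 1][-flank:]
                down = exon_seqs[j - 1][:flank]
                juncs.append(
                    JunctionSpec(gene.gene_id, i, j, up + down, len(up))
                )
    return JunctionLibrary(juncs, flank)


def extract_subgenome(
    genome: Mapping[str, str], keep_ids: Sequence[str]
) -> dict[str, str]:
    """Subset a sequence set to ``keep_ids``, preserving the listed order."""
    if not keep_ids:
        raise ValueError("keep_ids must be non-empty")
    missing = [k for k in keep_ids if k not in genome]
    if missing:
        raise KeyError(f"sequence id(s) not in genome: {missing}")
    return {k: genome[k] for k in keep_ids}
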