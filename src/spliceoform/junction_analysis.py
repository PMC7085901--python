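"""Two-step junction-mapping workflow: filter, count, call, quantify.

The workflow mirrors a sub-genome junction screen: (1) reduce the read set to
reads placing on any gene region of the family of interest (or on any
junction sequence, which catches junction-spanning reads that no contiguous
genomic region contains); (2) map the reduced set against the
all-combinations exon-junction library and count reads that cover the
breakpoint by at least ``min_overlap`` bases on both sides; (3) call
exon-skipping transcripts from supported non-canonical junctions; (4) turn
junction counts into per-transcript abundance estimates.

Alignment is deliberately simple and fully specified so that an exhaustive
all-offsets scan can verify it: an exact seed of ``seed_length`` bases
anchored at every read offset, extended ungapped over the full read with at
most ``max_mismatches`` mismatches, both orientations, no indels.  Because a
read of length L with m mismatches always contains an exact run of at least
(L - m) / (m + 1) bases, the seed step loses nothing whenever
L >= (m + 1) * seed_length + m, which holds for the defaults (150 bp reads,
20 bp seeds, 2 mismatches).  An ``N`` in either read or reference never
matches anything, itself included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .gene_models import (
    GeneModel,
    JunctionLibrary,
    TranscriptModel,
    canonical_junction_set,
    reverse_complement,
)
from .synthetic_data import SimulatedReadSet

__all__ = [
    "MappingParams",
    "JunctionCounts",
    "IsoformCall",
    "UngappedAligner",
    "filter_reads_to_gene_regions",
    "count_junction_reads",
    "call_isoforms",
    "quantify_transcripts",
    "apply_min_abundance_filter",
]

_N = ord("N")


@dataclass(frozen=True)
class MappingParams:
    min_overlap: int = 8  # bases required on each side of the breakpoint
    max_mismatches: int = 2
    seed_length: int = 20
    ambiguous_policy: str = "discard"  # or "count_all"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.ambiguous_policy not in ("discard", "count_all"):
            raise ValueError("ambiguous_policy must be 'discard' or 'count_all'")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _mismatches(a: np.ndarray, b: np.ndarray) -> int:
    # N in either sequence is always a mismatch, never a wildcard
    return int(np.count_nonzero((a != b) | (a == _N) | (b == _N)))


@dataclass(frozen=True)
class Alignment:
    ref_name: str
    offset: int  # read start within reference
    strand: str  # '+' read as given, '-' reverse complement aligned
    mismatches: int


class UngappedAligner:
    """Seed-and-extend ungapped full-read aligner over a small reference set."""

    def __init__(self, references: Mapping[str, str], params: MappingParams):
        self.params = params
        self.ref_names: list[str] = []
        self.ref_arrays: list[np.ndarray] = []
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        k = params.seed_length
        for name, seq in references.items():
            arr = _encode(seq)
            idx = len(self.ref_names)
            self.ref_names.append(name)
            self.ref_arrays.append(arr)
            raw = arr.tobytes()
            for pos in range(len(raw) - k + 1):
                self.index.setdefault(raw[pos : pos + k], []).append((idx, pos))

    def _candidates(self, read: str) -> set[tuple[int, int]]:
        """(ref_idx, diagonal) pairs with at least one exact seed hit."""
        k = self.params.seed_length
        raw = read.upper().encode("ascii")
        L = len(raw)
        out: set[tuple[int, int]] = set()
        for i in range(L - k + 1):
            for ref_idx, pos in self.index.get(raw[i : i + k], ()):
                diag = pos - i
                if 0 <= diag <= len(self.ref_arrays[ref_idx]) - L:
                    out.add((ref_idx, diag))
        return out

    def align_all(self, read: str) -> list[Alignment]:
        """Every full-read ungapped alignment with <= max_mismatches, both strands."""
        results: list[Alignment] = []
        for strand, oriented in (("+", read), ("-", reverse_complement(read))):
            arr = _encode(oriented)
            for ref_idx, diag in self._candidates(oriented):
                ref = self.ref_arrays[ref_idx]
                mm = _mismatches(arr, ref[diag : diag + len(arr)])
                if mm <= self.params.max_mismatches:
                    results.append(
                        Alignment(self.ref_names[ref_idx], diag, strand, mm)
                    )
        return results

    def matches_any(self, read: str) -> bool:
        for strand, oriented in (("+", read), ("-", reverse_complement(read))):
            arr = _encode(oriented)
            for ref_idx, diag in self._candidates(oriented):
                ref = self.ref_arrays[ref_idx]
                if (
                    _mismatches(arr, ref[diag : diag + len(arr)])
                    <= self.params.max_mismatches
                ):
                    return True
        return False


# ---------------------------------------------------------------------------
# Step 1: reduce reads to the gene family


def filter_reads_to_gene_regions(
    reads: SimulatedReadSet,
    gene_regions: Mapping[str, str],
    params: MappingParams = MappingParams(),
    junction_library: JunctionLibrary | None = None,
) -> SimulatedReadSet:
    """Retain reads that place on any gene region or any junction sequence.

    Gene regions (genomic spans, introns included) catch exon-interior reads;
    the junction library catches junction-spanning reads whose two halves are
    separated by an intron in the genome.  Records are preserved verbatim.
    """
    if not gene_regions:
        raise ValueError("gene_regions must be non-empty")
    refs = dict(gene_regions)
    if junction_library is not None:
        for j in junction_library:
            refs[f"junction:{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}"] = (
                j.sequence
            )
    aligner = UngappedAligner(refs, params)
    keep = [i for i, seq in enumerate(reads.sequences) if aligner.matches_any(seq)]
    return reads.subset(keep)


# ---------------------------------------------------------------------------
# Step 2: junction-spanning read counting


@dataclass
class JunctionCounts:
    """Supporting-read counts per junction, with counting provenance."""

    counts: dict[tuple[str, int, int], int]
    total_reads: int
    ambiguous_discarded: int = 0
    params: MappingParams = field(default_factory=MappingParams)

    def get(self, gene_id: str, up: int, down: int) -> int:
        return self.counts.get((gene_id, up, down), 0)

    def for_gene(self, gene_id: str) -> dict[tuple[int, int], int]:
        return {
            (u, d): c for (g, u, d), c in self.counts.items() if g == gene_id
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "upstream_exon": u, "downstream_exon": d, "count": c}
            for (g, u, d), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_id", "upstream_exon", "downstream_exon", "count"]
        )


def _supported_junctions(
    read: str,
    aligner: UngappedAligner,
    breakpoints: Mapping[str, int],
    min_overlap: int,
) -> list[tuple[str, int]]:
    """Junction names this read supports, with the best mismatch count each."""
    best: dict[str, int] = {}
    for aln in aligner.align_all(read):
        b = breakpoints[aln.ref_name]
        up_cov = b - aln.offset
        down_cov = aln.offset + len(read) - b
        if up_cov >= min_overlap and down_cov >= min_overlap:
            if aln.ref_name not in best or aln.mismatches < best[aln.ref_name]:
                best[aln.ref_name] = aln.mismatches
    return list(best.items())


def count_junction_reads(
    reads: SimulatedReadSet,
    library: JunctionLibrary,
    params: MappingParams = MappingParams(),
) -> JunctionCounts:
    """Count reads that span each junction's breakpoint by >= min_overlap per side.

    A read supporting several junctions keeps only those with the minimal
    mismatch count; if more than one remains, the ambiguous policy applies
    (``discard``: drop the read and tally it; ``count_all``: credit each).
    Mates are processed independently, but one fragment contributes at most
    one count to any single junction.
    """
    if library.flank < params.min_overlap:
        raise ValueError("library flank must be >= min_overlap")
    refs = {f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.sequence for j in library}
    breakpoints = {
        f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.breakpoint_offset
        for j in library
    }
    aligner = UngappedAligner(refs, params)
    key_of = {
        f"{j.gene_id}|{j.upstream_exon}|{j.downstream_exon}": j.key for j in library
    }
    seen: dict[tuple[str, int, int], set[str]] = {j.key: set() for j in library}
    counts: dict[tuple[str, int, int], int] = {j.key: 0 for j in library}
    ambiguous = 0
    for rid, seq in zip(reads.ids, reads.sequences):
        supported = _supported_junctions(seq, aligner, breakpoints, params.min_overlap)
        if not supported:
            continue
        best_mm = min(mm for _, mm in supported)
        hits = [name for name, mm in supported if mm == best_mm]
        if len(hits) > 1 and params.ambiguous_policy == "discard":
            ambiguous += 1
            continue
        frag = rid.rsplit("/", 1)[0]
        for name in hits:
            key = key_of[name]
            if frag not in seen[key]:
                seen[key].add(frag)
                counts[key] += 1
    return JunctionCounts(counts, len(reads), ambiguous, params)


# ---------------------------------------------------------------------------
# Step 3: isoform calling


@dataclass
class IsoformCall:
    gene_id: str
    transcripts: list[tuple[TranscriptModel, int]]  # (model, supporting count)
    supported_junctions: dict[tuple[int, int], int]
    ambiguous_junctions: list[tuple[int, int]] = field(default_factory=list)
    min_support: int = 1

    @property
    def n_transcripts(self) -> int:
        return len(self.transcripts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tm, support in self.transcripts:
            rows.append(
                {
                    "gene_id": self.gene_id,
                    "transcript_id": tm.transcript_id,
                    "exon_indices": ",".join(map(str, tm.exon_indices)),
                    "skipped_exons": ",".join(map(str, tm.skipped_exons)) or "-",
                    "support": support,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["gene_id", "transcript_id", "exon_indices", "skipped_exons", "support"],
        )


def _skip_name(gene_id: str, first_skipped: int, last_skipped: int) -> str:
    if first_skipped == last_skipped:
        return f"{gene_id}_DeltaEx{first_skipped}"
    return f"{gene_id}_DeltaEx{first_skipped}Ex{last_skipped}"


def call_isoforms(
    counts: JunctionCounts,
    gene: GeneModel,
    min_support: int = 3,
) -> IsoformCall:
    """Infer transcripts from junction support.

    The canonical transcript is called iff every consecutive junction reaches
    ``min_support``.  Each supported non-canonical junction (i, j), j > i + 1,
    yields one exon-skipping transcript retaining exons 1..i and j..n,
    provided its flanking consecutive junctions (i-1, i) and (j, j+1) — where
    they exist — are also supported.  When several non-canonical junctions are
    supported their phasing into multi-skip transcripts is not identifiable
    from junction counts alone, so each is reported as a single-skip
    transcript and flagged ambiguous.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    gene_counts = counts.for_gene(gene.gene_id)
    if not gene_counts:
        warnings.warn(f"gene {gene.gene_id}: no junctions in counts")
        return IsoformCall(gene.gene_id, [], {}, min_support=min_support)
    n = gene.n_exons
    supported = {pair: c for pair, c in gene_counts.items() if c >= min_support}
    canonical_pairs = canonical_junction_set(gene)
    transcripts: list[tuple[TranscriptModel, int]] = []
    if canonical_pairs and canonical_pairs <= set(supported):
        transcripts.append(
            (
                TranscriptModel(
                    f"{gene.gene_id}_canonical",
                    gene.gene_id,
                    tuple(range(1, n + 1)),
                ),
                min(supported[p] for p in canonical_pairs),
            )
        )
    noncanonical = sorted(
        p for p in supported if p not in canonical_pairs
    )
    ambiguous = noncanonical if len(noncanonical) > 1 else []
    for i, j in noncanonical:
        flanks = [
            p
            for p in ((i - 1, i), (j, j + 1))
            if 1 <= p[0] and p[1] <= n
        ]
        if all(p in supported for p in flanks):
            exons = tuple(range(1, i + 1)) + tuple(range(j, n + 1))
            transcripts.append(
                (
                    TranscriptModel(
                        _skip_name(gene.gene_id, i + 1, j - 1),
                        gene.gene_id,
                        exons,
                    ),
                    supported[(i, j)],
                )
            )
    return IsoformCall(
        gene.gene_id, transcripts, supported, ambiguous, min_support
    )


# ---------------------------------------------------------------------------
# Step 4: abundance from junction counts


def quantify_transcripts(
    counts: JunctionCounts,
    call: IsoformCall,
    gene: GeneModel,
) -> pd.DataFrame:
    """Per-transcript abundance in counts-per-million of examined reads.

    Each called transcript is quantified by the mean count over the junctions
    unique to it among the called set (for a single skip of exons i+1..j-1,
    the skip junction (i, j) is unique to the isoform; the canonical keeps its
    consecutive junctions outside the skipped region's flanks).  Junctions
    shared by several called transcripts carry no isoform information and are
    excluded.  A transcript with no unique junction gets NaN and a flag.
    """
    if not call.transcripts:
        raise ValueError("no transcripts called; nothing to quantify")
    chains: dict[str, set[tuple[int, int]]] = {}
    for tm, _ in call.transcripts:
        idx = tm.exon_indices
        chains[tm.transcript_id] = set(zip(idx, idx[1:]))
    rows = []
    total = max(counts.total_reads, 1)
    for tm, _ in call.transcripts:
        mine = chains[tm.transcript_id]
        others = set().union(
            *(c for t, c in chains.items() if t != tm.transcript_id)
        ) if len(chains) > 1 else set()
        unique = mine - others
        if unique:
            mean_count = float(
                np.mean([counts.get(gene.gene_id, u, d) for u, d in unique])
            )
            cpm = mean_count / total * 1.0e6
            flagged = False
        else:
            cpm = float("nan")
            flagged = True
        rows.append(
            {
                "transcript_id": tm.transcript_id,
                "gene_id": tm.gene_id,
                "unique_junctions": ";".join(f"{u}-{d}" for u, d in sorted(unique)) or "-",
                "cpm": cpm,
                "no_unique_junction": flagged,
            }
        )
    return pd.DataFrame(rows)


def apply_min_abundance_filter(
    abundances: Mapping[str, float], threshold: float
) -> dict[str, float]:
    """Drop transcripts below the abundance threshold.

    Models an assembler's low-expression cutoff: at whole-genome read depth a
    rare isoform falls under the cutoff and vanishes from the assembly, while
    a sub-genome (higher effective depth) analysis retains it.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {t: a for t, a in abundances.items() if a >= threshold}
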