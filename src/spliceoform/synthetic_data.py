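"""Synthetic fixture genome, RNA-seq read simulator and qPCR plate simulator.

This module generates desk-scale stand-ins for the study system: a painted
turtle-like *Dmrt1* gene whose canonical mRNA is 1104 bp and whose
exon-2+3-skipping isoform is 633 bp, random-sequence *Dmrt* paralogs (to probe
junction specificity), a stable normalizer gene, a stage-by-temperature
expression scenario with male-biased upregulation late in the thermosensitive
period, a tissue-mixing (adrenal-kidney masking) layer, a paired-end read
simulator with a ground-truth table, and a TaqMan-style qPCR simulator with
1:5 dilution-series standards.

All generators are driven by :class:`numpy.random.Generator` streams seeded
from explicit integers, so identical parameters yield byte-identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .gene_models import (
    GeneModel,
    GenomicInterval,
    TranscriptSequence,
    reverse_complement,
    splice,
    write_gene_annotation,
    write_genome,
)

__all__ = [
    "FixtureSpec",
    "Fixture",
    "ExpressionScenario",
    "ReadSimParams",
    "QPCRSimParams",
    "SimulatedReadSet",
    "CqTable",
    "build_fixture",
    "mix_tissues",
    "simulate_reads",
    "simulate_qpcr",
    "simulate_expression_matrix",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# transcript-role labels used throughout the expression scenario
CANONICAL = "canonical"
ISOFORM = "isoform"
NORMALIZER = "normalizer"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic genome.

    The default exon lengths [354, 241, 230, 159, 120] sum to 1104 bp with
    exons 2+3 summing to 471 bp, so the full splice is 1104 bp and the
    exon-2+3-skipping splice is 633 bp; the individual lengths themselves are
    a free choice within those two constraints.
    """

    dmrt1_exon_lengths: tuple[int, ...] = (354, 241, 230, 159, 120)
    intron_length: int = 500
    paralog_count: int = 2
    normalizer_gene: str = "Actb"
    min_overlap: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        le = self.dmrt1_exon_lengths
        if len(le) != 5:
            raise ValueError("dmrt1_exon_lengths must list 5 exons")
        if sum(le) != 1104:
            raise ValueError(f"exon lengths must sum to 1104 bp, got {sum(le)}")
        if le[1] + le[2] != 471:
            raise ValueError(
                f"exons 2+3 must sum to 471 bp (1104-633), got {le[1] + le[2]}"
            )
        if min(le) < self.min_overlap:
            raise ValueError("every exon must be at least min_overlap long")
        if self.intron_length < 1:
            raise ValueError("intron_length must be positive")
        if self.paralog_count < 0:
            raise ValueError("paralog_count must be non-negative")


@dataclass
class Fixture:
    """The generated genome, annotation and transcript table, in memory."""

    genome: dict[str, str]
    genes: list[GeneModel]
    transcripts: pd.DataFrame  # transcript_id, gene_id, role, exon_indices, length
    spec: FixtureSpec

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def transcript_sequence(self, transcript_id: str) -> TranscriptSequence:
        row = self.transcripts.set_index("transcript_id").loc[transcript_id]
        idx = tuple(int(i) for i in str(row["exon_indices"]).split(","))
        return splice(self.gene(row["gene_id"]), idx, self.genome, transcript_id)

    def transcripts_by_role(self) -> dict[str, TranscriptSequence]:
        """Map scenario roles (canonical/isoform/normalizer) to sequences."""
        out = {}
        for _, row in self.transcripts.iterrows():
            if row["role"] in (CANONICAL, ISOFORM, NORMALIZER):
                out[row["role"]] = self.transcript_sequence(row["transcript_id"])
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "transcripts": outdir / "transcripts.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_gene_annotation(self.genes, paths["annotation"])
        self.transcripts.to_csv(paths["transcripts"], sep="\t", index=False)
        return paths


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    exon_lengths: Sequence[int],
    intron_length: int,
    strand: str,
    family_id: str,
    pad: int = 200,
) -> tuple[str, str, GeneModel]:
    """Build one gene on its own scaffold from a seeded random stream."""
    scaffold = f"scf_{gene_id}"
    pieces = [_random_seq(rng, pad)]
    coords = []
    pos = pad
    for k, L in enumerate(exon_lengths):
        coords.append((pos, pos + L))
        pieces.append(_random_seq(rng, L))
        pos += L
        if k < len(exon_lengths) - 1:
            pieces.append(_random_seq(rng, intron_length))
            pos += intron_length
    pieces.append(_random_seq(rng, pad))
    seq = "".join(pieces)
    ivs = [GenomicInterval(scaffold, s, e, strand) for s, e in coords]
    if strand == "-":
        ivs = ivs[::-1]  # exon 1 = genomically last for minus-strand genes
    return scaffold, seq, GeneModel(gene_id, ivs, family_id=family_id)


def build_fixture(spec: FixtureSpec = FixtureSpec(), outdir: str | Path | None = None) -> Fixture:
    """Generate the fixture genome, annotation and transcript table.

    One scaffold per gene: Dmrt1 (5 exons, plus strand), ``paralog_count``
    Dmrt paralogs with distinct random sequences (the first on the minus
    strand, exercising strand handling), and the normalizer gene.  Paralog
    homology to Dmrt1 is zero by construction — independent uniform-random
    sequences — which is what makes them a clean junction-specificity probe.
    """
    rng = np.random.default_rng(spec.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []

    scaf, seq, g = _make_gene(
        rng, "Dmrt1", spec.dmrt1_exon_lengths, spec.intron_length, "+", "Dmrt"
    )
    genome[scaf] = seq
    genes.append(g)

    for p in range(spec.paralog_count):
        n_ex = int(rng.integers(3, 6))
        lens = [int(rng.integers(120, 400)) for _ in range(n_ex)]
        strand = "-" if p == 0 else "+"
        scaf, seq, g = _make_gene(
            rng, f"Dmrt{p + 2}", lens, spec.intron_length, strand, "Dmrt"
        )
        genome[scaf] = seq
        genes.append(g)

    norm_lens = [420, 380, 260]  # 1060 bp normalizer mRNA
    scaf, seq, g = _make_gene(
        rng, spec.normalizer_gene, norm_lens, spec.intron_length, "+", "housekeeping"
    )
    genome[scaf] = seq
    genes.append(g)

    rows = []
    for g in genes:
        all_idx = tuple(range(1, g.n_exons + 1))
        if g.gene_id == "Dmrt1":
            role = CANONICAL
        elif g.family_id == "Dmrt":
            role = "paralog"
        else:
            role = NORMALIZER
        rows.append(
            {
                "transcript_id": f"{g.gene_id}_canonical",
                "gene_id": g.gene_id,
                "role": role,
                "exon_indices": ",".join(map(str, all_idx)),
                "length": sum(len(iv) for iv in g.intervals),
            }
        )
        if g.gene_id == "Dmrt1":
            skip_idx = (1, 4, 5)
            rows.append(
                {
                    "transcript_id": "Dmrt1_DeltaEx2Ex3",
                    "gene_id": "Dmrt1",
                    "role": ISOFORM,
                    "exon_indices": ",".join(map(str, skip_idx)),
                    "length": sum(g.exon_length(i) for i in skip_idx),
                }
            )
    fixture = Fixture(genome, genes, pd.DataFrame(rows), spec)
    if outdir is not None:
        fixture.write(outdir)
    return fixture


# ---------------------------------------------------------------------------
# Expression scenario and tissue mixing


def mix_tissues(gonad_expr: float, ak_expr: float, gonad_fraction: float) -> float:
    """Expression in a mixed AKG sample: f*gonad + (1-f)*AK."""
    if not 0.0 <= gonad_fraction <= 1.0:
        raise ValueError(f"gonad_fraction must be in [0, 1], got {gonad_fraction}")
    if gonad_expr < 0 or ak_expr < 0:
        raise ValueError("expression levels must be non-negative")
    return gonad_fraction * gonad_expr + (1.0 - gonad_fraction) * ak_expr


@dataclass(frozen=True)
class ExpressionScenario:
    """Stage x temperature abundances for canonical, isoform and normalizer.

    Defaults encode the qualitative thermal pattern: canonical expression
    male-biased (MPT > FPT) only at stages 19 and 22 (4- and 8-fold), the
    skipping isoform tracking the canonical at one tenth the abundance, and a
    normalizer flat across every cell.  gonad_fraction models what tissue was
    actually sampled per stage: whole trunks at stage 9, adrenal-kidney-gonad
    complexes at 12/15, isolated gonads at 19/22 — the masking layer.
    """

    stages: tuple[int, ...] = (9, 12, 15, 19, 22)
    temperatures: tuple[str, ...] = ("MPT", "FPT")
    replicates: int = 12
    canonical_base: float = 10.0  # gonad abundance at FPT, arbitrary units
    canonical_mpt_fold: Mapping[int, float] = field(
        default_factory=lambda: {9: 1.0, 12: 1.0, 15: 1.0, 19: 4.0, 22: 8.0}
    )
    isoform_fraction: float = 0.1  # isoform = canonical / 10, every cell
    normalizer_abundance: float = 30.0
    ak_abundance: Mapping[str, float] = field(
        default_factory=lambda: {CANONICAL: 5.0, ISOFORM: 0.5, NORMALIZER: 30.0}
    )
    gonad_fraction: Mapping[int, float] = field(
        default_factory=lambda: {9: 0.02, 12: 0.1, 15: 0.1, 19: 1.0, 22: 1.0}
    )
    biological_sigma: float = 0.4  # lognormal sd (natural log) across embryos
    loading_sigma: float = 0.3  # shared per-sample loading factor (normalizer cancels)

    def gonad_abundance(self, role: str, stage: int, temperature: str) -> float:
        if role == NORMALIZER:
            return self.normalizer_abundance
        fold = self.canonical_mpt_fold[stage] if temperature == "MPT" else 1.0
        value = self.canonical_base * fold
        if role == ISOFORM:
            value *= self.isoform_fraction
        return value

    def mixed_abundance(self, role: str, stage: int, temperature: str) -> float:
        """Abundance in the sampled tissue after adrenal-kidney masking."""
        return mix_tissues(
            self.gonad_abundance(role, stage, temperature),
            self.ak_abundance[role],
            self.gonad_fraction[stage],
        )


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadSimParams:
    read_length: int = 150
    library_size: int = 50_000  # read pairs
    fragment_mean: float = 200.0
    fragment_sd: float = 30.0
    error_rate: float = 0.001  # per-base substitution probability
    paired: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed mean fragment length")
        if not 0.0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.library_size < 1:
            raise ValueError("library_size must be positive")


@dataclass
class SimulatedReadSet:
    """Flat read list (both mates) plus a fragment-level ground-truth table."""

    ids: list[str]
    sequences: list[str]
    truth: pd.DataFrame  # fragment_id, transcript_id, start, end
    read_length: int

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep: Sequence[int]) -> "SimulatedReadSet":
        frags = {self.ids[i].rsplit("/", 1)[0] for i in keep}
        return SimulatedReadSet(
            [self.ids[i] for i in keep],
            [self.sequences[i] for i in keep],
            self.truth[self.truth["fragment_id"].isin(frags)].reset_index(drop=True),
            self.read_length,
        )

    def origin_counts(self) -> pd.Series:
        return self.truth["transcript_id"].value_counts()

    def write_fastq(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write gzipped R1/R2 FASTQ files with constant placeholder qualities."""
        prefix = Path(prefix)
        r1 = prefix.with_name(prefix.name + "_R1.fastq.gz")
        r2 = prefix.with_name(prefix.name + "_R2.fastq.gz")
        handles = {
            "1": gzip.open(r1, "wt"),
            "2": gzip.open(r2, "wt"),
        }
        qual = "I" * self.read_length
        try:
            for rid, seq in zip(self.ids, self.sequences):
                mate = rid.rsplit("/", 1)[1]
                handles[mate].write(f"@{rid}\n{seq}\n+\n{qual[: len(seq)]}\n")
        finally:
            for fh in handles.values():
                fh.close()
        return r1, r2

    @classmethod
    def read_fastq(cls, r1: str | Path, r2: str | Path | None, read_length: int) -> "SimulatedReadSet":
        from Bio import SeqIO

        ids: list[str] = []
        seqs: list[str] = []
        for path in (r1, r2):
            if path is None:
                continue
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(str(path), "rt") as fh:
                for rec in SeqIO.parse(fh, "fastq"):
                    ids.append(rec.id)
                    seqs.append(str(rec.seq).upper())
        truth = pd.DataFrame(columns=["fragment_id", "transcript_id", "start", "end"])
        return cls(ids, seqs, truth, read_length)


def simulate_reads(
    transcripts: Mapping[str, TranscriptSequence] | Sequence[TranscriptSequence],
    abundances: Mapping[str, float],
    params: ReadSimParams,
) -> SimulatedReadSet:
    """Simulate paired-end reads with a known transcript of origin.

    The transcript of origin for each fragment is drawn with probability
    proportional to abundance x transcript length (a longer molecule sheds
    more fragments); fragment start positions are uniform; fragment lengths
    are Normal(mean, sd) clipped to [read_length, transcript length].
    Substitution errors are i.i.d. per base at ``error_rate``; R2 is the
    reverse complement of the fragment's 3' end.
    """
    if not isinstance(transcripts, Mapping):
        transcripts = {t.transcript_id: t for t in transcripts}
    names = [n for n in transcripts if abundances.get(n, 0.0) > 0]
    if not names:
        raise ValueError("all transcript abundances are zero")
    rng = np.random.default_rng(params.seed)
    lengths = np.array([transcripts[n].length for n in names], dtype=float)
    weights = np.array([abundances[n] for n in names]) * lengths
    probs = weights / weights.sum()

    short = [n for n in names if transcripts[n].length < params.fragment_mean]
    if short:
        warnings.warn(
            f"transcript(s) shorter than mean fragment length, truncating: {short}"
        )

    n = params.library_size
    origin = rng.choice(len(names), size=n, p=probs)
    frag_len = rng.normal(params.fragment_mean, params.fragment_sd, size=n)
    tlen = lengths[origin]
    frag_len = np.clip(np.rint(frag_len), params.read_length, tlen).astype(int)
    start = rng.integers(0, (tlen - frag_len + 1).astype(int))
    end = start + frag_len

    ids: list[str] = []
    seqs: list[str] = []
    rows = []
    L = params.read_length
    n_err = rng.binomial(L, params.error_rate, size=(n, 2))
    for k in range(n):
        t = transcripts[names[origin[k]]]
        frag = t.sequence[start[k] : end[k]]
        r1 = frag[:L]
        r2 = reverse_complement(frag[-L:])
        reads = [r1, r2] if params.paired else [r1]
        frag_id = f"frag{k:07d}"
        for m, read in enumerate(reads, start=1):
            if n_err[k, m - 1]:
                arr = bytearray(read, "ascii")
                pos = rng.choice(len(arr), size=n_err[k, m - 1], replace=False)
                for p in pos:
                    cur = arr[p]
                    alts = [b for b in b"ACGT" if b != cur]
                    arr[p] = alts[rng.integers(3)]
                read = arr.decode("ascii")
            ids.append(f"{frag_id}/{m}")
            seqs.append(read)
        rows.append(
            {
                "fragment_id": frag_id,
                "transcript_id": t.transcript_id,
                "start": int(start[k]),
                "end": int(end[k]),
            }
        )
    return SimulatedReadSet(ids, seqs, pd.DataFrame(rows), L)


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass(frozen=True)
class QPCRSimParams:
    """TaqMan-style simulator settings.

    ``efficiency`` is the per-cycle amplification factor E in (1, 2];
    Cq = cq_at_unit_input - log_E(abundance) + Normal(0, replicate_noise_sd).
    """

    efficiency: Mapping[str, float] = field(
        default_factory=lambda: {CANONICAL: 1.95, ISOFORM: 1.90, NORMALIZER: 2.0}
    )
    cq_at_unit_input: Mapping[str, float] = field(
        default_factory=lambda: {CANONICAL: 24.0, ISOFORM: 26.0, NORMALIZER: 22.0}
    )
    replicate_noise_sd: float = 0.1  # cycles, technical
    dilution_ratio: int = 5
    n_standards: int = 8
    tech_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_standards < 3:
            raise ValueError("n_standards must be >= 3")
        if self.dilution_ratio < 2:
            raise ValueError("dilution_ratio must be >= 2")
        for assay, e in self.efficiency.items():
            if not 1.0 < e <= 2.2:
                raise ValueError(f"assay {assay}: efficiency {e} outside (1, 2.2]")


@dataclass
class CqTable:
    """qPCR measurements: biological samples plus the dilution-series standards."""

    samples: pd.DataFrame  # assay, stage, temperature, sample_id, tech_rep, Cq
    standards: pd.DataFrame  # assay, dilution_step, tech_rep, relative_input, Cq

    def write(self, samples_path: str | Path, standards_path: str | Path) -> None:
        self.samples.to_csv(samples_path, sep="\t", index=False)
        self.standards.to_csv(standards_path, sep="\t", index=False)

    @classmethod
    def read(cls, samples_path: str | Path, standards_path: str | Path) -> "CqTable":
        return cls(
            pd.read_csv(samples_path, sep="\t"),
            pd.read_csv(standards_path, sep="\t"),
        )


def _cq(abundance: float, efficiency: float, cq0: float) -> float:
    if abundance <= 0:
        return np.nan  # "no amplification"
    return cq0 - np.log(abundance) / np.log(efficiency)


def simulate_qpcr(
    scenario: ExpressionScenario = ExpressionScenario(),
    params: QPCRSimParams = QPCRSimParams(),
) -> CqTable:
    """Simulate Cq tables for every assay under the expression scenario.

    Each biological sample (one embryo) gets a lognormal per-transcript
    biological factor and a shared lognormal loading factor (RNA input), then
    ``tech_reps`` technical replicates with Gaussian cycle noise.  A pooled
    stock (mean abundance over all samples per assay) seeds the 1:5 dilution
    series of ``n_standards`` standards, also in technical replicates.
    """
    rng = np.random.default_rng(params.seed)
    assays = list(params.efficiency)
    sample_rows = []
    pooled: dict[str, list[float]] = {a: [] for a in assays}
    for stage in scenario.stages:
        for temp in scenario.temperatures:
            for r in range(scenario.replicates):
                sample_id = f"s{stage}_{temp}_r{r + 1}"
                loading = float(
                    np.exp(rng.normal(0.0, scenario.loading_sigma))
                )
                for assay in assays:
                    mean_ab = scenario.mixed_abundance(assay, stage, temp)
                    bio = float(np.exp(rng.normal(0.0, scenario.biological_sigma)))
                    abundance = mean_ab * bio * loading
                    pooled[assay].append(abundance)
                    base_cq = _cq(
                        abundance,
                        params.efficiency[assay],
                        params.cq_at_unit_input[assay],
                    )
                    for tr in range(1, params.tech_reps + 1):
                        cq = (
                            base_cq + rng.normal(0.0, params.replicate_noise_sd)
                            if np.isfinite(base_cq)
                            else np.nan
                        )
                        sample_rows.append(
                            {
                                "assay": assay,
                                "stage": stage,
                                "temperature": temp,
                                "sample_id": sample_id,
                                "tech_rep": tr,
                                "Cq": cq,
                            }
                        )
    std_rows = []
    for assay in assays:
        stock = float(np.mean(pooled[assay]))
        for step in range(params.n_standards):
            rel_input = params.dilution_ratio ** (-step)
            base_cq = _cq(
                stock * rel_input,
                params.efficiency[assay],
                params.cq_at_unit_input[assay],
            )
            for tr in range(1, params.tech_reps + 1):
                std_rows.append(
                    {
                        "assay": assay,
                        "dilution_step": step,
                        "tech_rep": tr,
                        "relative_input": rel_input,
                        "Cq": base_cq
                        + rng.normal(0.0, params.replicate_noise_sd),
                    }
                )
    return CqTable(pd.DataFrame(sample_rows), pd.DataFrame(std_rows))


def simulate_expression_matrix(
    scenario: ExpressionScenario,
    seed: int,
    replicates: int | None = None,
    total_cpm: float = 1.0e4,
) -> pd.DataFrame:
    """Direct CPM-scale expression matrix (the RNA-seq path without reads).

    Per-sample values are the scenario's mixed abundances times lognormal
    biological noise, rescaled so the three assays sum to ``total_cpm`` on
    average — a cheap stand-in for full read simulation when only the
    statistics are under study.
    """
    rng = np.random.default_rng(seed)
    reps = scenario.replicates if replicates is None else replicates
    roles = [CANONICAL, ISOFORM, NORMALIZER]
    grand = np.mean(
        [
            sum(scenario.mixed_abundance(a, s, t) for a in roles)
            for s in scenario.stages
            for t in scenario.temperatures
        ]
    )
    scale = total_cpm / grand
    rows = []
    for stage in scenario.stages:
        for temp in scenario.temperatures:
            for r in range(reps):
                row = {"stage": stage, "temperature": temp, "replicate": r + 1}
                for role in roles:
                    noise = float(np.exp(rng.normal(0.0, scenario.biological_sigma)))
                    row[role] = scenario.mixed_abundance(role, stage, temp) * noise * scale
                rows.append(row)
    return pd.DataFrame(rows)
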